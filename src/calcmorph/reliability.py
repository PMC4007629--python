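"""Reliability and group-comparison statistics for repeated measurements.

Implements the study's statistical layer:

* ICC(2,1) — intraclass correlation under the two-way random-effects model,
  absolute agreement, single measurement — with the F-based 95% CI
  (Shrout–Fleiss / McGraw–Wong);
* RMS-SD — the root mean square of per-subject standard deviations over
  repeated measurements, sqrt(Σ SDᵢ² / N);
* CV — RMS-SD as a percentage of the parameter mean (linear and areal
  parameters only; angles have no natural ratio scale here);
* Bonett's approximation for the number of subjects needed to estimate an
  ICC with a given confidence-interval width;
* ANCOVA comparison of the gender groups adjusting for body height;
* independent-samples t-tests for demographics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .params import ANGLE_PARAMETERS, PARAMETERS

__all__ = [
    "ICCResult", "icc_2_1", "rms_sd", "cv_percent", "bonett_n",
    "reliability_report", "ancova_gender", "demographics_ttest",
]


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) point estimate with its two-sided confidence interval.

    ``degenerate`` is True when the ratings carry no variance at all, in
    which case the ICC is undefined and estimate/CI are NaN.
    """

    estimate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    degenerate: bool = False

    def __iter__(self):
        return iter((self.estimate, self.ci_low, self.ci_high))


def _ratings_matrix(ratings) -> np.ndarray:
    y = np.asarray(ratings, dtype=float)
    if isinstance(ratings, pd.DataFrame):
        y = ratings.to_numpy(dtype=float)
    if y.ndim != 2:
        raise DataError("ratings must be a 2-D subjects × raters table")
    n, k = y.shape
    if n < 2 or k < 2:
        raise DataError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(y)):
        raise DataError("ratings table must be complete (no missing values)")
    return y


def icc_2_1(ratings, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    Computed from the two-way ANOVA mean squares of the complete
    subjects × raters table:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    with the F-based confidence interval of McGraw & Wong (Satterthwaite
    degrees of freedom for the rater term). Zero total variance is flagged
    as degenerate rather than returned as a number.
    """
    y = _ratings_matrix(ratings)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((y - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    if sst <= 0:
        return ICCResult(math.nan, math.nan, math.nan, alpha, degenerate=True)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return ICCResult(math.nan, math.nan, math.nan, alpha, degenerate=True)
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # perfect agreement: CI collapses onto the estimate
        return ICCResult(icc, icc, icc, alpha)

    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    if not math.isfinite(a):
        return ICCResult(icc, icc, icc, alpha)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else (n - 1) * (k - 1)

    f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = (n * (msr - f_low * mse) /
             (f_low * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_up * msr - mse) /
             (k * msc + (k * n - k - n) * mse + n * f_up * msr))
    lower, upper = min(lower, icc), max(upper, icc)
    return ICCResult(icc, lower, upper, alpha)


def rms_sd(measurements) -> float:
    """RMS-SD precision: sqrt of the mean squared per-subject SD.

    ``measurements`` is either a 2-D array (subjects × repeats) or a long
    DataFrame with columns ``subject_id`` and ``value``. Every subject must
    have at least two repeats (sample SD, ddof=1).
    """
    if isinstance(measurements, pd.DataFrame):
        if not {"subject_id", "value"}.issubset(measurements.columns):
            raise DataError("long-format input needs columns subject_id, value")
        groups = [(sid, grp["value"].to_numpy(float))
                  for sid, grp in measurements.groupby("subject_id", sort=False)]
    else:
        y = np.asarray(measurements, dtype=float)
        if y.ndim != 2:
            raise DataError("measurements must be subjects × repeats")
        groups = [(i, row) for i, row in enumerate(y)]
    if not groups:
        raise DataError("no subjects supplied")
    sds = []
    for sid, vals in groups:
        if len(vals) < 2:
            raise DataError(f"subject {sid!r} has fewer than 2 repeated "
                            "measurements")
        sds.append(float(np.std(vals, ddof=1)))
    return float(np.sqrt(np.mean(np.square(sds))))


def cv_percent(rms_sd_value: float, mean_value: float) -> float:
    """Coefficient of variation: the precision as a percentage of the mean."""
    if not mean_value > 0:
        raise DataError(f"CV needs a positive mean, got {mean_value}")
    if rms_sd_value < 0:
        raise DataError(f"RMS-SD must be >= 0, got {rms_sd_value}")
    return 100.0 * rms_sd_value / mean_value


def bonett_n(rho0: float, width: float, k: int = 3, alpha: float = 0.05) -> int:
    """Subjects needed so that a (1−α) CI for an ICC near ``rho0`` has the
    requested total width, by Bonett's (2002) approximation:

        n = ceil( 8 z²_{α/2} (1−ρ0)² (1 + (k−1)ρ0)² / (k (k−1) w²) + 1 )

    ``k`` defaults to 3 raters.
    """
    if not 0.0 < rho0 < 1.0:
        raise DataError(f"planning ICC must lie in (0, 1), got {rho0}")
    if not width > 0:
        raise DataError(f"CI width must be positive, got {width}")
    if k < 2:
        raise DataError(f"need at least 2 raters, got {k}")
    if not 0.0 < alpha < 1.0:
        raise DataError(f"alpha must lie in (0, 1), got {alpha}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    n = (8.0 * z ** 2 * (1.0 - rho0) ** 2 * (1.0 + (k - 1) * rho0) ** 2 /
         (k * (k - 1) * width ** 2) + 1.0)
    return int(math.ceil(n - 1e-12))


# ---------------------------------------------------------------------------
# session-table reports
# ---------------------------------------------------------------------------

def _pivot(sessions: pd.DataFrame, param: str, examiner: Optional[int] = None,
           by: str = "session") -> pd.DataFrame:
    df = sessions
    if examiner is not None:
        df = df[df["examiner"] == examiner]
    return df.pivot_table(index="subject_id", columns=by, values=param,
                          sort=True)


def reliability_report(sessions: pd.DataFrame,
                       parameters: Sequence[str] = PARAMETERS,
                       intra_examiner: int = 1,
                       alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Intra- and inter-observer reliability from a long session table.

    Input columns: subject_id, examiner, session, one column per parameter.
    Returns three frames keyed ``intra``, ``inter_pairwise``, ``inter_overall``:

    * ``intra`` — per parameter, the designated examiner's repeat sessions:
      ICC(2,1) with CI, RMS-SD, and CV (% , NaN for angles);
    * ``inter_pairwise`` — per parameter and examiner pair, first-session
      measurements: ICC(2,1), RMS-SD across the pair, CV;
    * ``inter_overall`` — per parameter, first-session measurements of all
      examiners jointly: ICC(2,1) with CI (the "average" multi-examiner ICC).
    """
    needed = {"subject_id", "examiner", "session"}
    if not needed.issubset(sessions.columns):
        raise DataError(f"session table needs columns {sorted(needed)}")
    params = [p for p in parameters if p in sessions.columns]
    if not params:
        raise DataError("session table has no parameter columns")
    examiners = sorted(sessions["examiner"].unique())

    intra_rows, pair_rows, overall_rows = [], [], []
    for p in params:
        mean_val = float(sessions[p].mean())
        wide = _pivot(sessions, p, examiner=intra_examiner, by="session")
        if wide.shape[1] >= 2:
            res = icc_2_1(wide, alpha=alpha)
            prec = rms_sd(wide.to_numpy())
            cv = (math.nan if p in ANGLE_PARAMETERS
                  else cv_percent(prec, mean_val))
            intra_rows.append({"parameter": p, "icc": res.estimate,
                               "ci_low": res.ci_low, "ci_high": res.ci_high,
                               "rms_sd": prec, "cv_pct": cv,
                               "degenerate": res.degenerate})
        first = sessions[sessions["session"] == 1]
        wide_e = _pivot(first, p, by="examiner")
        for i, ea in enumerate(examiners):
            for eb in examiners[i + 1:]:
                if ea not in wide_e.columns or eb not in wide_e.columns:
                    continue
                pair = wide_e[[ea, eb]].to_numpy()
                res = icc_2_1(pair, alpha=alpha)
                prec = rms_sd(pair)
                cv = (math.nan if p in ANGLE_PARAMETERS
                      else cv_percent(prec, mean_val))
                pair_rows.append({"parameter": p, "examiner_a": ea,
                                  "examiner_b": eb, "icc": res.estimate,
                                  "ci_low": res.ci_low, "ci_high": res.ci_high,
                                  "rms_sd": prec, "cv_pct": cv,
                                  "degenerate": res.degenerate})
        if len(examiners) >= 2:
            res = icc_2_1(wide_e[examiners], alpha=alpha)
            overall_rows.append({"parameter": p, "icc": res.estimate,
                                 "ci_low": res.ci_low, "ci_high": res.ci_high,
                                 "degenerate": res.degenerate})
    return {
        "intra": pd.DataFrame(intra_rows),
        "inter_pairwise": pd.DataFrame(pair_rows),
        "inter_overall": pd.DataFrame(overall_rows),
    }


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def ancova_gender(records: pd.DataFrame,
                  parameters: Sequence[str] = PARAMETERS,
                  covariate: str = "height_m") -> pd.DataFrame:
    """Compare male and female groups per parameter, adjusting for height.

    Fits an equal-slopes linear model ``value ~ sex + covariate`` per
    parameter and reports the sex-effect F statistic and p value plus the
    covariate-adjusted group means evaluated at the pooled mean covariate.
    A constant covariate is dropped with a warning (plain one-way ANOVA).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if "sex" not in records.columns:
        raise DataError("records need a 'sex' column")
    sexes = sorted(records["sex"].unique())
    if len(sexes) != 2:
        raise DataError(f"need exactly two sexes, found {sexes}")
    params = [p for p in parameters if p in records.columns]
    if not params:
        raise DataError("records contain no parameter columns")

    use_cov = covariate in records.columns
    if use_cov and records[covariate].nunique() <= 1:
        warnings.warn(f"covariate {covariate!r} is constant; dropped from the "
                      "model", stacklevel=2)
        use_cov = False
    if not use_cov and covariate not in records.columns:
        raise DataError(f"covariate column {covariate!r} missing")

    rows = []
    for p in params:
        df = records[["sex", p] + ([covariate] if use_cov else [])].dropna()
        df = df.rename(columns={p: "value"})
        formula = "value ~ C(sex)" + (f" + {covariate}" if use_cov else "")
        fit = smf.ols(formula, data=df).fit()
        table = anova_lm(fit, typ=2)
        f_stat = float(table.loc["C(sex)", "F"])
        p_val = float(table.loc["C(sex)", "PR(>F)"])
        adj = {}
        for sex in sexes:
            pred = {"sex": [sex]}
            if use_cov:
                pred[covariate] = [float(df[covariate].mean())]
            adj[sex] = float(fit.predict(pd.DataFrame(pred)).iloc[0])
        rows.append({"parameter": p,
                     f"adj_mean_{sexes[0]}": adj[sexes[0]],
                     f"adj_mean_{sexes[1]}": adj[sexes[1]],
                     "F": f_stat, "p": p_val,
                     "covariate": covariate if use_cov else "none",
                     f"n_{sexes[0]}": int((df["sex"] == sexes[0]).sum()),
                     f"n_{sexes[1]}": int((df["sex"] == sexes[1]).sum())})
    return pd.DataFrame(rows)


def demographics_ttest(groups: pd.DataFrame,
                       variables: Sequence[str],
                       group_col: str = "sex") -> pd.DataFrame:
    """Two-sided independent-samples t-test per demographic variable.

    Degenerate (zero pooled variance) cases are flagged: t = 0, p = 1 when
    the group means coincide, otherwise t = ±inf, p = 0.
    """
    levels = sorted(groups[group_col].unique())
    if len(levels) != 2:
        raise DataError(f"need exactly two groups, found {levels}")
    a = groups[groups[group_col] == levels[0]]
    b = groups[groups[group_col] == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs at least 2 observations")
    rows = []
    for var in variables:
        x, y = a[var].to_numpy(float), b[var].to_numpy(float)
        pooled_var = np.var(x, ddof=1) + np.var(y, ddof=1)
        if pooled_var == 0:
            same = math.isclose(float(x.mean()), float(y.mean()))
            t = 0.0 if same else math.copysign(math.inf, x.mean() - y.mean())
            p = 1.0 if same else 0.0
            rows.append({"variable": var, "t": t, "p": p, "degenerate": True})
            continue
        t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append({"variable": var, "t": float(t), "p": float(p),
                     "degenerate": False})
    return pd.DataFrame(rows)
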