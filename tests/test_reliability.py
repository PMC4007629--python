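"""ICC(2,1), RMS-SD, CV, Bonett planning, ANCOVA, and t-tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import calcmorph as cm
from calcmorph.errors import DataError


class TestICC:
    def test_perfect_agreement(self):
        y = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0], [5.0, 5.0, 5.0]])
        res = cm.icc_2_1(y)
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert not res.degenerate

    def test_variance_ratio_limit(self):
        # sigma_b = 6.0, sigma_e = 0.6 -> ICC -> 36/(36+0.36) ~ 0.990
        rng = np.random.default_rng(0)
        est = []
        for _ in range(30):
            truth = rng.normal(0, 6.0, 36)
            y = truth[:, None] + rng.normal(0, 0.6, (36, 2))
            est.append(cm.icc_2_1(y).estimate)
        assert np.mean(est) == pytest.approx(36 / 36.36, abs=0.01)

    def test_against_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        y = (rng.normal(50, 5, (6, 1)) + rng.normal(0, 1, (6, 3)) +
             rng.normal(0, 0.5, (1, 3)))
        mine = cm.icc_2_1(y)
        long = pd.DataFrame({"s": np.repeat(range(6), 3),
                             "r": list(range(3)) * 6, "y": y.ravel()})
        ref = pg.intraclass_corr(long, targets="s", raters="r", ratings="y")
        row = ref[ref.Type == "ICC2"].iloc[0] if (ref.Type == "ICC2").any() \
            else ref[ref.Type == "ICC(A,1)"].iloc[0]
        assert mine.estimate == pytest.approx(float(row.ICC), abs=1e-3)
        lo, hi = row.CI95
        assert mine.ci_low == pytest.approx(float(lo), abs=0.01)
        assert mine.ci_high == pytest.approx(float(hi), abs=0.01)

    def test_mixed_effects_variance_oracle(self):
        # REML-free check: moment estimate of sigma_b^2/(sigma_b^2+sigma_r^2
        # +sigma_e^2) from the two-way ANOVA on a fixed 6x3 table
        y = np.array([[9.0, 10.0, 11.0], [5.0, 6.0, 5.5], [8.0, 8.5, 9.5],
                      [2.0, 2.5, 3.5], [7.0, 6.0, 7.5], [4.0, 5.0, 4.5]])
        n, k = y.shape
        msr = k * np.var(y.mean(1), ddof=1)
        msc = n * np.var(y.mean(0), ddof=1)
        sse = ((y - y.mean()) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
        mse = sse / ((n - 1) * (k - 1))
        sb2 = (msr - mse) / k
        sr2 = (msc - mse) / n
        oracle = sb2 / (sb2 + sr2 + mse)
        assert cm.icc_2_1(y).estimate == pytest.approx(oracle, abs=1e-3)

    def test_zero_variance_flagged(self):
        res = cm.icc_2_1(np.full((4, 3), 2.5))
        assert res.degenerate
        assert math.isnan(res.estimate)

    def test_monotone_in_error_variance(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(0, 6.0, 200)
        noise = rng.normal(0, 1.0, (200, 2))
        iccs = [cm.icc_2_1(truth[:, None] + sd * noise).estimate
                for sd in (0.1, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_small_table_rejected(self):
        with pytest.raises(DataError, match="2 subjects"):
            cm.icc_2_1(np.array([[1.0, 2.0]]))


class TestRmsSd:
    def test_identical_repeats_give_zero(self):
        assert cm.rms_sd(np.tile([[3.0]], (5, 4))) == 0.0

    def test_constant_per_subject_sd(self):
        c = 0.7
        y = np.array([[x, x + c * math.sqrt(2)] for x in (1.0, 5.0, 9.0)])
        assert cm.rms_sd(y) == pytest.approx(c, rel=1e-12)

    def test_error_recovery(self):
        rng = np.random.default_rng(2)
        vals = [cm.rms_sd(rng.normal(74.2, 6.0, (36, 1)) +
                          rng.normal(0, 0.6, (36, 2)))
                for _ in range(50)]
        assert np.mean(vals) == pytest.approx(0.6, abs=0.05)

    def test_single_repeat_names_subject(self):
        df = pd.DataFrame({"subject_id": ["s1", "s1", "s2"],
                           "value": [1.0, 2.0, 3.0]})
        with pytest.raises(DataError, match="s2"):
            cm.rms_sd(df)

    def test_ordering_and_shift_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(10, 2, (8, 3))
        base = cm.rms_sd(y)
        assert cm.rms_sd(y[::-1]) == pytest.approx(base, rel=1e-12)
        y2 = y.copy()
        y2[4] += 17.0  # shifting all repeats of one subject leaves its SD
        assert cm.rms_sd(y2) == pytest.approx(base, rel=1e-12)


class TestCV:
    def test_reference_row(self):
        assert round(cm.cv_percent(0.6, 74.2), 1) == 0.8

    def test_extremes(self):
        assert cm.cv_percent(0.0, 5.0) == 0.0
        assert cm.cv_percent(5.0, 5.0) == 100.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DataError, match="positive mean"):
            cm.cv_percent(1.0, 0.0)


class TestBonett:
    def test_three_rater_study_size(self):
        assert cm.bonett_n(0.8, 0.2, k=3, alpha=0.05) == 36

    def test_two_rater_value(self):
        assert cm.bonett_n(0.8, 0.2, k=2, alpha=0.05) == 51

    def test_inverse_square_width_dependence(self):
        n_w = cm.bonett_n(0.8, 0.1, k=3)
        n_2w = cm.bonett_n(0.8, 0.2, k=3)
        assert (n_w - 1) / (n_2w - 1) == pytest.approx(4.0, abs=0.15)

    def test_brute_force_width_search(self):
        # smallest n whose approximate CI width is <= the target
        z = stats.norm.ppf(0.975)
        for rho0 in (0.6, 0.8, 0.9):
            for k in (2, 3, 5):
                target = 0.2

                def width(n):
                    return math.sqrt(8 * z ** 2 * (1 - rho0) ** 2 *
                                     (1 + (k - 1) * rho0) ** 2 /
                                     (k * (k - 1) * (n - 1)))

                n = 2
                while width(n) > target:
                    n += 1
                assert cm.bonett_n(rho0, target, k=k) == n

    def test_domain_errors(self):
        with pytest.raises(DataError):
            cm.bonett_n(1.2, 0.2)
        with pytest.raises(DataError):
            cm.bonett_n(0.8, 0.2, k=1)


class TestReliabilityReport:
    def test_noiseless_sessions_perfect(self):
        cohort = cm.sample_cohort(cm.study_cohort_spec(seed=1,
                                                       sizes={"male": 12}))
        err = cm.ErrorSpec(within_sd={}, between_sd={}, n_sessions=2,
                           n_examiners=3)
        report = cm.reliability_report(cm.simulate_sessions(cohort, err))
        assert np.allclose(report["intra"]["icc"], 1.0)
        assert np.allclose(report["intra"]["rms_sd"], 0.0)
        assert np.allclose(report["inter_overall"]["icc"], 1.0)

    def test_parameter_ordering(self):
        cohort = cm.sample_cohort(cm.study_cohort_spec(seed=2,
                                                       sizes={"male": 8}))
        report = cm.reliability_report(
            cm.simulate_sessions(cohort, cm.study_error_spec(seed=3)))
        assert list(report["intra"]["parameter"]) == list(cm.PARAMETERS)
        assert list(report["inter_overall"]["parameter"]) == list(cm.PARAMETERS)

    def test_angles_have_no_cv(self):
        cohort = cm.sample_cohort(cm.study_cohort_spec(seed=4,
                                                       sizes={"male": 8}))
        report = cm.reliability_report(
            cm.simulate_sessions(cohort, cm.study_error_spec(seed=5)))
        intra = report["intra"].set_index("parameter")
        assert intra.loc[list(cm.ANGLE_PARAMETERS), "cv_pct"].isna().all()
        assert intra.loc[list(cm.LENGTH_PARAMETERS), "cv_pct"].notna().all()

    def test_pairwise_covers_all_examiner_pairs(self):
        cohort = cm.sample_cohort(cm.study_cohort_spec(seed=6,
                                                       sizes={"male": 8}))
        report = cm.reliability_report(
            cm.simulate_sessions(cohort, cm.study_error_spec(seed=7)))
        pairs = set(map(tuple, report["inter_pairwise"]
                        [["examiner_a", "examiner_b"]].drop_duplicates()
                        .to_numpy()))
        assert pairs == {(1, 2), (1, 3), (2, 3)}


def _null_cohort(rng, n=90):
    """Parameter depends on height only; sexes differ in height -> the
    height-adjusted sex effect is null."""
    sex = np.r_[["male"] * (n // 2), ["female"] * (n - n // 2)]
    height = np.where(sex == "male", rng.normal(1.74, 0.05, n),
                      rng.normal(1.61, 0.04, n))
    value = 40.0 * height + rng.normal(0, 2.0, n)
    return pd.DataFrame({"sex": sex, "height_m": height, "LAP": value})


class TestAncova:
    def test_null_type_i_error(self):
        rng = np.random.default_rng(8)
        pvals = [cm.ancova_gender(_null_cohort(rng), parameters=["LAP"])
                 ["p"].iloc[0] for _ in range(200)]
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.10

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        pvals = [cm.ancova_gender(_null_cohort(rng), parameters=["LAP"])
                 ["p"].iloc[0] for _ in range(200)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_for_large_adjusted_difference(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(100):
            df = _null_cohort(rng)
            df.loc[df.sex == "male", "LAP"] += 10.0
            p = cm.ancova_gender(df, parameters=["LAP"])["p"].iloc[0]
            hits += p < 0.01
        assert hits >= 99

    def test_adjusted_means_remove_height_effect(self):
        rng = np.random.default_rng(11)
        df = _null_cohort(rng, n=2000)
        res = cm.ancova_gender(df, parameters=["LAP"]).iloc[0]
        # raw male mean exceeds female by ~40*(1.74-1.61)=5.2; adjusted ~0
        raw_gap = (df[df.sex == "male"].LAP.mean() -
                   df[df.sex == "female"].LAP.mean())
        adj_gap = res["adj_mean_male"] - res["adj_mean_female"]
        assert raw_gap > 4.0
        assert abs(adj_gap) < 1.0

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(12)
        df = _null_cohort(rng)
        df["height_m"] = 1.7
        with pytest.warns(UserWarning, match="constant"):
            res = cm.ancova_gender(df, parameters=["LAP"])
        assert res["covariate"].iloc[0] == "none"


class TestDemographicsTTest:
    def test_hand_computed_two_sample(self):
        a = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        b = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
        df = pd.DataFrame({"sex": ["f"] * 5 + ["m"] * 5,
                           "weight": np.r_[a, b]})
        res = cm.demographics_ttest(df, ["weight"])
        sp = math.sqrt(((a.var(ddof=1) * 4) + (b.var(ddof=1) * 4)) / 8)
        t_hand = (a.mean() - b.mean()) / (sp * math.sqrt(2 / 5))
        assert res.t.iloc[0] == pytest.approx(t_hand, rel=1e-12)
        assert res.p.iloc[0] == pytest.approx(
            2 * stats.t.sf(abs(t_hand), 8), rel=1e-12)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"sex": ["f"] * 6 + ["m"] * 6,
                           "age": rng.normal(40, 10, 12)})
        res = cm.demographics_ttest(df, ["age"])
        df2 = df.assign(sex=df.sex.map({"f": "m", "m": "f"}))
        res2 = cm.demographics_ttest(df2, ["age"])
        assert res2.t.iloc[0] == pytest.approx(-res.t.iloc[0], rel=1e-12)
        assert res2.p.iloc[0] == pytest.approx(res.p.iloc[0], rel=1e-12)

    def test_degenerate_identical_groups(self):
        df = pd.DataFrame({"sex": ["f"] * 3 + ["m"] * 3,
                           "age": [40.0] * 6})
        res = cm.demographics_ttest(df, ["age"])
        assert res.degenerate.iloc[0]
        assert res.p.iloc[0] == 1.0 and res.t.iloc[0] == 0.0
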