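"""Synthetic inputs: cohorts, landmark realizations, repeated-measurement
sessions, and voxel phantoms with known ground truth.

The module bundles normative per-gender distribution summaries (mean, SD,
min, max) for the nine parameters of the adult calcaneus, together with
matching demographic summaries and measurement-precision magnitudes, and
generates from them:

* per-subject parameter tables (truncated-normal sampling per gender),
* exact landmark configurations realizing a prescribed parameter vector,
* repeated measurements with within-/between-observer error, and
* CT-like voxel phantoms (sphere unions) whose landmarks, bone volume and
  spherical-cap facet area are known in closed form.

Every sampling operation takes an explicit seed or ``numpy`` Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, GeometryError, InfeasibleParameterError
from .morphometry import FacetBoundary, LandmarkSet
from .params import (ANGLE_PARAMETERS, AREA_PARAMETERS, PARAMETERS,
                     ParameterVector, UNITS)
from .volume import Volume3D

__all__ = [
    "TruncNormSpec", "GroupSpec", "CohortSpec", "ErrorSpec",
    "Sphere", "SphericalCap", "PhantomSpec", "Phantom",
    "NORMATIVE_PARAMS", "NORMATIVE_HEIGHT", "NORMATIVE_DEMOGRAPHICS",
    "REFERENCE_PRECISION", "study_cohort_spec", "study_error_spec",
    "sample_cohort", "realize_landmarks", "simulate_sessions",
    "build_phantom", "calcaneus_phantom_spec", "sphere_phantom_spec",
]


# ---------------------------------------------------------------------------
# distribution specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncNormSpec:
    """Normal(mean, sd) truncated to [min, max]; None bound = unbounded."""

    mean: float
    sd: float
    min: Optional[float] = None
    max: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and math.isfinite(self.sd)):
            raise DataError("mean and sd must be finite")
        if self.sd < 0:
            raise DataError(f"sd must be >= 0, got {self.sd}")
        lo = -math.inf if self.min is None else self.min
        hi = math.inf if self.max is None else self.max
        if not lo < hi:
            raise DataError(f"infeasible truncation bounds: min {lo} >= max {hi}")
        if self.min is not None and not self.min < self.mean:
            raise DataError(f"require min < mean, got min {self.min}, mean {self.mean}")
        if self.max is not None and not self.mean < self.max:
            raise DataError(f"require mean < max, got mean {self.mean}, max {self.max}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF (exact) truncated-normal sampling."""
        if self.sd == 0.0:
            return np.full(n, self.mean)
        a = -np.inf if self.min is None else (self.min - self.mean) / self.sd
        b = np.inf if self.max is None else (self.max - self.mean) / self.sd
        u = rng.random(n)
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class GroupSpec:
    """One gender group: its size and per-parameter distributions."""

    n: int
    params: Mapping[str, TruncNormSpec]
    height: Optional[TruncNormSpec] = None  # metres; used by the ANCOVA layer

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DataError(f"group size must be positive, got {self.n}")
        missing = [p for p in PARAMETERS if p not in self.params]
        if missing:
            raise DataError(f"group spec missing parameters {missing}")


@dataclass(frozen=True)
class CohortSpec:
    """Per-gender group specs plus the sampling seed."""

    groups: Mapping[str, GroupSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise DataError("cohort spec needs at least one group")


@dataclass(frozen=True)
class ErrorSpec:
    """Measurement-error magnitudes for a repeated-measurement design.

    ``within_sd`` is the session-to-session SD of one observer;
    ``between_sd`` the SD of per-(subject, examiner) systematic offsets.
    Both are in each parameter's own units.
    """

    within_sd: Mapping[str, float]
    between_sd: Mapping[str, float]
    n_sessions: int = 2
    n_examiners: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, table in (("within_sd", self.within_sd),
                            ("between_sd", self.between_sd)):
            for p, v in table.items():
                if v < 0:
                    raise DataError(f"{name}[{p}] must be >= 0, got {v}")
        if self.n_sessions < 1 or self.n_examiners < 1:
            raise DataError("need at least one session and one examiner")


# ---------------------------------------------------------------------------
# normative study conditions
# ---------------------------------------------------------------------------

#: Per-gender normative summaries (mean, SD, min, max) of the nine
#: parameters for adult calcanei; lengths mm, angles deg, areas cm².
NORMATIVE_PARAMS: dict[str, dict[str, TruncNormSpec]] = {
    "male": {
        "LCA": TruncNormSpec(80.0, 3.4, 71.3, 85.9),
        "HPF": TruncNormSpec(31.5, 1.8, 28.5, 35.1),
        "LPF": TruncNormSpec(28.6, 2.9, 24.3, 34.5),
        "LAP": TruncNormSpec(21.1, 1.6, 18.5, 24.2),
        "HAP": TruncNormSpec(30.4, 1.8, 27.2, 33.6),
        "GA": TruncNormSpec(127.7, 6.4, 113.0, 144.0),
        "BA": TruncNormSpec(39.6, 2.6, 33.0, 45.0),
        "APF": TruncNormSpec(14.5, 1.0, 11.9, 16.2),
        "AMF": TruncNormSpec(6.1, 0.5, 5.5, 7.4),
    },
    "female": {
        "LCA": TruncNormSpec(69.2, 1.9, 64.2, 74.3),
        "HPF": TruncNormSpec(25.9, 1.1, 23.8, 28.2),
        "LPF": TruncNormSpec(22.4, 1.8, 19.5, 27.2),
        "LAP": TruncNormSpec(20.8, 1.5, 17.5, 23.5),
        "HAP": TruncNormSpec(24.4, 1.7, 22.4, 29.8),
        "GA": TruncNormSpec(123.5, 5.4, 110.0, 135.0),
        "BA": TruncNormSpec(30.7, 3.2, 23.0, 39.0),
        "APF": TruncNormSpec(12.9, 1.0, 11.1, 14.6),
        "AMF": TruncNormSpec(5.2, 0.3, 4.7, 6.5),
    },
}

#: Normative group sizes of the reference cohort (83 male, 96 female).
NORMATIVE_GROUP_SIZES: dict[str, int] = {"male": 83, "female": 96}

#: Body height (m) per gender, for the height-adjusted group comparison.
NORMATIVE_HEIGHT: dict[str, TruncNormSpec] = {
    "male": TruncNormSpec(1.74, 0.05, 1.63, 1.81),
    "female": TruncNormSpec(1.61, 0.04, 1.55, 1.68),
}

#: Additional demographics (age in years, weight in kg) per gender.
NORMATIVE_DEMOGRAPHICS: dict[str, dict[str, TruncNormSpec]] = {
    "male": {
        "age": TruncNormSpec(39.6, 9.8, 22.0, 55.0),
        "weight": TruncNormSpec(75.2, 5.0, 62.5, 92.5),
    },
    "female": {
        "age": TruncNormSpec(41.5, 10.5, 21.0, 59.0),
        "weight": TruncNormSpec(53.5, 4.5, 43.0, 63.5),
    },
}

#: Single-examiner (within-observer) repeat-measurement SDs, per parameter,
#: in the parameter's own units.
REFERENCE_WITHIN_SD: dict[str, float] = {
    "LCA": 0.6, "HPF": 0.4, "LPF": 0.5, "LAP": 0.4, "HAP": 0.4,
    "GA": 1.2, "BA": 1.0, "APF": 0.25, "AMF": 0.19,
}

#: Examiner-pair repeat SDs (first examiner pair); the between-observer
#: offset SD is derived as sqrt(pair² − within²) under the additive model.
_REFERENCE_PAIR_SD: dict[str, float] = {
    "LCA": 1.5, "HPF": 0.5, "LPF": 0.7, "LAP": 0.6, "HAP": 0.6,
    "GA": 2.2, "BA": 1.2, "APF": 0.40, "AMF": 0.24,
}

REFERENCE_BETWEEN_SD: dict[str, float] = {
    p: math.sqrt(max(_REFERENCE_PAIR_SD[p] ** 2 - REFERENCE_WITHIN_SD[p] ** 2, 0.0))
    for p in PARAMETERS
}

#: Both precision tables together, for convenience.
REFERENCE_PRECISION: dict[str, dict[str, float]] = {
    "within": dict(REFERENCE_WITHIN_SD),
    "between": dict(REFERENCE_BETWEEN_SD),
}


def study_cohort_spec(seed: int = 0,
                      sizes: Optional[Mapping[str, int]] = None) -> CohortSpec:
    """The default study cohort: normative distributions, 83 M / 96 F."""
    sizes = dict(NORMATIVE_GROUP_SIZES if sizes is None else sizes)
    groups = {
        sex: GroupSpec(n=sizes[sex], params=NORMATIVE_PARAMS[sex],
                       height=NORMATIVE_HEIGHT[sex])
        for sex in sizes
    }
    return CohortSpec(groups=groups, seed=seed)


def study_error_spec(seed: int = 0, n_sessions: int = 2,
                     n_examiners: int = 3) -> ErrorSpec:
    """The default repeated-measurement error model (reference precision)."""
    return ErrorSpec(within_sd=dict(REFERENCE_WITHIN_SD),
                     between_sd=dict(REFERENCE_BETWEEN_SD),
                     n_sessions=n_sessions, n_examiners=n_examiners, seed=seed)


# ---------------------------------------------------------------------------
# cohort + session simulation
# ---------------------------------------------------------------------------

def sample_cohort(spec: CohortSpec,
                  rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw a cohort table: one row per subject, columns subject_id, sex,
    (height_m when specified), and the nine parameters.

    Parameters are drawn independently per subject from each gender's
    truncated normal. Reproducible for a fixed spec (seeded internally from
    ``spec.seed`` unless an explicit generator is passed).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    frames = []
    offset = 0
    for sex in spec.groups:
        g = spec.groups[sex]
        cols: dict[str, np.ndarray | list] = {
            "subject_id": [f"S{offset + i + 1:04d}" for i in range(g.n)],
            "sex": [sex] * g.n,
        }
        if g.height is not None:
            cols["height_m"] = g.height.sample(g.n, rng)
        for p in PARAMETERS:
            cols[p] = g.params[p].sample(g.n, rng)
        frames.append(pd.DataFrame(cols))
        offset += g.n
    return pd.concat(frames, ignore_index=True)


def simulate_sessions(cohort: pd.DataFrame, err: ErrorSpec,
                      rng: Optional[np.random.Generator] = None
                      ) -> pd.DataFrame:
    """Simulate repeated measurements of every cohort subject.

    For each (subject, examiner) an offset ~ N(0, between_sd) is drawn once
    per parameter; each session then adds independent N(0, within_sd) noise:

        session value = truth + offset(subject, examiner) + noise(session)

    Returns a long table with one row per (subject, examiner, session).
    """
    rng = np.random.default_rng(err.seed) if rng is None else rng
    params = [p for p in PARAMETERS if p in cohort.columns]
    if not params:
        raise DataError("cohort table has no parameter columns")
    n = len(cohort)
    rows = []
    # offsets drawn per (subject, examiner, parameter), shared across sessions
    offsets = {
        p: rng.normal(0.0, err.between_sd.get(p, 0.0), size=(n, err.n_examiners))
        for p in params
    }
    for e in range(err.n_examiners):
        for s in range(err.n_sessions):
            block = pd.DataFrame({
                "subject_id": cohort["subject_id"].to_numpy(),
                "examiner": e + 1,
                "session": s + 1,
            })
            for p in params:
                noise = rng.normal(0.0, err.within_sd.get(p, 0.0), size=n)
                block[p] = cohort[p].to_numpy() + offsets[p][:, e] + noise
            rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    if "sex" in cohort.columns:
        out = out.merge(cohort[["subject_id", "sex"]], on="subject_id", how="left")
    return out


# ---------------------------------------------------------------------------
# landmark realization
# ---------------------------------------------------------------------------

#: Fixed oblique unit direction from C to D ("downwards and slightly
#: anterior-lateral"): the rational unit vector (3, -12, 4)/13.
D_DIRECTION: np.ndarray = np.array([3.0, -12.0, 4.0]) / 13.0


def realize_landmarks(v: ParameterVector) -> LandmarkSet:
    r"""Construct a landmark configuration whose measurement reproduces the
    seven landmark parameters of ``v`` exactly (to floating-point accuracy).

    Construction convention (deterministic, one solution chosen):

    * B at the origin, C at (LAP, 0, 0);
    * A in the z = 0 plane with \|AB\| = LPF and ∠ABC = GA, on the +y side;
    * D = C + HAP · d with the fixed oblique unit vector ``D_DIRECTION``;
    * G = (C + D)/2;
    * E in the z = 0 plane with \|GE\| = LCA and point-to-line distance from
      A to line(G, E) equal to HPF, taking the most posterior (smallest-x)
      of the feasible solutions;
    * F in the z = 0 plane with ∠CAF = 180° − BA and \|AF\| = LCA/2
      (the AF length is a free convention; angles do not depend on it).

    Raises :class:`InfeasibleParameterError` when no such configuration
    exists (e.g. HPF ≥ the realized \|A − G\| distance).
    """
    ga = math.radians(v.GA)
    B = np.zeros(3)
    C = np.array([v.LAP, 0.0, 0.0])
    A = v.LPF * np.array([math.cos(ga), math.sin(ga), 0.0])
    D = C + v.HAP * D_DIRECTION
    G = 0.5 * (C + D)

    w = A - G
    w_norm = float(np.linalg.norm(w))
    if not w_norm > v.HPF:
        raise InfeasibleParameterError(
            f"HPF = {v.HPF:.3f} mm must be strictly less than the realized "
            f"|A−G| = {w_norm:.3f} mm")
    vz = -G[2]  # E lies in the z = 0 plane
    r2 = v.LCA ** 2 - vz ** 2
    if r2 <= 0:
        raise InfeasibleParameterError(
            f"LCA = {v.LCA:.3f} mm too short to reach the z = 0 plane from G")
    r = math.sqrt(r2)
    q = w[:2]
    q2 = float(q @ q)
    if q2 == 0.0:
        raise InfeasibleParameterError("A lies directly above G; axis direction "
                                       "is unconstrained in the z = 0 plane")
    c_mag = v.LCA * math.sqrt(w_norm ** 2 - v.HPF ** 2)
    candidates = []
    for c in (c_mag, -c_mag):
        rhs = c - w[2] * vz
        p0 = q * (rhs / q2)
        h2 = r2 - float(p0 @ p0)
        if h2 < 0:
            continue
        perp = np.array([-q[1], q[0]]) / math.sqrt(q2)
        for sign in (1.0, -1.0):
            vxy = p0 + sign * math.sqrt(h2) * perp
            E = np.array([G[0] + vxy[0], G[1] + vxy[1], 0.0])
            candidates.append(E)
    if not candidates:
        raise InfeasibleParameterError(
            "no axis endpoint E satisfies both |GE| = LCA and the HPF "
            "perpendicular-distance constraint")
    E = min(candidates, key=lambda p: (p[0], p[1]))

    theta = math.radians(180.0 - v.BA)
    ac = (C - A)[:2]
    ac /= np.linalg.norm(ac)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    af = rot @ ac
    F = A + 0.5 * v.LCA * np.array([af[0], af[1], 0.0])

    return LandmarkSet(A=A, B=B, C=C, D=D, E=E, F=F)


# ---------------------------------------------------------------------------
# voxel phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float).reshape(3))
        if not self.radius > 0:
            raise DataError(f"sphere radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class SphericalCap:
    """A cap of height h on one sphere, along a given outward axis.

    Analytic area: 2πRh. The boundary circle lies in the plane at distance
    R − h from the centre along the axis.
    """

    sphere: int          # index into PhantomSpec.spheres
    axis: np.ndarray     # outward unit direction of the cap apex
    height: float        # cap height h, mm

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float).reshape(3)
        nrm = np.linalg.norm(ax)
        if nrm == 0:
            raise DataError("cap axis must be a nonzero vector")
        object.__setattr__(self, "axis", ax / nrm)
        if not self.height > 0:
            raise DataError(f"cap height must be positive, got {self.height}")


@dataclass(frozen=True)
class PhantomSpec:
    """A bone-like solid (union of spheres) embedded in soft tissue."""

    spheres: Sequence[Sphere]
    spacing: float = 0.625
    bone_hu: float = 700.0
    background_hu: float = 0.0
    noise_sd: float = 0.0
    threshold_hu: float = 150.0
    margin: float = 4.0          # empty border around the solid, mm
    cap: Optional[SphericalCap] = None
    landmarks: Optional[LandmarkSet] = None

    def __post_init__(self) -> None:
        if not self.spheres:
            raise DataError("phantom needs at least one sphere")
        if not self.spacing > 0:
            raise DataError("voxel spacing must be positive")
        if not self.background_hu < self.threshold_hu < self.bone_hu:
            raise DataError("require background HU < threshold < bone HU")
        if self.noise_sd < 0:
            raise DataError("noise SD must be >= 0")
        if self.cap is not None:
            R = self.spheres[self.cap.sphere].radius
            if self.cap.height > R:
                raise DataError(f"cap height {self.cap.height} exceeds sphere "
                                f"radius {R}")


@dataclass(frozen=True)
class Phantom:
    """A built phantom: volume plus closed-form ground truth."""

    volume: Volume3D
    landmarks: Optional[LandmarkSet]
    facet_area_mm2: Optional[float]
    facet_boundary: Optional[FacetBoundary]
    bone_volume_mm3: float
    spec: PhantomSpec


def _union_sdf(points: np.ndarray, spheres: Sequence[Sphere]) -> np.ndarray:
    """Signed distance to the sphere union (negative inside)."""
    d = np.full(points.shape[:-1], np.inf)
    for s in spheres:
        d = np.minimum(d, np.linalg.norm(points - s.center, axis=-1) - s.radius)
    return d


def _union_volume_mm3(spheres: Sequence[Sphere], n_grid: int = 0) -> float:
    """Analytic union volume: exact for one sphere or two overlapping
    spheres (lens correction); otherwise inclusion of pairwise overlaps only
    is wrong, so fall back to a fine midpoint grid."""
    if len(spheres) == 1:
        return 4.0 / 3.0 * math.pi * spheres[0].radius ** 3
    if len(spheres) == 2:
        r1, r2 = spheres[0].radius, spheres[1].radius
        d = float(np.linalg.norm(spheres[0].center - spheres[1].center))
        vol = 4.0 / 3.0 * math.pi * (r1 ** 3 + r2 ** 3)
        if d < r1 + r2:  # subtract the lens
            if d <= abs(r1 - r2):
                vol -= 4.0 / 3.0 * math.pi * min(r1, r2) ** 3
            else:
                lens = (math.pi * (r1 + r2 - d) ** 2 *
                        (d ** 2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2) /
                        (12 * d))
                vol -= lens
        return vol
    # numeric fallback at fine resolution
    lo = np.min([s.center - s.radius for s in spheres], axis=0)
    hi = np.max([s.center + s.radius for s in spheres], axis=0)
    n = n_grid or 160
    axes = [np.linspace(lo[i], hi[i], n) for i in range(3)]
    dv = np.prod([(a[1] - a[0]) for a in axes])
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return float(np.count_nonzero(_union_sdf(pts, spheres) <= 0) * dv)


def build_phantom(spec: PhantomSpec,
                  rng: Optional[np.random.Generator] = None) -> Phantom:
    """Voxelize a phantom spec onto a regular grid.

    Voxel values are ``bone_hu`` where the voxel centre lies inside the
    sphere union and ``background_hu`` outside, plus optional Gaussian noise.
    Ground-truth landmarks (validated to lie on the continuous union
    surface) and the analytic cap area 2πRh are carried through.
    """
    spheres = list(spec.spheres)
    lo = np.min([s.center - s.radius for s in spheres], axis=0) - spec.margin
    hi = np.max([s.center + s.radius for s in spheres], axis=0) + spec.margin
    shape = np.ceil((hi - lo) / spec.spacing).astype(int) + 1
    origin = lo
    axes = [origin[i] + np.arange(shape[i]) * spec.spacing for i in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    sdf = _union_sdf(pts, spheres)
    data = np.where(sdf <= 0, spec.bone_hu, spec.background_hu)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    vol = Volume3D(data=data, spacing=np.full(3, spec.spacing), origin=origin)

    if spec.landmarks is not None:
        for name, p in spec.landmarks.as_dict().items():
            d = float(_union_sdf(p[None, :], spheres)[0])
            if abs(d) > 1e-6:
                raise GeometryError(
                    f"ground-truth landmark {name} is {d:.3f} mm off the "
                    "phantom surface")

    cap_area = None
    boundary = None
    if spec.cap is not None:
        sph = spheres[spec.cap.sphere]
        R, h = sph.radius, spec.cap.height
        cap_area = 2.0 * math.pi * R * h
        rc = math.sqrt(max(2 * R * h - h * h, 0.0))
        axis = spec.cap.axis
        # orthonormal frame around the cap axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(float(axis @ ref)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, ref)
        u /= np.linalg.norm(u)
        w = np.cross(axis, u)
        t = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
        ring = (sph.center[None, :] + (R - h) * axis[None, :] +
                rc * (np.cos(t)[:, None] * u[None, :] +
                      np.sin(t)[:, None] * w[None, :]))
        apex = sph.center + R * axis
        label = "posterior"
        boundary = FacetBoundary(points=ring, seed=apex, label=label)
        exposed = _union_sdf(np.vstack([ring, apex[None, :]]), spheres)
        if np.any(np.abs(exposed) > 1e-6):
            raise GeometryError("facet cap is occluded by another phantom sphere")

    bone_mm3 = _union_volume_mm3(spheres)
    return Phantom(volume=vol, landmarks=spec.landmarks, facet_area_mm2=cap_area,
                   facet_boundary=boundary, bone_volume_mm3=bone_mm3, spec=spec)


def sphere_phantom_spec(radius: float = 10.0, spacing: float = 0.5,
                        cap_height: Optional[float] = 2.0,
                        noise_sd: float = 0.0) -> PhantomSpec:
    """A single-sphere phantom, optionally with an apex cap as the 'facet'."""
    cap = None
    if cap_height is not None:
        cap = SphericalCap(sphere=0, axis=np.array([0.0, 0.0, 1.0]),
                           height=cap_height)
    return PhantomSpec(spheres=[Sphere(center=np.zeros(3), radius=radius)],
                       spacing=spacing, cap=cap, noise_sd=noise_sd)


def calcaneus_phantom_spec(v: ParameterVector, spacing: float = 0.625,
                           noise_sd: float = 0.0,
                           arm_radius: float = 5.0) -> PhantomSpec:
    """A calcaneus-like phantom realizing a parameter vector.

    The landmark configuration for ``v`` is realized exactly; the solid is a
    central core sphere at the landmark centroid plus, for each landmark, a
    chain of overlapping "arm" spheres ending in a knob tangent to the
    landmark — so each landmark lies exactly on the union surface. Every
    sphere's radius is capped at its distance to the nearest landmark,
    which prevents one arm from engulfing another arm's landmark. The
    result is a connected, blobby, bone-like solid with exact ground truth.
    """
    lms = realize_landmarks(v)
    pts = np.stack(list(lms.as_dict().values()))
    centroid = pts.mean(axis=0)
    dists = np.linalg.norm(pts - centroid, axis=1)
    rb = arm_radius
    r0 = max(0.6 * dists.min(), rb)
    if dists.min() <= rb:
        raise GeometryError("a landmark lies inside the phantom core; use a "
                            "smaller arm_radius")
    raw: list[tuple[np.ndarray, float]] = [(centroid, r0)]
    for p, d in zip(pts, dists):
        u = (p - centroid) / d
        end = d - rb  # knob centre, tangent to the landmark
        s = r0
        while s < end:
            raw.append((centroid + min(s, end) * u, rb))
            s += 0.8 * rb
        raw.append((centroid + end * u, rb))
    spheres = []
    for c, r in raw:
        cap = float(np.linalg.norm(pts - c, axis=1).min())
        spheres.append(Sphere(center=c, radius=min(r, cap)))
    sdf = _union_sdf(pts, spheres)
    if np.any(np.abs(sdf) > 1e-9):
        raise GeometryError("phantom spheres occlude a ground-truth landmark")
    return PhantomSpec(spheres=spheres, spacing=spacing, noise_sd=noise_sd,
                       landmarks=lms)


# ---------------------------------------------------------------------------
# table IO helpers
# ---------------------------------------------------------------------------

def units_header(extra: str = "") -> str:
    parts = [f"{p}:{UNITS[p]}" for p in PARAMETERS]
    line = "# units " + " ".join(parts)
    if extra:
        line += " " + extra
    return line


def write_table(df: pd.DataFrame, path, seed: Optional[int] = None) -> None:
    """Write a cohort/session table as CSV with a units comment header."""
    extra = f"seed={seed}" if seed is not None else ""
    with open(path, "w") as fh:
        fh.write(units_header(extra) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"cannot parse table {path}: {exc}") from exc
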