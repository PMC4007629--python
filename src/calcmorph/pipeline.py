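"""Orchestration of the simulation → segmentation → measurement → report
stages, shared by the command-line interface and the examples.

Every stage takes a :class:`PipelineConfig`, writes plain-text outputs into
``out_dir`` (CSV/JSON, NIfTI volumes, PLY meshes), records the seed in each
table header, and logs a config hash so a run can be reproduced from its
log alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import DataError, MissingLandmarkError
from .morphometry import measure_all, read_boundaries, read_landmarks
from .params import PARAMETERS, ParameterVector
from .reliability import ancova_gender, reliability_report
from .segmentation import (DEFAULT_THRESHOLD_HU, extract_mesh,
                           label_components, separate_bones, threshold_bone)
from .synthetic import (NORMATIVE_PARAMS, build_phantom, calcaneus_phantom_spec,
                        read_table, sample_cohort, simulate_sessions,
                        study_cohort_spec, study_error_spec, write_table)
from .volume import read_volume, write_labels, write_mesh, write_volume

log = logging.getLogger("calcmorph")

__all__ = ["PipelineConfig", "run_simulate", "run_phantom", "run_segment",
           "run_measure", "run_report", "run_compare"]


@dataclass
class PipelineConfig:
    """Paths and knobs for the pipeline stages; unused fields are ignored
    by stages that do not need them."""

    out_dir: Path = Path("calcmorph_out")
    seed: int = 0
    # simulate
    n_male: int = 83
    n_female: int = 96
    n_sessions: int = 2
    n_examiners: int = 3
    reliability_subjects: int = 36
    # volumes
    volume: Optional[Path] = None
    threshold_hu: float = DEFAULT_THRESHOLD_HU
    spacing_override: Optional[tuple] = None
    seed_file: Optional[Path] = None
    phantom_spacing: float = 0.625
    # measurement
    landmarks: Optional[Path] = None
    landmarks_dir: Optional[Path] = None
    mesh: Optional[Path] = None
    boundaries: Optional[Path] = None
    # reports
    sessions_csv: Optional[Path] = None
    cohort_csv: Optional[Path] = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("volume", "seed_file", "landmarks", "landmarks_dir",
                     "mesh", "boundaries", "sessions_csv", "cohort_csv"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    def digest(self) -> str:
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def log_banner(self, stage: str) -> None:
        log.info("calcmorph %s | stage=%s seed=%d config=%s",
                 __version__, stage, self.seed, self.digest())


def _outdir(config: PipelineConfig) -> Path:
    config.out_dir.mkdir(parents=True, exist_ok=True)
    return config.out_dir


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Sample the default normative cohort and its measurement sessions.

    Writes ``cohort.csv`` (all subjects) and ``sessions.csv`` (repeated
    measurements of the first ``reliability_subjects`` subjects by
    ``n_examiners`` examiners over ``n_sessions`` sessions).
    """
    config.log_banner("simulate")
    out = _outdir(config)
    spec = study_cohort_spec(seed=config.seed,
                             sizes={"male": config.n_male,
                                    "female": config.n_female})
    rng = np.random.default_rng(config.seed)
    cohort = sample_cohort(spec, rng=rng)
    log.info("sampled cohort: %d subjects (%d male, %d female)",
             len(cohort), config.n_male, config.n_female)
    err = study_error_spec(n_sessions=config.n_sessions,
                           n_examiners=config.n_examiners)
    # the reliability subset is drawn at random across both sexes
    n_sub = min(config.reliability_subjects, len(cohort))
    subset = cohort.sample(n=n_sub, random_state=rng).sort_index()
    sessions = simulate_sessions(subset, err, rng=rng)
    paths = {"cohort": out / "cohort.csv", "sessions": out / "sessions.csv"}
    write_table(cohort, paths["cohort"], seed=config.seed)
    write_table(sessions, paths["sessions"], seed=config.seed)
    return paths


def run_phantom(config: PipelineConfig) -> dict[str, Path]:
    """Build the calcaneus-like phantom at the normative male means and
    write its volume, ground-truth landmarks, and truth summary."""
    config.log_banner("phantom")
    out = _outdir(config)
    means = {p: NORMATIVE_PARAMS["male"][p].mean for p in PARAMETERS}
    spec = calcaneus_phantom_spec(ParameterVector(**means),
                                  spacing=config.phantom_spacing)
    phantom = build_phantom(spec, rng=np.random.default_rng(config.seed))
    paths = {
        "volume": out / "phantom.nii.gz",
        "landmarks": out / "phantom_landmarks.csv",
        "truth": out / "phantom_truth.json",
    }
    write_volume(phantom.volume, paths["volume"])
    from .morphometry import write_landmarks

    assert phantom.landmarks is not None
    write_landmarks(phantom.landmarks, paths["landmarks"])
    truth = {"seed": config.seed, "parameters": means,
             "bone_volume_mm3": phantom.bone_volume_mm3,
             "spacing_mm": config.phantom_spacing}
    paths["truth"].write_text(json.dumps(truth, indent=2))
    log.info("phantom voxel grid %s at %.3f mm", phantom.volume.shape,
             config.phantom_spacing)
    return paths


def _read_seed_file(path: Path) -> list[tuple]:
    df = read_table(path)
    need = {"x_mm", "y_mm", "z_mm", "label"}
    if not need.issubset(df.columns):
        raise DataError(f"seed file {path} must have columns {sorted(need)}")
    return [((r.x_mm, r.y_mm, r.z_mm), int(r.label)) for r in df.itertuples()]


def run_segment(config: PipelineConfig) -> dict[str, Path]:
    """Threshold, label (optionally split with seeds), and mesh a volume."""
    config.log_banner("segment")
    if config.volume is None:
        raise DataError("segment stage needs an input volume")
    out = _outdir(config)
    vol = read_volume(config.volume, spacing_override=config.spacing_override)
    mask = threshold_bone(vol, config.threshold_hu)
    if not mask.any():
        raise DataError(f"threshold {config.threshold_hu} HU leaves an empty mask")
    if config.seed_file is not None:
        seeds = _read_seed_file(config.seed_file)
        labels = separate_bones(mask, seeds, spacing=vol.spacing,
                                origin=vol.origin)
    else:
        labels = label_components(mask, spacing=vol.spacing, origin=vol.origin)
    target = 1 if config.seed_file is None else min(
        lbl for _, lbl in _read_seed_file(config.seed_file))
    mesh = extract_mesh(vol, labels, target_label=target)
    paths = {"labels": out / "labels.nii.gz", "mesh": out / "bone.ply"}
    write_labels(labels, paths["labels"])
    write_mesh(mesh, paths["mesh"])
    log.info("labelled %d bones; meshed label %d: %d vertices, %d faces",
             len(labels.counts()), target, len(mesh.vertices), len(mesh.faces))
    return paths


def run_measure(config: PipelineConfig) -> pd.DataFrame:
    """Measure morphological records from landmark files.

    Directory mode: one ``<subject_id>.csv`` per subject in
    ``landmarks_dir``. Single mode: one landmark file, optionally with a
    mesh (PLY/STL) and facet-boundary CSV for the areal parameters. Files
    with missing landmarks are skipped with a warning; unparseable files
    abort the run.
    """
    config.log_banner("measure")
    out = _outdir(config)
    jobs: list[tuple[str, Path]] = []
    if config.landmarks_dir is not None:
        for f in sorted(Path(config.landmarks_dir).glob("*.csv")):
            jobs.append((f.stem, f))
    elif config.landmarks is not None:
        jobs.append((Path(config.landmarks).stem, Path(config.landmarks)))
    else:
        raise DataError("measure stage needs --landmarks or --landmarks-dir")

    mesh = None
    boundaries = None
    if config.mesh is not None:
        import trimesh

        mesh = trimesh.load(str(config.mesh), process=True)
    if config.boundaries is not None:
        boundaries = read_boundaries(config.boundaries)

    rows, skipped = [], 0
    for subject, path in jobs:
        try:
            lms = read_landmarks(path)
        except MissingLandmarkError as exc:
            log.warning("skipping %s: %s", subject, exc)
            skipped += 1
            continue
        rec = measure_all(lms, mesh=mesh, boundaries=boundaries)
        rows.append({"subject_id": subject, **rec.as_dict()})
    log.info("measured %d subjects (%d skipped)", len(rows), skipped)
    df = pd.DataFrame(rows, columns=["subject_id", *PARAMETERS])
    write_table(df, out / "records.csv", seed=config.seed)
    return df


def run_report(config: PipelineConfig) -> dict[str, Path]:
    """Reliability report (ICC, RMS-SD, CV) from a session table."""
    config.log_banner("reliability")
    if config.sessions_csv is None:
        raise DataError("reliability stage needs --sessions CSV")
    out = _outdir(config)
    sessions = read_table(config.sessions_csv)
    if sessions["examiner"].nunique() < 2:
        raise DataError("inter-observer reliability needs at least two "
                        "examiners in the session table")
    report = reliability_report(sessions)
    paths = {}
    for name, df in report.items():
        paths[name] = out / f"reliability_{name}.csv"
        write_table(df, paths[name], seed=config.seed)
    blob = {name: df.to_dict(orient="records") for name, df in report.items()}
    paths["json"] = out / "reliability.json"
    paths["json"].write_text(json.dumps({"seed": config.seed, **blob}, indent=2,
                                        default=float))
    return paths


def run_compare(config: PipelineConfig) -> dict[str, Path]:
    """Height-adjusted gender comparison (ANCOVA) from a cohort table."""
    config.log_banner("compare")
    if config.cohort_csv is None:
        raise DataError("compare stage needs --cohort CSV")
    out = _outdir(config)
    cohort = read_table(config.cohort_csv)
    result = ancova_gender(cohort)
    paths = {"csv": out / "gender_comparison.csv",
             "json": out / "gender_comparison.json"}
    write_table(result, paths["csv"], seed=config.seed)
    paths["json"].write_text(json.dumps(
        {"seed": config.seed, "rows": result.to_dict(orient="records")},
        indent=2, default=float))
    return paths
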