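"""End-to-end orchestration: simulate -> preprocess -> segment -> extract -> grade.

Every stage materializes its artifacts on disk (NIfTI volumes, CSV
tables, JSON results) so each can be inspected and re-run in isolation.
A subject that fails one stage is excluded downstream and accounted for
in the run report; nothing is dropped silently.  A single global seed
deterministically derives all per-stage seeds.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imgio import (
    read_nifti,
    write_nifti,
    window_normalize,
    equalize_histogram,
    extract_slices,
    LABEL_BACKGROUND,
)
from .phantom import PhantomParams, simulate_cohort
from .segmentation import threshold_segment, default_thresholds, multiclass_dice, DiceReport
from .features import extract_ventricle, compute_features
from .grading import REGIONS, HyperSearchSpec, binarize_vrs, evaluate_cv, FEATURE_NAMES

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_config"]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["subject_id", *FEATURE_NAMES, "reference_slice_index", "butterfly_slice_index"]


@dataclass
class RunConfig:
    """All pipeline parameters; serializes losslessly to/from YAML."""

    out_dir: str = "ctatrophy_run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "preprocess", "segment", "extract", "grade")
    # simulate
    n_subjects: int = 30
    rating_noise: float = 0.05
    grid_shape: tuple[int, int, int] = (24, 48, 48)
    noise_sd: float = 2.0
    # preprocess
    window_lo: float = 0.0
    window_hi: float = 80.0
    n_bins: int = 256
    min_brain_fraction: float = 0.01
    # segment (threshold fallback; thresholds in HU on the raw volume)
    tissue_means: dict = field(default_factory=lambda: {"CSF": 8.0, "GM": 38.0, "WM": 28.0})
    # extract
    max_ventricle_components: int = 2
    # grade
    n_hyper_draws: int = 50
    cv_folds: int = 3
    # provenance only: upstream registration/skull-strip settings of the
    # source protocol (not executed here; volumes arrive registered+masked)
    upstream: dict = field(default_factory=lambda: {
        "registration": "rigid 6-dof, spline interpolation",
        "skull_strip_fractional_intensity": 0.01,
    })

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)


def validate_config(config: RunConfig) -> list[str]:
    """Name every out-of-range or inconsistent parameter; [] means valid."""
    findings = []
    if config.n_subjects < 1:
        findings.append("n_subjects must be >= 1")
    if not 0.0 <= config.rating_noise <= 0.5:
        findings.append(f"rating_noise={config.rating_noise} outside [0, 0.5]")
    if any(d < 16 for d in config.grid_shape):
        findings.append(f"grid_shape={config.grid_shape}: each component must be >= 16")
    if not config.window_lo < config.window_hi:
        findings.append(
            f"degenerate intensity window: window_lo={config.window_lo} "
            f">= window_hi={config.window_hi}"
        )
    if config.n_bins < 2:
        findings.append("n_bins must be >= 2")
    if not 0.0 <= config.min_brain_fraction <= 1.0:
        findings.append(f"min_brain_fraction={config.min_brain_fraction} outside [0, 1]")
    if config.cv_folds < 2:
        findings.append(f"cv_folds={config.cv_folds}: cross-validation needs >= 2 folds")
    if config.n_hyper_draws < 1:
        findings.append("n_hyper_draws must be >= 1")
    tm = config.tissue_means
    if set(tm) != {"CSF", "GM", "WM"} or not tm["CSF"] < tm["WM"] < tm["GM"]:
        findings.append(f"tissue_means must satisfy CSF < WM < GM, got {tm}")
    unknown = set(config.stages) - {"simulate", "preprocess", "segment", "extract", "grade"}
    if unknown:
        findings.append(f"unknown stages: {sorted(unknown)}")
    return findings


@dataclass
class RunReport:
    """Per-stage accounting plus results; every subject is processed,
    skipped (with reason), or failed at each stage it enters."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    warnings_log: list = field(default_factory=list)
    dice_report: dict | None = None
    grader_results: dict = field(default_factory=dict)

    def record_stage(self, name: str, n_in: int, processed: int, skipped: int,
                     failed: int, seconds: float, detail: dict | None = None) -> None:
        assert processed + skipped + failed == n_in, "subject accounting violated"
        self.stages[name] = {
            "n_in": n_in, "processed": processed, "skipped": skipped,
            "failed": failed, "seconds": round(seconds, 3), **(detail or {}),
        }

    def write(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))
        return Path(path)


def _derived_seed(seed: int, stage: str) -> int:
    # crc32 is a stable string hash (Python's hash() is salted per process)
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


def _subject_ids(dir_: Path, suffix: str) -> list[str]:
    return sorted(p.name[: -len(suffix)] for p in dir_.glob(f"*{suffix}"))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order and write a consolidated report."""
    findings = validate_config(config)
    if findings:
        raise ValueError("invalid config: " + "; ".join(findings))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    config.to_yaml(out / "config.yaml")

    order = [s for s in ("simulate", "preprocess", "segment", "extract", "grade")
             if s in config.stages]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage in order:
            t0 = time.perf_counter()
            _STAGE_FNS[stage](config, out, report)
            report.stages[stage]["seconds"] = round(time.perf_counter() - t0, 3)
        report.warnings_log = [f"{w.category.__name__}: {w.message}" for w in caught]
    report.write(out / "report.json")
    return report


def _stage_simulate(config: RunConfig, out: Path, report: RunReport) -> None:
    t0 = time.perf_counter()
    base = PhantomParams(grid_shape=config.grid_shape, noise_sd=config.noise_sd,
                         tissue_means=dict(config.tissue_means))
    cohort = simulate_cohort(
        config.n_subjects, rating_noise=config.rating_noise,
        seed=_derived_seed(config.seed, "simulate"), base_params=base,
    )
    vol_dir = out / "volumes"
    vol_dir.mkdir(exist_ok=True)
    rows = []
    for subj in cohort:
        write_nifti(subj.ct, vol_dir / f"{subj.subject_id}_ct.nii.gz")
        write_nifti(subj.labels, vol_dir / f"{subj.subject_id}_truth.nii.gz")
        for rec in subj.ratings:
            rows.append({
                "subject_id": rec.subject_id, "region": rec.region,
                "vrs_score": rec.vrs_score,
                "true_severity": subj.true_severity[rec.region],
            })
    pd.DataFrame(rows).to_csv(out / "ratings.csv", index=False, float_format="%.8g")
    report.record_stage("simulate", config.n_subjects, config.n_subjects, 0, 0,
                        time.perf_counter() - t0)


def _stage_preprocess(config: RunConfig, out: Path, report: RunReport) -> None:
    t0 = time.perf_counter()
    vol_dir = out / "volumes"
    pre_dir = out / "preproc"
    pre_dir.mkdir(exist_ok=True)
    ids = _subject_ids(vol_dir, "_ct.nii.gz")
    if not ids:
        raise FileNotFoundError(f"preprocess: no *_ct.nii.gz volumes under {vol_dir}")
    processed = failed = 0
    for sid in ids:
        try:
            ct = read_nifti(vol_dir / f"{sid}_ct.nii.gz")
            truth = read_nifti(vol_dir / f"{sid}_truth.nii.gz", label=True)
            mask = truth.data != LABEL_BACKGROUND
            vol = window_normalize(ct, config.window_lo, config.window_hi)
            vol = equalize_histogram(vol, mask, n_bins=config.n_bins)
            extract_slices(vol, mask, config.min_brain_fraction)  # validates visibility
            write_nifti(vol, pre_dir / f"{sid}_pre.nii.gz")
            processed += 1
        except Exception as exc:
            logger.error("preprocess failed for %s: %s", sid, exc)
            failed += 1
    report.record_stage("preprocess", len(ids), processed, 0, failed,
                        time.perf_counter() - t0)


def _stage_segment(config: RunConfig, out: Path, report: RunReport) -> None:
    t0 = time.perf_counter()
    vol_dir = out / "volumes"
    seg_dir = out / "seglabels"
    seg_dir.mkdir(exist_ok=True)
    ids = _subject_ids(vol_dir, "_ct.nii.gz")
    if not ids:
        raise FileNotFoundError(f"segment: no *_ct.nii.gz volumes under {vol_dir}")
    thresholds = default_thresholds(config.tissue_means)
    processed = failed = 0
    dsc = {}
    for sid in ids:
        try:
            ct = read_nifti(vol_dir / f"{sid}_ct.nii.gz")
            truth = read_nifti(vol_dir / f"{sid}_truth.nii.gz", label=True)
            mask = truth.data != LABEL_BACKGROUND
            pred = threshold_segment(ct, mask, thresholds)
            write_nifti(pred, seg_dir / f"{sid}_seg.nii.gz")
            _, dsc[sid] = multiclass_dice(pred, truth)
            processed += 1
        except Exception as exc:
            logger.error("segment failed for %s: %s", sid, exc)
            failed += 1
    if dsc:
        rep = DiceReport(dsc)
        report.dice_report = {"mean": rep.mean, "sd": rep.sd, "n": len(dsc)}
        pd.DataFrame(
            {"subject_id": list(dsc), "dsc": list(dsc.values())}
        ).to_csv(out / "dice.csv", index=False, float_format="%.8g")
    report.record_stage("segment", len(ids), processed, 0, failed,
                        time.perf_counter() - t0)


def _stage_extract(config: RunConfig, out: Path, report: RunReport) -> None:
    t0 = time.perf_counter()
    seg_dir = out / "seglabels"
    vol_dir = out / "volumes"
    ids = _subject_ids(seg_dir, "_seg.nii.gz")
    if not ids:
        raise FileNotFoundError(f"extract: no *_seg.nii.gz volumes under {seg_dir}")
    rows = []
    processed = failed = 0
    for sid in ids:
        try:
            labels = read_nifti(seg_dir / f"{sid}_seg.nii.gz", label=True)
            truth = read_nifti(vol_dir / f"{sid}_truth.nii.gz", label=True)
            mask = truth.data != LABEL_BACKGROUND
            ven = extract_ventricle(labels, mask, max_components=config.max_ventricle_components)
            fv = compute_features(labels, mask, ven)
            rows.append({
                "subject_id": sid,
                **{name: getattr(fv, name) for name in FEATURE_NAMES},
                "reference_slice_index": fv.reference_slice_index,
                "butterfly_slice_index": fv.butterfly_slice_index,
            })
            processed += 1
        except Exception as exc:
            logger.error("extract failed for %s: %s", sid, exc)
            failed += 1
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(
        out / "features.csv", index=False, float_format="%.10g"
    )
    report.record_stage("extract", len(ids), processed, 0, failed,
                        time.perf_counter() - t0)


def _stage_grade(config: RunConfig, out: Path, report: RunReport) -> None:
    t0 = time.perf_counter()
    features = pd.read_csv(out / "features.csv")
    ratings = pd.read_csv(out / "ratings.csv")
    grade_dir = out / "grading"
    grade_dir.mkdir(exist_ok=True)
    spec = HyperSearchSpec(
        n_draws=config.n_hyper_draws, cv_folds=config.cv_folds,
        seed=_derived_seed(config.seed, "grade"),
    )
    n_in = len(REGIONS)
    processed = failed = 0
    for region in REGIONS:
        try:
            result = grade_region(features, ratings, region, spec)
            (grade_dir / f"{region}.json").write_text(
                json.dumps(result.to_dict(), indent=2, sort_keys=True)
            )
            pd.DataFrame(result.roc_points, columns=["fpr", "tpr", "threshold"]).to_csv(
                grade_dir / f"{region}_roc.csv", index=False, float_format="%.10g"
            )
            report.grader_results[region] = {
                "auc": result.auc, "sens": result.sens, "spec": result.spec,
                "acc": result.acc, "youden_j": result.youden_j,
            }
            processed += 1
        except Exception as exc:
            logger.error("grading failed for %s: %s", region, exc)
            failed += 1
    report.record_stage("grade", n_in, processed, 0, failed, time.perf_counter() - t0)


def grade_region(features: pd.DataFrame, ratings: pd.DataFrame, region: str,
                 spec: HyperSearchSpec):
    """Join the feature and rating tables for one region and grade it."""
    reg = ratings[ratings["region"] == region]
    merged = features.merge(reg, on="subject_id", how="inner", validate="1:1")
    if merged.empty:
        raise ValueError(f"no subjects with both features and {region} ratings")
    X = merged[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = np.array([binarize_vrs(s, region) for s in merged["vrs_score"]])
    return evaluate_cv(X, y, spec, region=region)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "segment": _stage_segment,
    "extract": _stage_extract,
    "grade": _stage_grade,
}
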