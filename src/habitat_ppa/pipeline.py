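"""End-to-end orchestration: segment -> spatial map -> features -> statistics.

Runs per patient with quarantine-not-abort failure handling, persists all
intermediates, and records every tunable decision in a machine-readable
manifest. Inputs are single-slice 2D images (NIfTI-1 single-slice volumes
or delimited text arrays) plus a clinical CSV with columns
patient_id, os_months, event, os_class, subtype, age_years, sex.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import evaluate_binary, subtype_one_vs_rest
from .features import FEATURE_NAMES, RGrid, extract_features
from .segmentation import assign_habitats
from .spatial_map import build_point_pattern, make_grid
from .survival import demographics_table, feature_screen
from .synthetic import TumorSlicePair

log = logging.getLogger("habitat_ppa")

CLINICAL_COLUMNS = ["patient_id", "os_months", "event", "os_class",
                    "subtype", "age_years", "sex"]


@dataclass
class PipelineConfig:
    input_dir: str | None = None
    output_dir: str = "habitat_ppa_run"
    box_size: int = 8
    n_radii: int = 50
    r_min_frac: float = 0.01    # radii span [w*r_min_frac, w*r_max_frac]
    r_max_frac: float = 0.25
    n_test: int = 1024
    bandwidth: float | None = None   # None -> 2 * box_size
    positive_class: str = "le12"
    cutoff_method: str = "roc"
    folds: int = 3
    top_k: int = 5
    seed: int = 0
    missing_policy: str = "complete-case"


def load_array(path) -> np.ndarray:
    """Read a 2D array from NIfTI (single-slice volume) or delimited text."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib
        data = np.asanyarray(nib.load(path).dataobj)
    else:
        data = np.loadtxt(path, delimiter=",")
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single 2D slice, got shape {data.shape} "
            "(multi-slice volumes are not supported)")
    return data


def validate_inputs(input_dir) -> list[str]:
    """Schema and consistency report for a cohort directory; empty = clean."""
    problems: list[str] = []
    d = Path(input_dir)
    clin_path = d / "clinical.csv"
    if not clin_path.exists():
        return [f"missing clinical table: {clin_path}"]
    clinical = pd.read_csv(clin_path)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing_cols:
        problems.append(f"clinical.csv missing columns: {missing_cols}")
        return problems
    bad_class = clinical[
        (clinical.os_months <= 12) != (clinical.os_class == "le12")]
    for pid in bad_class.patient_id:
        problems.append(f"{pid}: os_class inconsistent with os_months")
    for pid in clinical.patient_id:
        paths = {k: d / f"{pid}_{k}.nii.gz" for k in ("t1", "t2", "mask")}
        absent = [k for k, p in paths.items() if not p.exists()]
        if absent:
            problems.append(f"{pid}: missing image files {absent}")
            continue
        try:
            arrs = {k: load_array(p) for k, p in paths.items()}
        except ValueError as exc:
            problems.append(f"{pid}: {exc}")
            continue
        shapes = {k: a.shape for k, a in arrs.items()}
        if len(set(shapes.values())) != 1:
            problems.append(f"{pid}: shape mismatch {shapes}")
        elif not arrs["mask"].astype(bool).any():
            problems.append(f"{pid}: empty ROI mask")
    return problems


def analyze_patient(pair: TumorSlicePair, config: PipelineConfig | None = None):
    """Segment one patient, build the point pattern and extract 27 features."""
    config = config or PipelineConfig()
    habitats = assign_habitats(pair, seed=config.seed)
    grid = make_grid(pair.mask, box_size=config.box_size)
    pattern = build_point_pattern(habitats, grid)
    w = min(pattern.window_sides)
    rgrid = RGrid(np.linspace(w * config.r_min_frac, w * config.r_max_frac,
                              config.n_radii))
    bandwidth = config.bandwidth or 2.0 * config.box_size
    fv = extract_features(pattern, rgrid=rgrid, n_test=config.n_test,
                          bandwidth=bandwidth)
    return fv, pattern, habitats


def cohort_features(pairs, patient_ids, config: PipelineConfig | None = None):
    """Feature table for a cohort; failures quarantined, not fatal."""
    config = config or PipelineConfig()
    rows, quarantine = {}, {}
    for pid, pair in zip(patient_ids, pairs):
        try:
            fv, _, _ = analyze_patient(pair, config)
            rows[pid] = fv.values
        except Exception as exc:  # per-patient quarantine
            log.warning("patient %s quarantined: %s", pid, exc)
            quarantine[pid] = str(exc)
    features = pd.DataFrame(rows).T
    features.index.name = "patient_id"
    if len(features):
        features = features[list(FEATURE_NAMES)]
    return features, quarantine


def analyze_cohort(pairs, clinical: pd.DataFrame,
                   config: PipelineConfig | None = None) -> dict:
    """Full in-memory analysis: features, survival screen, classification."""
    config = config or PipelineConfig()
    features, quarantine = cohort_features(pairs, clinical.patient_id, config)
    if len(features) < 2:
        raise RuntimeError(
            f"fewer than 2 patients succeeded ({len(features)}); "
            f"quarantined: {quarantine}")
    clin = clinical.set_index("patient_id").loc[features.index]
    screen = feature_screen(features, clin.os_months, clin.event,
                            clin.os_class, positive_class=config.positive_class,
                            cutoff_method=config.cutoff_method)
    labels = (clin.os_class == config.positive_class).astype(int).to_numpy()
    result = {"features": features, "screen": screen,
              "demographics": demographics_table(clin.reset_index()),
              "quarantine": quarantine, "os12_report": None,
              "subtype_reports": None}
    try:
        result["os12_report"] = evaluate_binary(
            features, labels, task="os12", k=config.top_k,
            folds=config.folds, seed=config.seed)
    except ValueError as exc:
        log.warning("12-month classification skipped: %s", exc)
    try:
        result["subtype_reports"] = subtype_one_vs_rest(
            features, clin.subtype.to_numpy(), folds=config.folds,
            seed=config.seed, k=config.top_k)
    except ValueError as exc:
        log.warning("subtype classification skipped: %s", exc)
    return result


def _report_json(report) -> dict | None:
    if report is None:
        return None
    return {"task": report.task, "selected_features": report.selected_features,
            "cutoff": report.cutoff, "auc": report.auc, "tpr": report.tpr,
            "tnr": report.tnr, "acc": report.acc,
            "counts": asdict(report.counts), "notes": report.notes}


def run_pipeline(config: PipelineConfig) -> Path:
    """Disk-to-disk run over a cohort directory; returns the run directory.

    Exit contract: raises if the inputs are invalid or fewer than 2
    patients survive quarantine; otherwise all outputs and a manifest are
    written to ``config.output_dir``.
    """
    if config.input_dir is None:
        raise ValueError("config.input_dir is required")
    problems = validate_inputs(config.input_dir)
    fatal = [p for p in problems if "clinical" in p]
    if fatal:
        raise RuntimeError("; ".join(fatal))

    d = Path(config.input_dir)
    clinical = pd.read_csv(d / "clinical.csv")
    pairs, ids = [], []
    quarantine = {}
    for pid in clinical.patient_id:
        try:
            t1 = load_array(d / f"{pid}_t1.nii.gz")
            t2 = load_array(d / f"{pid}_t2.nii.gz")
            mask = load_array(d / f"{pid}_mask.nii.gz").astype(bool)
            pair = TumorSlicePair(t1=t1, t2=t2, mask=mask)
            pair.validate()
            pairs.append(pair)
            ids.append(pid)
        except Exception as exc:
            quarantine[pid] = str(exc)
            log.warning("patient %s quarantined at load: %s", pid, exc)

    result = analyze_cohort(pairs,
                            clinical[clinical.patient_id.isin(ids)],
                            config)
    result["quarantine"].update(quarantine)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["features"].to_csv(out / "features.csv")
    result["screen"].to_csv(out / "screen.csv", index=False)
    result["demographics"].to_csv(out / "demographics.csv", index=False)
    reports = {"os12": _report_json(result["os12_report"])}
    if result["subtype_reports"]:
        reports["subtype"] = {s: _report_json(r)
                              for s, r in result["subtype_reports"].items()}
    (out / "classification.json").write_text(json.dumps(reports, indent=1))
    manifest = {"version": __version__, "config": asdict(config),
                "n_patients": int(len(result["features"])),
                "quarantine": result["quarantine"],
                "validation": problems,
                "decisions": {
                    "tie_rule": "intensity == threshold -> low habitat",
                    "neighbor_relation": "closed r-ball, 0 < d <= r",
                    "edge_correction": "none (uncorrected estimators)",
                    "simpson_form": "Gini-Simpson 1 - sum(p^2)",
                    "cutpoint_substitution":
                        "two-group log-rank on the ROC-dichotomized split",
                    "classifier_substitution": "L2 logistic regression",
                }}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
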