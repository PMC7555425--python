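"""End-to-end orchestration: each stage reads and writes file artifacts.

The stages mirror the QC workflow: simulate a phantom dataset, calibrate
the metric-score maps on a synthetic second-observer cohort, compute
reference quality scores (rQS), extract radiomics features, train the
LASSO, predict estimated quality scores (eQS) and evaluate agreement.
Per-case failures are quarantined (recorded in the output table) rather
than aborting a batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import metrics as sm
from . import model as qm
from . import phantom as ph
from . import scoring as sc
from .imaging import PreprocessConfig, preprocess, read_mask, read_volume, write_mask, write_volume
from .radiomics import ExtractionSettings, extract_case

log = logging.getLogger("segqc")

__all__ = [
    "RunConfig",
    "run_simulate",
    "run_calibrate",
    "run_rqs",
    "run_extract",
    "run_train",
    "run_predict",
    "run_evaluate",
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; the defaults are the system's reference settings
    (bin width 64, 5 CV folds, observer anchor 85)."""

    seed: int = 0
    n_patients: int = 20
    n_cohort: int = 50
    observer_jitter: float = 1.0
    anchor: float = 85.0
    bin_width: float = 64.0
    folds: int = 5
    bias_tolerance: float = 1.0
    normalization: str = "none"
    bias_correction: bool = False
    phantom: ph.PhantomSpec = field(default_factory=ph.PhantomSpec)
    methods: tuple[str, ...] = tuple(ph.METHOD_RECIPES)


def _manifest_path(data_dir) -> Path:
    return Path(data_dir) / "manifest.csv"


def run_simulate(out_dir, config: RunConfig) -> pd.DataFrame:
    """Write a phantom dataset: images, gold masks, simulated automated
    masks from each "method" recipe, and the manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    rows = []
    for p, child in enumerate(root.spawn(config.n_patients)):
        rng = np.random.default_rng(child)
        pid = f"P{p:03d}"
        dataset = "siteA" if p % 2 == 0 else "siteB"
        spec = ph._case_spec(config.phantom, rng, int(rng.integers(0, 2**31)))
        image, gold = ph.generate_phantom(spec)
        write_volume(image, out / f"{pid}_image.nii.gz")
        write_mask(gold, out / f"{pid}_gold.nii.gz")
        observer = ph.perturb_mask(
            gold,
            ph.PerturbationSpec(
                "boundary_jitter", config.observer_jitter, int(rng.integers(0, 2**31))
            ),
        )
        write_mask(observer, out / f"{pid}_observer.nii.gz")
        for method in config.methods:
            mseed = int(rng.integers(0, 2**31))
            auto, applied = ph.simulate_method_masks(gold, method, mseed)
            auto_path = out / f"{pid}_{method}_auto.nii.gz"
            write_mask(auto, auto_path)
            rows.append(
                {
                    "case_id": f"{pid}-{method}",
                    "patient_id": pid,
                    "dataset": dataset,
                    "method": method,
                    "perturbations": ";".join(
                        f"{s.kind}:{s.magnitude:g}" for s in applied
                    ),
                    "seed": mseed,
                    "image": f"{pid}_image.nii.gz",
                    "gold": f"{pid}_gold.nii.gz",
                    "observer": f"{pid}_observer.nii.gz",
                    "auto": auto_path.name,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(_manifest_path(out), index=False)
    return manifest


def run_calibrate(out_path, config: RunConfig) -> sc.ScoreCalibration:
    """Fit the 12 metric-score maps on a synthetic second-observer cohort."""
    cases = ph.generate_observer_cohort(
        config.n_cohort,
        config.phantom,
        ph.PerturbationSpec("boundary_jitter", config.observer_jitter),
        seed=config.seed + 1,
    )
    panels = [sm.metric_panel(c.observer, c.gold) for c in cases]
    calib = sc.fit_calibration(panels, anchor=config.anchor)
    calib.to_json(str(out_path))
    return calib


def run_rqs(data_dir, calibration_path, out_csv) -> pd.DataFrame:
    """Compute the 12 metrics and the composite rQS for every manifest case."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(_manifest_path(data_dir))
    calib = sc.ScoreCalibration.from_json(str(calibration_path))
    rows = []
    for _, rec in manifest.iterrows():
        row = {"case_id": rec.case_id, "patient_id": rec.patient_id}
        try:
            vol = read_volume(str(data_dir / rec.image))
            gold = read_mask(str(data_dir / rec.gold), vol)
            auto = read_mask(str(data_dir / rec.auto), vol)
            panel = sm.metric_panel(auto, gold)
            score = sc.score_panel(panel, calib)
            row.update(panel.as_series().to_dict())
            row["rqs"] = score.value
            row["error"] = ""
        except Exception as exc:  # quarantine the case, keep the batch going
            log.warning("rQS failed for %s: %s", rec.case_id, exc)
            row["rqs"] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df


def run_extract(data_dir, out_csv, config: RunConfig) -> pd.DataFrame:
    """Extract the 321-feature vector for every manifest case."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(_manifest_path(data_dir))
    settings = ExtractionSettings(bin_width=config.bin_width)
    pp = PreprocessConfig(
        bias_correction=config.bias_correction, normalization=config.normalization
    )
    rows = []
    for _, rec in manifest.iterrows():
        row = {"case_id": rec.case_id, "patient_id": rec.patient_id}
        try:
            vol = read_volume(str(data_dir / rec.image))
            auto = read_mask(str(data_dir / rec.auto), vol)
            vol = preprocess(vol, pp, region=auto)
            fv = extract_case(vol, auto, settings)
            row.update(fv.values)
            row["fingerprint"] = fv.fingerprint
            row["error"] = ""
        except Exception as exc:
            log.warning("extraction failed for %s: %s", rec.case_id, exc)
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df


def _join_features_scores(features_csv, scores_csv):
    feats = pd.read_csv(features_csv)
    scores = pd.read_csv(scores_csv)[["case_id", "rqs"]]
    merged = feats.merge(scores, on="case_id", how="inner")
    merged = merged[(merged.get("error", "").fillna("") == "") & merged.rqs.notna()]
    feature_cols = [c for c in merged.columns if c.count("_") >= 2 and c not in ("case_id",)]
    from .radiomics import FEATURE_NAMES

    feature_cols = [c for c in FEATURE_NAMES if c in merged.columns]
    return merged, feature_cols


def run_train(
    features_csv, scores_csv, out_model, config: RunConfig, out_folds=None
) -> qm.QualityRegressionResults:
    """Train the LASSO on (features, rQS) with patient-level CV."""
    merged, feature_cols = _join_features_scores(features_csv, scores_csv)
    reg = qm.QualityRegression(
        merged[feature_cols],
        merged["rqs"],
        patient_ids=list(merged["patient_id"]),
    )
    res = reg.fit(
        cv=config.folds, seed=config.seed, bias_tolerance=config.bias_tolerance
    )
    res.qc_model.to_json(str(out_model))
    if out_folds and res.search is not None:
        pd.DataFrame(
            sorted(res.search.fold_assignment.items()),
            columns=["patient_id", "fold"],
        ).to_csv(out_folds, index=False)
    return res


def run_predict(features_csv, model_path, out_csv) -> pd.DataFrame:
    """Apply a trained model; writes per-case eQS (clamped to [0, 100])."""
    model = qm.QCModel.from_json(str(model_path))
    feats = pd.read_csv(features_csv)
    ok = feats.get("error", "").fillna("") == ""
    usable = feats[ok]
    preds = qm.predict(model, usable[list(model.feature_names)])
    out = pd.DataFrame({"case_id": feats["case_id"], "eqs": np.nan})
    out.loc[ok.to_numpy(), "eqs"] = preds
    out.to_csv(out_csv, index=False)
    return out


def run_evaluate(pred_csv, scores_csv, out_json, manifest_csv=None, out_cases=None):
    """Agreement report (pooled and per dataset x method subgroup)."""
    preds = pd.read_csv(pred_csv)
    scores = pd.read_csv(scores_csv)[["case_id", "rqs"]]
    table = preds.merge(scores, on="case_id").dropna(subset=["eqs", "rqs"])
    if manifest_csv is not None:
        labels = pd.read_csv(manifest_csv)[["case_id", "dataset", "method"]]
        table = table.merge(labels, on="case_id", how="left")
    pooled = ev.evaluate(table.eqs, table.rqs, list(table.case_id))
    payload = {"pooled": _report_dict(pooled)}
    if "dataset" in table and "method" in table:
        groups = ev.subgroup_report(table)
        for key, rep in groups.items():
            if key == "pooled":
                continue
            payload["-".join(map(str, key))] = _report_dict(rep)
    with open(out_json, "w") as fh:
        json.dump(payload, fh, indent=2)
    if out_cases:
        table = table.assign(
            difference=table.eqs - table.rqs,
            outlier=table.case_id.isin(pooled.outlier_ids),
        )
        table.to_csv(out_cases, index=False)
    return pooled


def _report_dict(rep: ev.EvaluationReport) -> dict:
    from dataclasses import asdict

    d = asdict(rep)
    d["outlier_ids"] = list(d["outlier_ids"])
    return d
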