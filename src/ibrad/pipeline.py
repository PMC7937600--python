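"""End-to-end orchestration: extract -> screen/select -> cross-validate.

Each stage consumes and produces files only (manifest CSV in, feature CSV,
univariate CSV, model JSON, CV/ROC CSVs out), so stages can be run and
tested independently; the in-memory variants (``extract_patients``,
``select_model``) back both the CLI and the desk-scale studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_stats import FeatureTable, UnivariateResult, screen_cohort, zscore
from .features import FeatureConfig, extract_all, realised_feature_count
from .imaging import load_mask, load_volume, resample_inplane
from .model_selection import (
    CVResult,
    ModelSpec,
    aic_forward_stop,
    predict_prob,
    repeated_cv,
    roc_points,
    seeded_pair,
    third_feature_search,
)
from .synthetic import SyntheticPatient

log = logging.getLogger("ibrad")


@dataclass
class RunConfig:
    """Run-level knobs; everything an output needs to be reproduced."""

    manifest: str = ""
    out_dir: str = "results"
    features: FeatureConfig = field(default_factory=FeatureConfig)
    screening_alpha: float = 0.05
    cv_k: int = 10
    cv_repetitions: int = 300
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        feat_raw = raw.pop("features", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if feat_raw:
            cfg.features = FeatureConfig(**feat_raw)
        return cfg


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_patient_features(image, mask, config: FeatureConfig) -> dict[str, float]:
    """Resample one aligned pair to the analysis grid and extract all features."""
    image, mask = resample_inplane(image, mask, config.target_spacing_mm)
    return extract_all(image, mask, config)


def extract_patients(
    patients: list[SyntheticPatient], config: FeatureConfig | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """In-memory extraction over generated patients -> FeatureTable + truth."""
    config = config or FeatureConfig()
    rows, meta = {}, []
    for p in patients:
        rows[p.image.patient_id] = extract_patient_features(p.image, p.mask, config)
        meta.append(
            {"patient_id": p.image.patient_id, "cohort": p.image.cohort,
             "outcome": p.outcome, "h": p.truth.get("h", np.nan)}
        )
    features = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    meta_df = pd.DataFrame(meta).set_index("patient_id").loc[features.index]
    table = FeatureTable(
        features, meta_df["outcome"], meta_df["cohort"], require_both_classes=False
    )
    return table, meta_df


def run_extract(config: RunConfig, manifest_path: str | None = None) -> str:
    """Extract the feature table for every patient in a manifest CSV.

    Per-patient failures are logged and skipped; the run continues. Returns
    the feature CSV path; a JSON sidecar records the config and the realised
    feature count.
    """
    manifest_path = manifest_path or config.manifest
    manifest = pd.read_csv(manifest_path)
    os.makedirs(config.out_dir, exist_ok=True)
    rows, meta, failures = {}, [], []
    t0 = time.time()
    for rec in manifest.itertuples(index=False):
        try:
            img = load_volume(rec.image, "nifti")
            img.patient_id, img.cohort = str(rec.patient_id), str(rec.cohort)
            msk = load_mask(rec.mask, img, "nifti")
            rows[str(rec.patient_id)] = extract_patient_features(img, msk, config.features)
            meta.append({"patient_id": str(rec.patient_id), "cohort": str(rec.cohort),
                         "outcome": int(rec.outcome)})
        except Exception as exc:  # noqa: BLE001 - per-patient isolation is the contract
            failures.append({"patient_id": str(rec.patient_id), "error": str(exc)})
            log.error("patient %s failed: %s", rec.patient_id, exc)
    if not rows:
        raise RuntimeError("no patient could be extracted")
    features = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    features.index.name = "patient_id"
    out = features.copy()
    meta_df = pd.DataFrame(meta).set_index("patient_id")
    out.insert(0, "cohort", meta_df["cohort"])
    out.insert(1, "outcome", meta_df["outcome"])
    csv_path = os.path.join(config.out_dir, "features.csv")
    out.to_csv(csv_path)
    sidecar = {
        "realised_feature_count": realised_feature_count(config.features),
        "n_patients": len(out),
        "failures": failures,
        "seed": config.seed,
        "features_config": dataclasses.asdict(config.features),
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(os.path.join(config.out_dir, "features.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    log.info("extracted %d patients, %d features each", len(out), features.shape[1])
    return csv_path


def load_feature_table(csv_path: str) -> FeatureTable:
    df = pd.read_csv(csv_path, index_col=0)
    feature_cols = [c for c in df.columns if c not in ("cohort", "outcome", "h")]
    return FeatureTable(df[feature_cols], df["outcome"], df["cohort"])


# ---------------------------------------------------------------------------
# selection + fitting
# ---------------------------------------------------------------------------

def select_model(
    table: FeatureTable, alpha: float = 0.05, pcc_threshold: float | None = None
) -> tuple[ModelSpec, dict[str, list[UnivariateResult]]]:
    """Standardise, screen both cohorts, seed, grow, stop on AIC.

    Standardisation (per cohort) precedes selection, matching the screening
    design; the leakage-free re-standardisation happens inside ``repeated_cv``.
    ``pcc_threshold`` optionally drops candidates whose |Pearson r| with a
    seed feature exceeds the threshold (off by default).
    """
    cohorts = table.cohorts
    if len(cohorts) != 2:
        raise ValueError(f"expected exactly 2 cohorts, found {cohorts}")
    std = zscore(table, scope="per_cohort")
    res = {c: screen_cohort(std, c, alpha=alpha) for c in cohorts}
    pair = seeded_pair(res[cohorts[0]], res[cohorts[1]])
    significant = sorted(
        {r.feature for c in cohorts for r in res[c] if r.significant} - set(pair)
    )
    if pcc_threshold is not None:
        from .cohort_stats import pearson_corr

        kept = []
        for cand in significant:
            rs = []
            for seed_feat in pair:
                both = std.features[[cand, seed_feat]].dropna()
                if len(both) >= 3:
                    rs.append(abs(pearson_corr(both[cand], both[seed_feat])))
            if not rs or max(rs) <= pcc_threshold:
                kept.append(cand)
        significant = kept
    y = std.outcome.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = third_feature_search(std.features, y, pair, significant)
        model = aic_forward_stop(
            std.features, y, model, [c for c in significant if c not in model.features]
        )
    return model, res


def run_select_and_fit(config: RunConfig, features_csv: str) -> tuple[str, str]:
    """File-level selection stage: feature CSV -> model JSON + univariate CSV."""
    table = load_feature_table(features_csv)
    model, res = select_model(table, alpha=config.screening_alpha)
    os.makedirs(config.out_dir, exist_ok=True)
    uni = pd.DataFrame(
        [dataclasses.asdict(r) for results in res.values() for r in results]
    )
    uni_path = os.path.join(config.out_dir, "univariate.csv")
    uni.to_csv(uni_path, index=False)
    model_path = os.path.join(config.out_dir, "model.json")
    with open(model_path, "w") as fh:
        json.dump(
            {
                "features": model.features,
                "intercept": model.intercept,
                "coefficients": model.coefficients,
                "aic": model.aic,
                "train_auc": model.train_auc,
                "seed": config.seed,
                "screening_alpha": config.screening_alpha,
            },
            fh,
            indent=2,
        )
    return model_path, uni_path


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def run_crossval(config: RunConfig, features_csv: str, model_path: str) -> str:
    """CV the selected model and export per-repetition AUCs and ROC points."""
    table = load_feature_table(features_csv)
    with open(model_path) as fh:
        model_doc = json.load(fh)
    features = model_doc["features"]
    missing = [f for f in features if f not in table.features.columns]
    if missing:
        raise ValueError(f"model features absent from table: {missing}")
    cv = repeated_cv(
        table, features, k=config.cv_k, repetitions=config.cv_repetitions, seed=config.seed
    )
    os.makedirs(config.out_dir, exist_ok=True)
    pd.DataFrame(
        {"repetition": np.arange(cv.repetitions), "auc": cv.auc_per_repetition}
    ).to_csv(os.path.join(config.out_dir, "cv_auc.csv"), index=False)

    # apparent ROC of the final model on the merged table and per cohort
    std = zscore(table, scope="per_cohort")
    model = ModelSpec(
        features=features,
        intercept=model_doc["intercept"],
        coefficients=model_doc["coefficients"],
        aic=model_doc["aic"],
    )
    X = std.features[features].to_numpy(dtype=np.float64)
    keep = np.all(np.isfinite(X), axis=1)
    scores = predict_prob(model, X[keep])
    y = std.outcome.to_numpy()[keep]
    cohorts = std.cohort.to_numpy()[keep]
    roc_points(scores, y).to_csv(os.path.join(config.out_dir, "roc_merged.csv"), index=False)
    for c in np.unique(cohorts):
        sel = cohorts == c
        roc_points(scores[sel], y[sel]).to_csv(
            os.path.join(config.out_dir, f"roc_{c}.csv"), index=False
        )
    report = {
        "k": cv.k,
        "repetitions": cv.repetitions,
        "seed": cv.seed,
        "mean_cv_auc": cv.mean_auc,
        "cv_auc_ci": list(cv.auc_ci),
    }
    report_path = os.path.join(config.out_dir, "cv_report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    return report_path
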