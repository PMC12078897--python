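"""End-to-end orchestration: cohort -> habitats -> features -> models -> reports.

``run_study`` is the in-memory driver used by tests and examples;
``run_pipeline`` is the on-disk driver behind the CLI, writing a run
directory with features, model coefficients, evaluation reports and a
manifest for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as ev
from .features import FeatureConfig, extract_feature_vector
from .grid import Mask3D
from .habitats import cluster_voxels, compute_sse_curve, elbow_select_k, pooled_sse_curve
from .models import (
    FINAL_MODEL_NAMES,
    SUBREGIONS,
    HabitatModel,
    ModelBundle,
    enumerate_candidates,
    fit_final_models,
    fit_subregion_model,
    ith_index,
    select_habitat_model,
    univariable_multivariable_lr,
)
from .selection import chi_square_filter, select_features, split_cohort
from .synthetic import CohortConfig, SyntheticPatient, covariate_table, generate_cohort

__all__ = [
    "select_cohort_k",
    "patient_region_masks",
    "extract_cohort_features",
    "train_grading_models",
    "run_study",
    "run_pipeline",
    "PipelineConfig",
    "TrainResult",
]

log = logging.getLogger(__name__)


def select_cohort_k(
    cohort: list[SyntheticPatient], k_max: int = 8, seed: int = 0, restarts: int = 25
) -> tuple[int, "pd.DataFrame"]:
    """Pooled-elbow cluster count over every patient and sequence.

    Per patient and sequence, the SSE curve of K-means over K = 1..k_max
    is computed on standardised within-VOI intensities; curves are
    min-max normalised, averaged over the cohort, and the elbow K of the
    pooled curve is returned together with the pooled curve itself.
    """
    curves = []
    for i, p in enumerate(cohort):
        for vol in (p.t2w, p.dwi):
            curves.append(
                compute_sse_curve(vol, p.voi, k_max=k_max, seed=seed + i, restarts=restarts)
            )
    pooled = pooled_sse_curve(curves)
    k = elbow_select_k(pooled)
    return k, pd.DataFrame({"k": pooled.k_values, "pooled_sse": pooled.sse})


def patient_region_masks(patient: SyntheticPatient, k: int = 2, seed: int = 0) -> dict[str, Mask3D]:
    """Cluster both sequences at K and emit the six standard region masks."""
    masks: dict[str, Mask3D] = {
        "whole_T2WI": patient.voi,
        "whole_DWI": patient.voi,
    }
    for seq, vol in (("T2WI", patient.t2w), ("DWI", patient.dwi)):
        hmap, _ = cluster_voxels(vol, patient.voi, k, seed=seed)
        for lab in range(1, k + 1):
            sel = (hmap.labels.data == lab).astype(np.int16)
            masks[f"{seq}_habitat{lab}"] = Mask3D(sel, patient.voi.spacing, patient.voi.origin)
    return masks


def extract_cohort_features(
    cohort: list[SyntheticPatient],
    config: FeatureConfig | None = None,
    k: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Patients x features table with region/image-type/class provenance tags."""
    config = config or FeatureConfig.original_only()
    rows = {}
    for i, p in enumerate(cohort):
        masks = patient_region_masks(p, k=k, seed=seed + i)
        rows[p.id] = extract_feature_vector(p.t2w, p.dwi, masks, config)
    return pd.DataFrame(rows).T


def _impute_train_median(X: pd.DataFrame, train: np.ndarray) -> pd.DataFrame:
    med = X.loc[X.index[train]].median()
    return X.fillna(med)


@dataclass
class TrainResult:
    train_mask: np.ndarray
    subregion_models: dict
    subregion_selected: dict[str, list[str]]
    candidate_aucs: dict
    habitat_model: HabitatModel
    radiomics_selected: list[str]
    clin_table: pd.DataFrame
    clin_retained: list[str]
    bundle: ModelBundle
    blocks: dict[str, pd.DataFrame]  # all rows, model-input order
    scores: dict[str, np.ndarray] = field(default_factory=dict)  # all rows per model
    reports: dict[str, dict] = field(default_factory=dict)

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.reports).T


def train_grading_models(
    features: pd.DataFrame,
    records: pd.DataFrame,
    seed: int = 0,
    ratio: float = 0.2,
    label_col: str = "grade",
) -> TrainResult:
    """Fit subregion models, the habitat (ITH) model and the seven final models.

    ``features`` is the cohort feature table; ``records`` carries the
    covariates plus the binary grade.  All selection, standardisation,
    calibration and thresholds are computed on the training rows of the
    stratified 8:2 split only.
    """
    records = records.loc[features.index]
    y = records[label_col].to_numpy(dtype=int)
    train = split_cohort(y, ratio=ratio, seed=seed)
    y_tr, y_val = y[train], y[~train]

    # --- per-subregion models and the candidate ITH indices
    sub_models, sub_selected = {}, {}
    probs_all: dict[str, np.ndarray] = {}
    for region in SUBREGIONS:
        cols = [c for c in features.columns if c.startswith(region + "|")]
        Xr = _impute_train_median(features[cols], train)
        sel = select_features(Xr.loc[Xr.index[train]], y_tr, seed=seed)
        chosen = sel.selected
        if not chosen:
            # degenerate screen: fall back to the strongest chi-square features
            chosen = sel.chi2_p.nsmallest(3).index.tolist()
            log.warning("%s: LASSO selected nothing; falling back to %s", region, chosen)
        model = fit_subregion_model(Xr.loc[Xr.index[train], chosen], y_tr, region)
        sub_models[region] = model
        sub_selected[region] = chosen
        probs_all[region] = model.predict_probability(Xr[chosen])

    probs_tr = {r: p[train] for r, p in probs_all.items()}
    probs_val = {r: p[~train] for r, p in probs_all.items()}
    cand_aucs = {}
    for cand in enumerate_candidates():
        idx_val = ith_index(probs_val, cand.subset)
        cand_aucs[cand.subset], *_ = ev.roc_auc_delong(idx_val, y_val)
    habitat_model = select_habitat_model(cand_aucs, sub_models, None, y_tr, probs_tr)
    ith_all = ith_index(probs_all, habitat_model.subset)

    # --- whole-tumour radiomics block
    whole_cols = [c for c in features.columns if c.startswith("whole_")]
    Xw = _impute_train_median(features[whole_cols], train)
    sel_rad = select_features(Xw.loc[Xw.index[train]], y_tr, seed=seed)
    rad_selected = sel_rad.selected or sel_rad.chi2_p.nsmallest(3).index.tolist()

    # --- clinical / laboratory / imaging block
    clin_cols = [c for c in records.columns if c != label_col]
    clin_train = records.loc[records.index[train], clin_cols + [label_col]]
    clin_table, retained = univariable_multivariable_lr(clin_train, label_col)
    if not retained:
        retained = clin_table["p_uni"].nsmallest(2).index.tolist()
        log.warning("no covariate retained at p<0.05; falling back to %s", retained)

    blocks_all = {
        "clinlabimag": records[retained].astype(float),
        "radiomics": Xw[rad_selected],
        "habitat": pd.DataFrame({"ith_index": ith_all}, index=features.index),
    }
    blocks_train = {k: v.loc[v.index[train]] for k, v in blocks_all.items()}
    bundle = fit_final_models(blocks_train, y_tr)

    scores, reports = {}, {}
    X_all = pd.concat(blocks_all.values(), axis=1)
    for name in FINAL_MODEL_NAMES:
        s = bundle.models[name].predict_probability(X_all)
        scores[name] = s
        rep = ev.evaluate_model(s[~train], y_val, bundle.thresholds[name])
        reports[name] = rep.summary()

    return TrainResult(
        train_mask=train,
        subregion_models=sub_models,
        subregion_selected=sub_selected,
        candidate_aucs=cand_aucs,
        habitat_model=habitat_model,
        radiomics_selected=rad_selected,
        clin_table=clin_table,
        clin_retained=retained,
        bundle=bundle,
        blocks=blocks_all,
        scores=scores,
        reports=reports,
    )


def run_study(
    cohort_config: CohortConfig,
    feature_config: FeatureConfig | None = None,
    k: int | None = None,
    k_max: int = 8,
    seed: int | None = None,
    elbow_restarts: int = 10,
):
    """Generate, cluster, extract and model a synthetic cohort in memory.

    ``k=None`` selects K by the pooled cohort elbow first.  Returns
    (cohort, features, records, TrainResult, selected K).
    """
    seed = cohort_config.seed if seed is None else seed
    cohort = generate_cohort(cohort_config)
    if k is None:
        k, _ = select_cohort_k(cohort, k_max=k_max, seed=seed, restarts=elbow_restarts)
    features = extract_cohort_features(cohort, feature_config, k=k, seed=seed)
    records = covariate_table(cohort)
    result = train_grading_models(features, records, seed=seed)
    return cohort, features, records, result, k


# --------------------------------------------------------------- on-disk run


@dataclass
class PipelineConfig:
    """Declarative config for a full on-disk run; JSON round-trippable."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    feature_bank: str = "original"  # "original" | "full"
    k: int | None = None
    k_max: int = 8
    split_ratio: float = 0.2
    seed: int = 7

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig.default() if self.feature_bank == "full" else FeatureConfig.original_only()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"]["covariate_spec"] = [dataclasses.asdict(c) for c in self.cohort.covariate_spec]
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        from .synthetic import CovariateSpec

        d = json.loads(text)
        cd = d.pop("cohort")
        cd["covariate_spec"] = tuple(CovariateSpec(**c) for c in cd["covariate_spec"])
        for key in ("volume_shape", "spacing", "tumor_radius_range", "habitat_fraction_low",
                    "habitat_fraction_high", "misalignment_shift"):
            cd[key] = tuple(cd[key])
        cd["texture_regions"] = tuple((seq, int(h)) for seq, h in cd["texture_regions"])
        cd["intensity_means"] = {s: tuple(v) for s, v in cd["intensity_means"].items()}
        return cls(cohort=CohortConfig(**cd), **d)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage and write a run directory; returns the manifest.

    Outputs: ``features.csv``, ``records.csv``, ``sse_curve.csv``,
    ``selection.json``, ``model_coefficients.json``, ``reports.csv`` and
    ``manifest.json``.  Re-running with the same config reproduces every
    numeric output.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = config.to_json()
    (out / "config.json").write_text(cfg_text)

    cohort = generate_cohort(config.cohort)
    k = config.k
    if k is None:
        k, pooled = select_cohort_k(cohort, k_max=config.k_max, seed=config.seed, restarts=10)
        pooled.to_csv(out / "sse_curve.csv", index=False)
    features = extract_cohort_features(cohort, config.feature_config(), k=k, seed=config.seed)
    features.to_csv(out / "features.csv")
    records = covariate_table(cohort)
    records.to_csv(out / "records.csv")

    result = train_grading_models(features, records, seed=config.seed, ratio=config.split_ratio)
    (out / "selection.json").write_text(
        json.dumps(
            {
                "k": k,
                "subregion_selected": result.subregion_selected,
                "habitat_subset": sorted(result.habitat_model.subset),
                "radiomics_selected": result.radiomics_selected,
                "clinlabimag_retained": result.clin_retained,
            },
            indent=2,
        )
    )
    coefs = {
        name: {
            "features": m.feature_names,
            "coef": list(map(float, m.coef)),
            "intercept": m.intercept,
            "threshold": result.bundle.thresholds[name],
        }
        for name, m in result.bundle.models.items()
    }
    (out / "model_coefficients.json").write_text(json.dumps(coefs, indent=2))
    result.report_frame().to_csv(out / "reports.csv")

    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_patients": len(cohort),
        "k": int(k),
        "n_features": int(features.shape[1]),
        "models": list(result.bundle.models),
        "format_version": 1,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
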