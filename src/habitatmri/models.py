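"""Subregion grading models, the ITH index, and the seven final models.

One logistic model is fitted per habitat subregion (DWI_habitat1,
DWI_habitat2, T2WI_habitat1, T2WI_habitat2) on its LASSO-selected
features.  The intratumoral-heterogeneity (ITH) index of a candidate
subset of subregions is the unweighted mean of their predicted
probabilities; 13 candidate subsets (every singleton plus every subset
containing at least one subregion from each sequence) are scored on the
internal validation set, and the winner — recalibrated by a logistic map
fitted on training — becomes the Habitat model.  Seven final logistic
models combine the clinical/laboratory/imaging block, the radiomics
block, and the habitat block.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

__all__ = [
    "SUBREGIONS",
    "FINAL_MODEL_NAMES",
    "FittedLogistic",
    "SubregionModel",
    "CandidateSpec",
    "HabitatModel",
    "ModelBundle",
    "fit_logistic",
    "fit_subregion_model",
    "ith_index",
    "enumerate_candidates",
    "select_habitat_model",
    "univariable_multivariable_lr",
    "youden_threshold",
    "fit_final_models",
]

log = logging.getLogger(__name__)

SUBREGIONS = ("DWI_habitat1", "DWI_habitat2", "T2WI_habitat1", "T2WI_habitat2")
_SEQ_OF = {r: ("DWI" if r.startswith("DWI") else "T2WI") for r in SUBREGIONS}

FINAL_MODEL_NAMES = (
    "ClinLabImag",
    "Radiomics",
    "Habitat",
    "ClinLabImag-Radiomics",
    "ClinLabImag-Habitat",
    "Radiomics-Habitat",
    "Combined",
)


@dataclass
class FittedLogistic:
    """Logistic model on standardised inputs, with its training constants."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    coef: np.ndarray  # log-odds per standardised unit
    intercept: float
    ridge_stabilized: bool = False

    def _z(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def decision(self, X) -> np.ndarray:
        """Linear predictor (log-odds)."""
        return self.intercept + self._z(X) @ self.coef

    def predict_probability(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision(X)))
        eps = 1e-12
        return np.clip(p, eps, 1 - eps)


def fit_logistic(X: pd.DataFrame, y, ridge: float = 0.0) -> FittedLogistic:
    """Maximum-likelihood logistic fit on standardised features.

    Falls back to a ridge-stabilised fit (penalty 1e-4) when the MLE does
    not exist (complete separation) or fails to converge.
    """
    y = np.asarray(y).astype(int)
    names = list(X.columns)
    if not names:  # intercept-only model: closed form
        p = y.mean()
        return FittedLogistic([], np.empty(0), np.empty(0), np.empty(0), float(np.log(p / (1 - p))))
    Xv = X.to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xv - mu) / sd
    stabilized = ridge > 0
    coef = intercept = None
    if not stabilized:
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation is handled below
                res = sm.Logit(y, sm.add_constant(Z, has_constant="add")).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            if res.mle_retvals.get("converged", False) and np.all(np.isfinite(params)) and np.abs(params).max() < 30:
                intercept, coef = float(params[0]), params[1:]
        except Exception:
            pass
        if coef is None:
            log.warning("logistic MLE unstable (separation?); using ridge-stabilised fit")
            stabilized = True
    if stabilized:
        lam = ridge if ridge > 0 else 1e-4
        m = LogisticRegression(l1_ratio=0.0, C=1.0 / (lam * len(y)), max_iter=5000).fit(Z, y)
        intercept, coef = float(m.intercept_[0]), m.coef_[0]
    return FittedLogistic(names, mu, sd, coef, intercept, ridge_stabilized=stabilized)


@dataclass
class SubregionModel:
    region: str
    model: FittedLogistic

    def predict_probability(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict_probability(features)


def fit_subregion_model(selected_features: pd.DataFrame, labels, region: str) -> SubregionModel:
    if selected_features.shape[1] < 1:
        raise ValueError(f"{region}: at least one selected feature is required")
    return SubregionModel(region, fit_logistic(selected_features, labels))


def ith_index(probabilities: dict[str, np.ndarray] | pd.DataFrame, subset) -> np.ndarray:
    """Unweighted mean of the subset's subregion probabilities, in [0, 1].

    Missing members (empty habitats) are averaged over with a warning.
    """
    subset = sorted(subset)
    if isinstance(probabilities, pd.DataFrame):
        probabilities = {c: probabilities[c].to_numpy() for c in probabilities.columns}
    avail = [s for s in subset if s in probabilities]
    missing = set(subset) - set(avail)
    if missing:
        log.warning("ITH index: missing subregion probabilities %s; using the rest", sorted(missing))
    if not avail:
        raise ValueError("no subregion probabilities available")
    return np.mean([np.asarray(probabilities[s], dtype=float) for s in avail], axis=0)


@dataclass(frozen=True)
class CandidateSpec:
    subset: frozenset

    def __repr__(self):
        return "+".join(sorted(self.subset))


def enumerate_candidates() -> list[CandidateSpec]:
    """All 13 candidate subsets: 4 singletons + 9 cross-sequence subsets.

    The two within-sequence pairs are excluded: a multi-subregion index
    must mix information from both sequences.
    """
    out = [CandidateSpec(frozenset([r])) for r in SUBREGIONS]
    dwi = [r for r in SUBREGIONS if _SEQ_OF[r] == "DWI"]
    t2 = [r for r in SUBREGIONS if _SEQ_OF[r] == "T2WI"]
    for nd in (1, 2):
        for nt in (1, 2):
            for ds in itertools.combinations(dwi, nd):
                for ts in itertools.combinations(t2, nt):
                    out.append(CandidateSpec(frozenset(ds + ts)))
    assert len(out) == 13
    return out


@dataclass
class HabitatModel:
    subset: frozenset
    subregion_models: dict[str, SubregionModel]
    calibration: FittedLogistic  # logistic map: ITH index -> probability
    validation_auc: float = float("nan")

    def index(self, subregion_features: dict[str, pd.DataFrame]) -> np.ndarray:
        probs = {
            r: m.predict_probability(subregion_features[r])
            for r, m in self.subregion_models.items()
            if r in self.subset and r in subregion_features
        }
        return ith_index(probs, self.subset)

    def predict_probability(self, subregion_features: dict[str, pd.DataFrame]) -> np.ndarray:
        idx = self.index(subregion_features)
        return self.calibration.predict_probability(pd.DataFrame({"ith_index": idx}))


def select_habitat_model(
    candidate_aucs: dict[frozenset, float],
    subregion_models: dict[str, SubregionModel],
    train_index: pd.DataFrame | np.ndarray,
    train_labels,
    train_probabilities: dict[str, np.ndarray],
) -> HabitatModel:
    """Argmax of internal-validation AUC; ties to the smaller, then
    lexicographically earlier subset.  The winning index is wrapped with a
    logistic recalibration fitted on training."""
    ranked = sorted(
        candidate_aucs.items(),
        key=lambda kv: (-round(kv[1], 12), len(kv[0]), tuple(sorted(kv[0]))),
    )
    subset, auc = ranked[0]
    idx = ith_index(train_probabilities, subset)
    calib = fit_logistic(pd.DataFrame({"ith_index": idx}), train_labels)
    return HabitatModel(subset, subregion_models, calib, validation_auc=float(auc))


def univariable_multivariable_lr(records: pd.DataFrame, label_col: str = "grade") -> tuple[pd.DataFrame, list[str]]:
    """Per-covariate Wald ORs then a joint refit of the p < 0.05 set.

    Returns the OR table (univariable and, where applicable, multivariable
    OR / 95% CI / p) and the covariates retained at p < 0.05 in the joint
    fit.  Covariates with an empty level are dropped with a warning.
    """
    y = records[label_col].to_numpy(dtype=int)
    covs = [c for c in records.columns if c != label_col]
    rows = {}
    usable = []
    for c in covs:
        x = records[c].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            log.warning("covariate %s has a single level; dropped", c)
            continue
        xz = (x - x.mean()) / x.std() if set(np.unique(x)) - {0.0, 1.0} else x
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, sm.add_constant(xz)).fit(disp=0)
            b, se = res.params[1], res.bse[1]
        except Exception:
            log.warning("univariable fit failed for %s; dropped", c)
            continue
        rows[c] = {
            "or_uni": np.exp(b),
            "ci_low_uni": np.exp(b - 1.959963984540054 * se),
            "ci_high_uni": np.exp(b + 1.959963984540054 * se),
            "p_uni": res.pvalues[1],
        }
        usable.append(c)
    table = pd.DataFrame(rows).T
    entering = [c for c in usable if table.loc[c, "p_uni"] < 0.05]
    retained: list[str] = []
    if entering:
        X = records[entering].to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        bin_cols = [set(np.unique(records[c])) <= {0.0, 1.0} for c in entering]
        Xs = np.column_stack(
            [X[:, i] if bin_cols[i] else (X[:, i] - mu[i]) / sd[i] for i in range(len(entering))]
        )
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(Xs)).fit(disp=0)
        for i, c in enumerate(entering):
            b, se, p = res.params[i + 1], res.bse[i + 1], res.pvalues[i + 1]
            table.loc[c, ["or_multi", "ci_low_multi", "ci_high_multi", "p_multi"]] = [
                np.exp(b), np.exp(b - 1.96 * se), np.exp(b + 1.96 * se), p,
            ]
            if p < 0.05:
                retained.append(c)
    return table, retained


def youden_threshold(scores, labels) -> float:
    """Probability threshold maximising sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, dtype=float))
    j = tpr - fpr
    best = int(np.argmax(j))
    t = float(thr[best])
    return min(t, 1.0)  # roc_curve prepends max+1


@dataclass
class ModelBundle:
    models: dict[str, FittedLogistic]
    thresholds: dict[str, float]
    blocks: dict[str, list[str]] = field(default_factory=dict)

    def predict_probability(self, name: str, X: pd.DataFrame) -> np.ndarray:
        return self.models[name].predict_probability(X)


def fit_final_models(blocks: dict[str, pd.DataFrame], labels) -> ModelBundle:
    """Fit the seven final logistic models on training rows.

    ``blocks`` maps 'clinlabimag' / 'radiomics' / 'habitat' to training
    feature frames (same row order as ``labels``).  Each model stores a
    training-set Youden threshold.  An empty block makes every model that
    needs it fail with a surfaced error.
    """
    key_of = {"ClinLabImag": ("clinlabimag",), "Radiomics": ("radiomics",), "Habitat": ("habitat",),
              "ClinLabImag-Radiomics": ("clinlabimag", "radiomics"),
              "ClinLabImag-Habitat": ("clinlabimag", "habitat"),
              "Radiomics-Habitat": ("radiomics", "habitat"),
              "Combined": ("clinlabimag", "radiomics", "habitat")}
    for k, df in blocks.items():
        if df.shape[1] == 0:
            raise ValueError(f"block '{k}' is empty; cannot fit the final models")
    models, thresholds, used = {}, {}, {}
    for name, keys in key_of.items():
        X = pd.concat([blocks[k] for k in keys], axis=1)
        m = fit_logistic(X, labels)
        models[name] = m
        thresholds[name] = youden_threshold(m.predict_probability(X), labels)
        used[name] = list(X.columns)
    return ModelBundle(models, thresholds, used)
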