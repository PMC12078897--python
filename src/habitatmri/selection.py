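"""Feature selection: stratified cohort split, chi-square filter, LASSO.

Continuous features are binarised at their training median for the
chi-square screen (scale-free and balanced); survivors enter an
L1-penalised logistic path whose penalty is chosen by 10-fold
cross-validated deviance (minimum rule).  No validation row ever touches
medians, standardisation constants or the penalty choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = ["SelectionResult", "split_cohort", "chi_square_filter", "lasso_select", "select_features"]

log = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    chi2_p: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    passed_chi2: list[str] = field(default_factory=list)
    lasso_path: dict | None = None
    selected: list[str] = field(default_factory=list)
    seed: int = 0


def split_cohort(labels, ratio: float = 0.2, seed: int = 0) -> np.ndarray:
    """Stratified train/validation assignment; True = training row.

    Each grade stratum contributes ``round(ratio * n_stratum)`` patients
    to the validation set, so proportions are preserved to within one
    patient per stratum.  Deterministic given the seed.
    """
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    train = np.ones(y.size, dtype=bool)
    for g in np.unique(y):
        idx = np.flatnonzero(y == g)
        if idx.size < 5:
            log.warning("stratum %s has only %d patients; best-effort split", g, idx.size)
        n_val = int(round(ratio * idx.size))
        val = rng.permutation(idx)[:n_val]
        train[val] = False
    return train


def chi_square_filter(
    features: pd.DataFrame, labels, alpha: float = 0.05
) -> SelectionResult:
    """Median-split chi-square screen; keeps features with p < alpha."""
    y = np.asarray(labels).astype(int)
    pvals = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)) or np.ptp(x) == 0:
            log.warning("feature %s is constant or non-finite; excluded from chi-square screen", col)
            continue
        b = (x > np.median(x)).astype(int)
        if b.min() == b.max():  # median split degenerate (heavy ties)
            b = (x >= np.median(x)).astype(int)
            if b.min() == b.max():
                continue
        table = pd.crosstab(b, y).to_numpy()
        if table.shape != (2, 2):
            continue
        chi2, p, *_ = stats.chi2_contingency(table, correction=False)
        pvals[col] = p
    chi2_p = pd.Series(pvals, dtype=float)
    passed = chi2_p.index[chi2_p < alpha].tolist()
    return SelectionResult(chi2_p=chi2_p, passed_chi2=passed)


def lasso_select(
    features: pd.DataFrame,
    labels,
    n_folds: int = 10,
    seed: int = 0,
    n_penalties: int = 25,
    max_fallback_terms: int = 20,
) -> SelectionResult:
    """L1 logistic path; penalty by minimum cross-validated deviance.

    Falls back to the largest penalty keeping at most
    ``max_fallback_terms`` nonzero coefficients if the chosen fit
    separates the training data completely.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    X = features.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    Cs = np.logspace(-3, 1.5, n_penalties)
    cv = StratifiedKFold(n_splits=min(n_folds, min(np.bincount(y))), shuffle=True, random_state=seed)
    mean_dev = []
    for C in Cs:
        est = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=0)
        scores = cross_val_score(est, Z, y, cv=cv, scoring="neg_log_loss")
        mean_dev.append(-2.0 * scores.mean())
    mean_dev = np.asarray(mean_dev)
    best = int(np.argmin(mean_dev))

    coefs = {}
    def _fit(C):
        m = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=0).fit(Z, y)
        coefs[C] = m.coef_[0]
        return m

    model = _fit(Cs[best])
    proba = model.predict_proba(Z)[:, 1]
    separated = np.all((proba > 0.5) == (y == 1)) and (np.minimum(proba, 1 - proba) < 1e-4).all()
    nnz = int(np.count_nonzero(model.coef_))
    if separated and nnz > max_fallback_terms:
        log.warning("complete separation at CV-chosen penalty; falling back to a sparser fit")
        for i in range(best, -1, -1):
            model = _fit(Cs[i])
            if np.count_nonzero(model.coef_) <= max_fallback_terms:
                break
    sel_mask = model.coef_[0] != 0
    selected = [c for c, keep in zip(features.columns, sel_mask) if keep]
    path = {"Cs": Cs, "cv_deviance": mean_dev, "coefs": coefs, "chosen_C": float(Cs[best])}
    return SelectionResult(lasso_path=path, selected=selected, seed=seed)


def select_features(
    features: pd.DataFrame, labels, alpha: float = 0.05, n_folds: int = 10, seed: int = 0
) -> SelectionResult:
    """Chi-square screen followed by LASSO on the survivors."""
    res = chi_square_filter(features, labels, alpha)
    if not res.passed_chi2:
        log.warning("no feature passed the chi-square screen")
        return res
    lasso = lasso_select(features[res.passed_chi2], labels, n_folds=n_folds, seed=seed)
    res.lasso_path = lasso.lasso_path
    res.selected = lasso.selected
    res.seed = seed
    return res
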