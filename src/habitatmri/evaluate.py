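"""Discrimination, comparison, calibration, utility, attribution, agreement.

AUCs use the Mann-Whitney statistic with midrank tie handling; variances
and the paired model comparison use DeLong's structural components.
Shapley attributions for the (linear) logistic models are exact closed
forms on the log-odds scale.  Inter-reader agreement uses Cohen's kappa
(categorical) and the two-way random-effects, absolute-agreement,
single-measurement ICC (continuous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .models import FittedLogistic

__all__ = [
    "EvalReport",
    "AttributionReport",
    "roc_auc_delong",
    "delong_test",
    "threshold_metrics",
    "calibration_curve",
    "decision_curve",
    "linear_shap",
    "cohens_kappa",
    "icc_two_way",
    "cohort_comparison_tests",
    "evaluate_model",
]


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return v10, v01


def roc_auc_delong(scores, labels) -> tuple[float, tuple[float, float], float]:
    """AUC, DeLong 95% CI (truncated to [0, 1]) and the DeLong variance."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, v01 = _delong_components(scores, labels)
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) + (
        np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0
    )
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return auc, ci, float(var)


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong z-test for the paired AUC difference."""
    labels = np.asarray(labels).astype(int)
    a10, a01 = _delong_components(np.asarray(scores_a, dtype=float), labels)
    b10, b01 = _delong_components(np.asarray(scores_b, dtype=float), labels)
    auc_a, auc_b = a10.mean(), b10.mean()
    m, n = len(a10), len(a01)
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([a10, b10]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([a01, b01]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def threshold_metrics(scores, labels, threshold: float) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, precision at a fixed threshold.

    Precision is reported as NaN when no positive call is made.
    """
    y = np.asarray(labels).astype(int)
    call = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(call & (y == 1)))
    fn = int(np.sum(~call & (y == 1)))
    tn = int(np.sum(~call & (y == 0)))
    fp = int(np.sum(call & (y == 0)))
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / y.size,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }


def calibration_curve(scores, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-frequency calibration bins (observed vs mean predicted).

    Quantile bins collapsed by ties are merged with their neighbours.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    edges = np.unique(np.quantile(scores, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        edges = np.array([scores.min() - 1e-9, scores.max() + 1e-9])
    which = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {"bin": b, "n": int(sel.sum()), "predicted": float(scores[sel].mean()),
             "observed": float(y[sel].mean())}
        )
    return pd.DataFrame(rows)


def decision_curve(scores, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit over a threshold-probability grid, with references.

    net benefit = TP/n - FP/n * pt/(1-pt); treat-all and treat-none
    reference curves are included.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n = y.size
    prev = y.mean()
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    rows = []
    for pt in np.asarray(thresholds, dtype=float):
        call = scores >= pt
        tp = np.sum(call & (y == 1)) / n
        fp = np.sum(call & (y == 0)) / n
        w = pt / (1.0 - pt)
        rows.append(
            {"threshold": pt, "net_benefit": tp - fp * w,
             "treat_all": prev - (1 - prev) * w, "treat_none": 0.0}
        )
    return pd.DataFrame(rows)


@dataclass
class AttributionReport:
    """Exact Shapley values of a linear-logistic model (log-odds scale)."""

    values: pd.DataFrame  # patients x features
    base_value: float  # score at the background mean
    scores: np.ndarray  # per-patient log-odds
    ranking: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def block_aggregate(self, blocks: dict[str, list[str]]) -> pd.DataFrame:
        return pd.DataFrame(
            {name: self.values[cols].sum(axis=1) for name, cols in blocks.items()}
        )


def linear_shap(model: FittedLogistic, X: pd.DataFrame, background: pd.Series | None = None) -> AttributionReport:
    """phi_ij = beta_j (x_ij - x̄_j) on the log-odds scale.

    The background defaults to the model's stored training means, under
    which attributions sum exactly to score − base score per patient.
    """
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"features missing from input: {missing}")
    Z = (X[model.feature_names].to_numpy(dtype=float) - model.mean) / model.sd
    if background is None:
        zbg = np.zeros(len(model.feature_names))
    else:
        zbg = (background[model.feature_names].to_numpy(dtype=float) - model.mean) / model.sd
    phi = (Z - zbg) * model.coef
    base = float(model.intercept + zbg @ model.coef)
    scores = base + phi.sum(axis=1)
    values = pd.DataFrame(phi, index=X.index, columns=model.feature_names)
    ranking = values.abs().mean(axis=0).sort_values(ascending=False)
    return AttributionReport(values, base, scores, ranking)


def cohens_kappa(table_or_a, b=None) -> float:
    """Cohen's kappa from a k x k agreement table or two rating vectors."""
    if b is not None:
        return float(cohen_kappa_score(np.asarray(table_or_a), np.asarray(b)))
    t = np.asarray(table_or_a, dtype=float)
    n = t.sum()
    po = np.trace(t) / n
    pe = float((t.sum(axis=0) * t.sum(axis=1)).sum()) / n**2
    if abs(1.0 - pe) < 1e-12:
        return float("nan")  # degenerate marginals
    return float((po - pe) / (1.0 - pe))


def icc_two_way(ratings: pd.DataFrame | np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater."""
    r = np.asarray(ratings, dtype=float)
    n, k = r.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    long = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": r.ravel(),
        }
    )
    res = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="ratings")
    res = res.set_index("Type")
    key = "ICC2" if "ICC2" in res.index else "ICC(A,1)"  # label varies across pingouin versions
    return float(res.loc[key, "ICC"])


def cohort_comparison_tests(
    records: pd.DataFrame, grouping: str, variables: list[str] | None = None
) -> pd.DataFrame:
    """Per-variable group comparisons, test chosen by data type.

    Binary/categorical: Pearson chi-square, or Fisher's exact (2 x 2)
    when any expected count is below 5.  Continuous: Mann-Whitney U
    (two groups).  Constant variables are skipped with a note.
    """
    g = records[grouping]
    groups = sorted(g.unique())
    if variables is None:
        variables = [c for c in records.columns if c != grouping]
    rows = []
    for var in variables:
        x = records[var]
        if x.nunique() <= 1:
            rows.append({"variable": var, "test": "skipped (constant)", "p": float("nan")})
            continue
        if x.nunique() <= 4:  # categorical
            table = pd.crosstab(x, g).to_numpy()
            expected = stats.contingency.expected_freq(table)
            if table.shape == (2, 2) and (expected < 5).any():
                _, p = stats.fisher_exact(table)
                test = "fisher"
            else:
                _, p, *_ = stats.chi2_contingency(table, correction=False)
                test = "chi2"
        else:
            if len(groups) != 2:
                rows.append({"variable": var, "test": "skipped (>2 groups)", "p": float("nan")})
                continue
            _, p = stats.mannwhitneyu(
                x[g == groups[0]], x[g == groups[1]], alternative="two-sided"
            )
            test = "mannwhitney"
        rows.append({"variable": var, "test": test, "p": float(p)})
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class EvalReport:
    auc: float
    ci95: tuple[float, float]
    threshold: float
    metrics: dict[str, float]
    roc_points: pd.DataFrame
    calibration: pd.DataFrame
    decision: pd.DataFrame

    def summary(self) -> dict[str, float]:
        return {"auc": self.auc, "ci_low": self.ci95[0], "ci_high": self.ci95[1], **self.metrics}


def evaluate_model(scores, labels, threshold: float, n_bins: int = 10) -> EvalReport:
    """Full per-model report at a training-fixed threshold."""
    from sklearn.metrics import roc_curve

    auc, ci, _ = roc_auc_delong(scores, labels)
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, dtype=float))
    roc_pts = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return EvalReport(
        auc=auc,
        ci95=ci,
        threshold=threshold,
        metrics=threshold_metrics(scores, labels, threshold),
        roc_points=roc_pts,
        calibration=calibration_curve(scores, labels, n_bins),
        decision=decision_curve(scores, labels),
    )
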