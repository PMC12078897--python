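"""K-means habitat subregions and SSE elbow selection.

Each sequence's within-VOI voxel intensities are standardised and
clustered in 1-D; clusters are relabelled by descending mean so that
habitat 1 is always the high-signal subregion.  The number of clusters is
chosen once per cohort from the pooled, min-max-normalised SSE curve by
the maximum-chord-distance (Kneedle-style) elbow rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .grid import HabitatMap, Mask3D, Volume3D, check_same_grid

__all__ = [
    "SSECurve",
    "cluster_voxels",
    "cluster_voxels_joint",
    "compute_sse_curve",
    "pooled_sse_curve",
    "elbow_select_k",
    "habitat_masks",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SSECurve:
    """Within-cluster sum of squared errors over K = 1..Kmax."""

    k_values: np.ndarray
    sse: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.k_values, dtype=int)
        s = np.asarray(self.sse, dtype=float)
        if k.size != s.size or k.size < 2 or np.any(np.diff(k) <= 0):
            raise ValueError("k_values must be increasing and match sse length")
        if np.any(s < -1e-9):
            raise ValueError("sse must be nonnegative")
        object.__setattr__(self, "k_values", k)
        object.__setattr__(self, "sse", s)

    def normalized(self) -> "SSECurve":
        s = self.sse
        rng = s.max() - s.min()
        return SSECurve(self.k_values, (s - s.min()) / rng if rng > 0 else np.zeros_like(s))


def _kmeanspp_init(xs: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [xs[rng.integers(xs.size)]]
    d2 = (xs - centers[0]) ** 2
    for _ in range(k - 1):
        tot = d2.sum()
        if tot <= 0:
            centers.append(xs[rng.integers(xs.size)])
        else:
            centers.append(xs[rng.choice(xs.size, p=d2 / tot)])
        d2 = np.minimum(d2, (xs - centers[-1]) ** 2)
    return np.asarray(centers, dtype=float)


def _kmeans_1d(
    x: np.ndarray, k: int, seed: int, restarts: int, max_iter: int = 300, tol: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Lloyd's algorithm specialised to 1-D (sorted prefix sums), best of restarts.

    In 1-D, nearest-centre assignment is the segmentation of the sorted
    sample at centre midpoints, so each iteration is O(k log n).  Returns
    (labels in 0..k-1 ordered by ascending centre, SSE).
    """
    rng = np.random.default_rng(seed)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    cs = np.concatenate([[0.0], np.cumsum(xs)])
    cs2 = np.concatenate([[0.0], np.cumsum(xs**2)])
    scale = max(float(np.abs(xs).max()), 1e-12)

    def segment(centers):
        centers = np.sort(centers)
        cuts = np.searchsorted(xs, (centers[1:] + centers[:-1]) / 2.0)
        return np.concatenate([[0], cuts, [n]])

    best_sse, best_seg = np.inf, None
    for _ in range(restarts):
        centers = _kmeanspp_init(xs, k, rng)
        for _ in range(max_iter):
            seg = segment(centers)
            counts = np.diff(seg)
            sums = cs[seg[1:]] - cs[seg[:-1]]
            new = np.where(counts > 0, sums / np.maximum(counts, 1), np.sort(centers))
            if (counts == 0).any():
                new[counts == 0] = xs[rng.integers(n, size=int((counts == 0).sum()))]
            shift = float(np.abs(new - np.sort(centers)).max())
            centers = new
            if shift <= tol * scale:
                break
        seg = segment(centers)
        counts = np.diff(seg)
        sums = cs[seg[1:]] - cs[seg[:-1]]
        sq = cs2[seg[1:]] - cs2[seg[:-1]]
        sse = float(np.sum(sq - np.where(counts > 0, sums**2 / np.maximum(counts, 1), 0.0)))
        if sse < best_sse:
            best_sse, best_seg = sse, seg
    lab_sorted = np.repeat(np.arange(k), np.diff(best_seg))
    labels = np.empty(n, dtype=int)
    labels[order] = lab_sorted
    return labels, best_sse


def _standardized_intensities(volume: Volume3D, mask: Mask3D) -> tuple[np.ndarray, np.ndarray]:
    check_same_grid(volume, mask)
    vals = np.asarray(volume.data[mask.voi], dtype=float)
    sd = vals.std()
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    return vals, z


def cluster_voxels(
    volume: Volume3D,
    mask: Mask3D,
    k: int,
    seed: int = 0,
    restarts: int = 25,
) -> tuple[HabitatMap, float]:
    """K-means on standardised within-VOI intensities; best of ``restarts``.

    Returns the habitat map (labels ordered by descending cluster mean)
    and the SSE of the best solution, on the standardised scale.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals, z = _standardized_intensities(volume, mask)
    if vals.size < k:
        raise ValueError(f"VOI has {vals.size} voxels < k={k}")
    if np.unique(vals).size < k:
        raise ValueError(f"k={k} exceeds the number of distinct intensities")
    if k == 1:
        labels = np.ones(vals.size, dtype=int)
        sse = float(np.sum(z**2))
        centers_mean = np.array([vals.mean()])
    else:
        raw, sse = _kmeans_1d(z, k, seed=seed, restarts=restarts)
        # raw clusters are ordered by ascending centre; habitat 1 = highest mean
        labels = k - raw
        centers_mean = np.array([vals[labels == lab].mean() for lab in range(1, k + 1)])
    grid = np.zeros(mask.shape, dtype=np.int16)
    grid[mask.voi] = labels
    hmap = HabitatMap(
        Mask3D(grid, mask.spacing, mask.origin),
        sequence=volume.sequence or "unknown",
        cluster_means=centers_mean,
    )
    return hmap, sse


def cluster_voxels_joint(
    volumes: list[Volume3D],
    mask: Mask3D,
    k: int,
    seed: int = 0,
    restarts: int = 25,
) -> tuple[HabitatMap, float]:
    """Non-default variant: one K-means over the stacked sequences.

    Voxels are clustered in the joint (e.g. 2-D T2WI x DWI) standardised
    intensity space instead of per sequence; labels are ordered by the
    descending mean of the first volume.
    """
    from sklearn.cluster import KMeans

    if k < 1:
        raise ValueError("k must be >= 1")
    cols = []
    for vol in volumes:
        vals, z = _standardized_intensities(vol, mask)
        cols.append(z)
    Z = np.column_stack(cols)
    if Z.shape[0] < k:
        raise ValueError(f"VOI has {Z.shape[0]} voxels < k={k}")
    km = KMeans(n_clusters=k, n_init=restarts, max_iter=300, tol=1e-6, random_state=seed).fit(Z)
    first_vals = volumes[0].data[mask.voi]
    means = np.array([first_vals[km.labels_ == c].mean() for c in range(k)])
    order = np.argsort(-means)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[km.labels_]
    grid = np.zeros(mask.shape, dtype=np.int16)
    grid[mask.voi] = labels
    hmap = HabitatMap(
        Mask3D(grid, mask.spacing, mask.origin),
        sequence="+".join(v.sequence or "?" for v in volumes),
        cluster_means=means[order],
    )
    return hmap, float(km.inertia_)


def compute_sse_curve(
    volume: Volume3D, mask: Mask3D, k_max: int = 8, seed: int = 0, restarts: int = 25
) -> SSECurve:
    """SSE for K = 1..k_max (K capped at the number of distinct intensities)."""
    n_distinct = np.unique(volume.data[mask.voi]).size
    ks, sses = [], []
    for k in range(1, k_max + 1):
        if k > n_distinct:
            break
        _, sse = cluster_voxels(volume, mask, k, seed=seed, restarts=restarts)
        ks.append(k)
        sses.append(sse)
    return SSECurve(np.array(ks), np.array(sses))


def pooled_sse_curve(curves: list[SSECurve]) -> SSECurve:
    """Cohort-mean of min-max-normalised SSE curves (common K grid)."""
    k0 = curves[0].k_values
    for c in curves:
        if not np.array_equal(c.k_values, k0):
            raise ValueError("all curves must share the same K grid")
    pooled = np.mean([c.normalized().sse for c in curves], axis=0)
    return SSECurve(k0, pooled)


def elbow_select_k(curve: SSECurve, tol: float = 1e-9) -> int:
    """K at maximum perpendicular distance to the chord, both axes min-max scaled.

    Candidates are the interior points; ties break toward smaller K.  A
    curve that increases beyond tolerance is isotonically regressed
    (decreasing) first, with a warning.
    """
    k, s = curve.k_values.astype(float), curve.sse.astype(float)
    if k.size < 3:
        raise ValueError("elbow selection needs K = 1..Kmax with Kmax >= 3")
    if np.any(np.diff(s) > tol * max(s.max(), 1.0)):
        log.warning("SSE curve is non-monotone; applying isotonic regression")
        s = IsotonicRegression(increasing=False).fit_transform(k, s)
    kn = (k - k[0]) / (k[-1] - k[0])
    rng = s[0] - s[-1]
    sn = (s - s[-1]) / rng if rng > 0 else np.zeros_like(s)
    # chord joins (0, sn[0]) .. (1, sn[-1]); distance of interior points to it
    p0, p1 = np.array([0.0, sn[0]]), np.array([1.0, sn[-1]])
    d = p1 - p0
    d /= np.linalg.norm(d)
    pts = np.column_stack([kn, sn]) - p0
    dist = np.abs(pts[:, 0] * d[1] - pts[:, 1] * d[0])
    interior = slice(1, -1)
    best = int(np.argmax(np.round(dist[interior], 12))) + 1  # ties -> smaller K
    return int(k[best])


def habitat_masks(hmap: HabitatMap) -> tuple[list[Mask3D], np.ndarray]:
    """Split a habitat map into per-label masks plus volume fractions.

    Empty habitats are excluded with a warning (their features are
    undefined); fractions are over the full VOI and sum to 1 when no
    habitat is empty.
    """
    labels = hmap.labels.data
    n_voi = int((labels > 0).sum())
    masks, fracs = [], []
    for lab in range(1, hmap.n_clusters + 1):
        sel = labels == lab
        n = int(sel.sum())
        if n == 0:
            log.warning("habitat %d is empty; excluded", lab)
            continue
        masks.append(Mask3D(sel.astype(np.int16), hmap.labels.spacing, hmap.labels.origin))
        fracs.append(n / n_voi)
    return masks, np.asarray(fracs)
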