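"""First-order intensity statistics and fixed-bin-width discretisation."""

from __future__ import annotations

import numpy as np

from ..grid import Mask3D, Volume3D

__all__ = ["discretize", "first_order_features"]


def discretize(volume: Volume3D | np.ndarray, mask: Mask3D | np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Fixed-bin-width quantisation anchored at the within-mask minimum.

    Returns an integer grid with levels 1..N inside the mask, 0 outside,
    and the number of occupied-range levels N.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume, dtype=float)
    m = mask.voi if isinstance(mask, Mask3D) else np.asarray(mask) > 0
    if not m.any():
        raise ValueError("empty mask")
    vals = data[m]
    lev = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    # the maximum falls on a bin edge; fold it into the top bin
    n_levels = int(np.floor((vals.max() - vals.min()) / bin_width)) + 1
    lev = np.minimum(lev, n_levels)
    grid = np.zeros(data.shape, dtype=np.int64)
    grid[m] = lev
    return grid, n_levels


def first_order_features(
    volume: Volume3D | np.ndarray,
    mask: Mask3D | np.ndarray,
    bin_width: float = 25.0,
    voxel_volume: float | None = None,
) -> dict[str, float]:
    """The 18 first-order features (histogram features use ``bin_width``)."""
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume, dtype=float)
    m = mask.voi if isinstance(mask, Mask3D) else np.asarray(mask) > 0
    if not m.any():
        raise ValueError("empty mask")
    if voxel_volume is None:
        voxel_volume = volume.voxel_volume if isinstance(volume, Volume3D) else 1.0
    x = data[m].astype(float)
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    _, n_levels = discretize(data, m, bin_width)
    counts = np.bincount(
        np.minimum(np.floor((x - x.min()) / bin_width).astype(int), n_levels - 1)
    )
    p = counts[counts > 0] / n
    sd = np.sqrt(var)
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / sd**3 if sd > 0 else 0.0),
        "Kurtosis": float(m4 / var**2 if var > 0 else 0.0),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
    }
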