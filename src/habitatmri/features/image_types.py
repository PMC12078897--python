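"""The 21-image-type filter bank applied before intensity/texture features.

Derived image types (all on the original voxel grid): the original image,
8 single-level stationary-wavelet sub-bands (coif1; L = approximation,
H = detail per axis), Laplacian-of-Gaussian at sigma = 1..4 mm, four
monotone/pointwise intensity transforms (square, square root, logarithm,
exponential), the gradient magnitude, and three local-binary-pattern-style
neighbourhood maps (radius-1 sign fraction, radius-2 sign fraction, and
local neighbourhood kurtosis).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from ..grid import Mask3D, Volume3D
from .config import FeatureConfig

__all__ = ["build_image_types"]

_WAVELET_KEYS = {  # sub-band name -> pywt swtn key (a = lowpass, d = highpass)
    "LLL": "aaa", "LLH": "aad", "LHL": "ada", "LHH": "add",
    "HLL": "daa", "HLH": "dad", "HHL": "dda", "HHH": "ddd",
}

_OFFSETS_26 = [
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def _wavelet_bands(data: np.ndarray) -> dict[str, np.ndarray]:
    pads = [(0, n % 2) for n in data.shape]  # swt needs even extents
    padded = np.pad(data, pads, mode="edge")
    coeffs = pywt.swtn(padded, wavelet="coif1", level=1, start_level=0)[0]
    sl = tuple(slice(0, n) for n in data.shape)
    return {name: coeffs[key][sl] for name, key in _WAVELET_KEYS.items()}


def _neighbor_stack(data: np.ndarray, radius: int) -> np.ndarray:
    """Stack of the 26 neighbours at the given Chebyshev radius (edge padded)."""
    p = radius
    padded = np.pad(data, p, mode="edge")
    core = tuple(slice(p, p + n) for n in data.shape)
    stack = np.empty((26,) + data.shape)
    for a, (i, j, k) in enumerate(_OFFSETS_26):
        sl = tuple(
            slice(p + o * radius, p + o * radius + n)
            for o, n in zip((i, j, k), data.shape)
        )
        stack[a] = padded[sl]
    del core
    return stack


def _lbp_maps(data: np.ndarray) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for name, radius in (("lbp-3D-m1", 1), ("lbp-3D-m2", 2)):
        nb = _neighbor_stack(data, radius)
        out[name] = (nb >= data[None]).mean(axis=0)
    nb = _neighbor_stack(data, 1)
    mu = nb.mean(axis=0)
    var = nb.var(axis=0)
    m4 = ((nb - mu[None]) ** 4).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = np.where(var > 0, m4 / np.maximum(var, 1e-30) ** 2, 0.0)
    out["lbp-3D-k"] = kurt
    return out


def build_image_types(
    volume: Volume3D, mask: Mask3D | None = None, config: FeatureConfig | None = None
) -> dict[str, Volume3D]:
    """Return the configured derived images, each on the original grid."""
    config = config or FeatureConfig.default()
    data = np.asarray(volume.data, dtype=np.float64)
    wanted = set(config.image_types)
    out: dict[str, np.ndarray] = {}

    if "original" in wanted:
        out["original"] = data
    if any(t.startswith("wavelet") for t in wanted):
        out.update({f"wavelet-{k}": v for k, v in _wavelet_bands(data).items()})
    for t in wanted:
        if t.startswith("log-sigma"):
            sigma_mm = float(t.split("-")[2].replace("mm", ""))
            sigma_vox = [sigma_mm / s for s in volume.spacing]
            if any(sv >= n for sv, n in zip(sigma_vox, volume.shape)):
                raise ValueError(f"LoG sigma {sigma_mm} mm exceeds the volume extent")
            # sigma^2 normalisation keeps the response scale comparable
            # across sigmas (and compatible with the fixed bin width)
            out[t] = sigma_mm**2 * ndimage.gaussian_laplace(data, sigma_vox, mode="nearest")
    scale = max(float(np.abs(data).max()), 1e-12)
    if "square" in wanted:
        out["square"] = data**2 / scale  # rescaled to keep the original magnitude
    if "squareroot" in wanted:
        out["squareroot"] = np.sign(data) * np.sqrt(np.abs(data) * scale)
    if "logarithm" in wanted:
        out["logarithm"] = np.sign(data) * np.log1p(np.abs(data)) * scale / np.log1p(scale)
    if "exponential" in wanted:
        out["exponential"] = np.exp(data / scale) * scale / np.e
    if "gradient" in wanted:
        grads = np.gradient(data, *volume.spacing)
        out["gradient"] = np.sqrt(sum(g**2 for g in grads))
    if any(t.startswith("lbp") for t in wanted):
        # LBP maps live on [0, 1] (sign fractions) or ~[1, 10] (kurtosis);
        # rescale to the original magnitude so discretisation resolves them
        out.update({k: v * scale for k, v in _lbp_maps(data).items()})

    return {
        t: Volume3D(out[t], volume.spacing, volume.origin, volume.sequence)
        for t in config.image_types
    }
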