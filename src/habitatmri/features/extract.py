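"""Per-region feature vectors with provenance-tagged names.

Column names follow ``region|image_type|class|feature`` (shape features
use image type ``original``).  Each region of a preprocessed patient
yields ``config.total_features`` values (1904 with the full filter bank).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..grid import Mask3D, Volume3D
from .config import FeatureConfig
from .firstorder import discretize, first_order_features
from .image_types import build_image_types
from .shape import shape_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["feature_names", "region_features", "extract_feature_vector"]

log = logging.getLogger(__name__)

STANDARD_REGIONS = (
    "whole_T2WI", "whole_DWI",
    "T2WI_habitat1", "T2WI_habitat2", "DWI_habitat1", "DWI_habitat2",
)


def feature_names(region: str, config: FeatureConfig) -> list[str]:
    """The ordered provenance-tagged column names for one region."""
    names = [f"{region}|original|shape|{f}" for f in config.feature_lists["shape"]]
    for itype in config.image_types:
        for cls in ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm"):
            names += [f"{region}|{itype}|{cls}|{f}" for f in config.feature_lists[cls]]
    return names


def region_features(
    image_bank: dict[str, Volume3D],
    mask: Mask3D,
    config: FeatureConfig,
    region: str,
) -> dict[str, float]:
    """All features of one region given a prebuilt image-type bank."""
    from scipy import ndimage

    out: dict[str, float] = {}
    shp = shape_features(mask)
    for f in config.feature_lists["shape"]:
        out[f"{region}|original|shape|{f}"] = shp[f]
    # texture matrices only see the mask's bounding box (identical counts)
    bbox = ndimage.find_objects(mask.voi.astype(np.int8))[0]
    m_crop = mask.voi[bbox]
    vv = float(np.prod(mask.spacing))
    for itype in config.image_types:
        vol = image_bank[itype]
        crop = np.asarray(vol.data[bbox], dtype=float)
        fo = first_order_features(crop, m_crop, bin_width=config.bin_width, voxel_volume=vv)
        q, n_lev = discretize(crop, m_crop, config.bin_width)
        vals = {
            "firstorder": fo,
            "glcm": glcm_features(q, n_lev, config.directions, config.glcm_distance),
            "glrlm": glrlm_features(q, n_lev, config.directions),
            "glszm": glszm_features(q, n_lev),
            "gldm": gldm_features(q, n_lev),
            "ngtdm": ngtdm_features(q, n_lev),
        }
        for cls, d in vals.items():
            for f in config.feature_lists[cls]:
                out[f"{region}|{itype}|{cls}|{f}"] = d[f]
    return out


def extract_feature_vector(
    t2w: Volume3D,
    dwi: Volume3D,
    region_masks: dict[str, Mask3D],
    config: FeatureConfig | None = None,
) -> pd.Series:
    """Extract every region's features for one patient.

    ``region_masks`` maps region names (``whole_T2WI``, ``DWI_habitat2``,
    ...) to masks on the common preprocessed grid; the parent sequence is
    inferred from the region name.  Empty regions yield missing values
    with a warning.  The image-type bank is built once per sequence and
    shared across its regions.
    """
    config = config or FeatureConfig.default()
    banks: dict[str, dict[str, Volume3D]] = {}
    values: dict[str, float] = {}
    for region, mask in region_masks.items():
        seq = "T2WI" if "T2WI" in region else "DWI"
        parent = t2w if seq == "T2WI" else dwi
        if mask.n_voxels == 0:
            log.warning("region %s is empty; features reported missing", region)
            for name in feature_names(region, config):
                values[name] = float("nan")
            continue
        if seq not in banks:
            banks[seq] = build_image_types(parent, config=config)
        values.update(region_features(banks[seq], mask, config, region))
    ser = pd.Series(values, dtype=float)
    expected = len(region_masks) * config.total_features
    if ser.size != expected:
        raise RuntimeError(f"feature bookkeeping error: {ser.size} != {expected}")
    return ser
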