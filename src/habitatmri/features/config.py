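"""Feature-extraction configuration: filter bank, binning, feature name lists.

The default configuration fixes the feature budget: 14 shape features
(original image only) plus 90 intensity/texture features on each of 21
derived image types, 1904 in total, with per-class counts 378 (first
order), 441 (GLCM), 336 (GLRLM), 336 (GLSZM), 294 (GLDM) and 105 (NGTDM).
The totals are validated at construction and on every extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureConfig", "DIRECTIONS_13", "IMAGE_TYPES_21", "FEATURE_NAMES"]

# the 13 unique 3-D voxel offsets (first nonzero component positive)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

IMAGE_TYPES_21: tuple[str, ...] = (
    "original",
    "wavelet-LLL", "wavelet-LLH", "wavelet-LHL", "wavelet-LHH",
    "wavelet-HLL", "wavelet-HLH", "wavelet-HHL", "wavelet-HHH",
    "log-sigma-1mm", "log-sigma-2mm", "log-sigma-3mm", "log-sigma-4mm",
    "square", "squareroot", "logarithm", "exponential",
    "gradient",
    "lbp-3D-m1", "lbp-3D-m2", "lbp-3D-k",
)

FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
        "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    ),
    "shape": (
        "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
        "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
        "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
        "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
    ),
    "glcm": (
        "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
        "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
        "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
        "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
        "MaximumProbability", "SumEntropy",
    ),
    "glrlm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
        "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ),
    "glszm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy", "ZonePercentage", "ZoneVariance",
    ),
    "gldm": (
        "DependenceEntropy", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "DependenceVariance",
        "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
        "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ),
    "ngtdm": ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength"),
}

_NONSHAPE = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings; totals are validated at construction."""

    image_types: tuple[str, ...] = IMAGE_TYPES_21
    bin_width: float = 25.0
    glcm_distance: int = 1
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
    feature_lists: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(FEATURE_NAMES))

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        unknown = set(self.image_types) - set(IMAGE_TYPES_21)
        if unknown:
            raise ValueError(f"unknown image types: {sorted(unknown)}")
        if "original" not in self.image_types:
            raise ValueError("the original image type is required (shape features)")

    @property
    def n_per_image_type(self) -> int:
        return sum(len(self.feature_lists[c]) for c in _NONSHAPE)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: len(self.feature_lists[c]) * len(self.image_types) for c in _NONSHAPE}
        counts["shape"] = len(self.feature_lists["shape"])
        return counts

    @property
    def total_features(self) -> int:
        return self.class_counts["shape"] + self.n_per_image_type * len(self.image_types)

    @classmethod
    def default(cls) -> "FeatureConfig":
        cfg = cls()
        assert cfg.total_features == 14 + 90 * 21 == 1904
        return cfg

    @classmethod
    def original_only(cls) -> "FeatureConfig":
        """Reduced bank (original image only, 104 features/region) for fast runs."""
        return cls(image_types=("original",))
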