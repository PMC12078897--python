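"""Lightweight 3-D image containers and NIfTI round-trip helpers.

A :class:`Volume3D` is a scalar voxel grid with physical spacing and origin
(mm, axis-aligned); a :class:`Mask3D` is an integer label grid on the same
lattice.  Masks and habitat maps always live in the voxel-index space of
their parent volume; world coordinates appear only inside registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "Mask3D",
    "HabitatMap",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


@dataclass
class Volume3D:
    """3-D scalar image with voxel spacing (mm), origin (mm) and a sequence tag."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sequence: str | None = None  # "T2WI" | "DWI" | None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def copy(self, data: np.ndarray | None = None) -> "Volume3D":
        return replace(self, data=(self.data.copy() if data is None else data))

    def same_grid(self, other: "Volume3D | Mask3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class Mask3D:
    """Integer label grid aligned to a parent :class:`Volume3D`; VOI = nonzero."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("mask values must be integers")
            self.data = rounded.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voi(self) -> np.ndarray:
        """Boolean array of the volume of interest (nonzero labels)."""
        return self.data > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    def copy(self, data: np.ndarray | None = None) -> "Mask3D":
        return replace(self, data=(self.data.copy() if data is None else data))

    def same_grid(self, other: "Volume3D | Mask3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class HabitatMap:
    """Partition of a VOI into ordered intensity clusters.

    Labels are 0 outside the VOI and 1..K inside; label 1 is always the
    cluster with the highest mean intensity (the high-signal habitat).
    """

    labels: Mask3D
    sequence: str
    cluster_means: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.cluster_means = np.asarray(self.cluster_means, dtype=float)
        k = int(self.labels.data.max(initial=0))
        if self.cluster_means.size != k:
            raise ValueError(
                f"cluster_means has {self.cluster_means.size} entries for {k} labels"
            )
        if k >= 2 and not np.all(np.diff(self.cluster_means) <= 1e-9):
            raise ValueError("cluster means must be non-increasing with label")

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_means.size)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_volume(path, sequence: str | None = None) -> Volume3D:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return Volume3D(np.asarray(img.dataobj, dtype=np.float64), spacing, origin, sequence)


def write_mask(mask: Mask3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask.data, dtype=np.int16), _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def read_mask(path) -> Mask3D:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj)
    return Mask3D(np.rint(data).astype(np.int16), spacing, origin)


def check_same_grid(volume: Volume3D, mask: Mask3D, *, volume_name: str = "volume", mask_name: str = "mask") -> None:
    """Hard error naming both inputs when grids disagree."""
    if not volume.same_grid(mask):
        raise ValueError(
            f"grid mismatch between {volume_name} (shape {volume.shape}, spacing {volume.spacing}) "
            f"and {mask_name} (shape {mask.shape}, spacing {mask.spacing})"
        )
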