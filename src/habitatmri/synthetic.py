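"""Phantom multi-sequence MRI cohorts with planted habitat structure.

Every downstream stage of the pipeline (preprocessing, habitat clustering,
radiomics, grading models) is testable against ground truth planted here:
two intensity habitats per sequence with grade-dependent volume fractions
and spatial texture, smooth multiplicative bias fields, inter-sequence
misalignment, and a Table-1-style covariate mix with two covariates that
carry real grade effects.

The tumour is a sphere deformed by a smooth random radial perturbation;
the low-signal habitat (habitat 2) is planted as one or more coherent
blobs inside it so that intensity clustering recovers spatially contiguous
subregions.  Spatial texture is Gaussian-smoothed white noise whose
smoothing length is set from the requested lag-1 autocorrelation
(rho = exp(-1/(4 sigma^2)) for a Gaussian kernel of width sigma voxels),
so grade-dependent texture differences are measurable by co-occurrence
and gray-tone-difference features.

All randomness flows from one root seed through named substreams
(one per patient and purpose), so cohorts are reproducible and patients
can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .grid import Mask3D, Volume3D

__all__ = [
    "CovariateSpec",
    "CohortConfig",
    "SyntheticPatient",
    "generate_cohort",
    "generate_patient",
    "apply_artifacts",
    "generate_reader_tables",
    "covariate_table",
    "histogram_is_bimodal",
    "DEFAULT_COVARIATES",
]


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CovariateSpec:
    """A binary Table-1-style covariate with grade-conditional prevalence.

    ``threshold`` documents the positivity rule for laboratory markers
    (e.g. "CA19-9 > 39 U/mL"); it is descriptive only.
    """

    name: str
    prevalence_low: float
    prevalence_high: float
    threshold: str | None = None

    @property
    def log_odds_effect(self) -> float:
        """Planted high-vs-low grade log odds ratio."""
        pl, ph = self.prevalence_low, self.prevalence_high
        return float(np.log(ph / (1 - ph)) - np.log(pl / (1 - pl)))


# Variable mix modelled on a liver-tumour grading cohort: four serum markers
# with published positivity thresholds, morphological and signal-pattern
# imaging reads.  Only tumour margin and the T2WI signal pattern carry
# substantive grade effects; the rest are near-null background covariates.
DEFAULT_COVARIATES: tuple[CovariateSpec, ...] = (
    CovariateSpec("sex_male", 0.26, 0.35),
    CovariateSpec("ca19_9_positive", 0.56, 0.64, "CA19-9 > 39 U/mL"),
    CovariateSpec("cea_positive", 0.41, 0.34, "CEA > 4.7 ng/mL"),
    CovariateSpec("afp_positive", 0.32, 0.25, "AFP > 7 ng/mL"),
    CovariateSpec("ca12_5_positive", 0.61, 0.72, "CA12-5 > 35 U/mL"),
    CovariateSpec("tumor_margin_infiltrative", 0.60, 0.30),
    CovariateSpec("t2wi_boundary_blurry", 0.45, 0.40),
    CovariateSpec("bile_duct_dilatation", 0.39, 0.46),
    CovariateSpec("capsule_retraction", 0.37, 0.38),
    CovariateSpec("tumor_thrombus", 0.47, 0.36),
    CovariateSpec("vascular_traversal_sign", 0.33, 0.28),
    CovariateSpec("enlarged_lymph_nodes", 0.20, 0.22),
    CovariateSpec("t2wi_targetoid_sign", 0.45, 0.75),
    CovariateSpec("dwi_targetoid_sign", 0.69, 0.63),
)


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_patients: int = 100
    prevalence_high: float = 0.65
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range: tuple[float, float] = (6.0, 10.0)  # mm
    # (habitat1, habitat2) volume fractions; habitat2 = low-signal blobs
    habitat_fraction_low: tuple[float, float] = (0.82, 0.18)
    habitat_fraction_high: tuple[float, float] = (0.68, 0.32)
    # per-sequence (habitat1, habitat2) mean intensities, habitat1 > habitat2
    intensity_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"T2WI": (220.0, 120.0), "DWI": (200.0, 100.0)}
    )
    intensity_sd: float = 25.0
    # lag-1 spatial autocorrelation of the within-VOI noise, per grade
    texture_correlation_low: float = 0.30
    texture_correlation_high: float = 0.60
    texture_correlation_jitter: float = 0.10  # per-patient sd of the autocorrelation
    # (sequence, habitat) regions carrying the grade-dependent texture effect
    texture_regions: tuple[tuple[str, int], ...] = (
        ("T2WI", 1), ("T2WI", 2), ("DWI", 1), ("DWI", 2),
    )
    bias_amplitude: float = 0.3
    misalignment_shift: tuple[float, float, float] = (3.0, 0.0, 0.0)  # mm
    misalignment_warp: float = 1.0  # mm, smooth-warp amplitude (10-voxel scale)
    covariate_spec: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    fraction_concentration: float = 25.0  # Beta concentration of per-patient fractions
    seed: int = 7

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 < self.prevalence_high < 1.0:
            raise ConfigurationError("prevalence_high must lie in (0, 1)")
        if any(s < 8 for s in self.volume_shape):
            raise ConfigurationError("volume_shape too small for a tumour phantom")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacings must be positive")
        for fr in (self.habitat_fraction_low, self.habitat_fraction_high):
            if abs(sum(fr) - 1.0) > 1e-9 or any(f <= 0 for f in fr):
                raise ConfigurationError(f"habitat fractions {fr} must be positive and sum to 1")
        for seq, (m1, m2) in self.intensity_means.items():
            if not m1 > m2:
                raise ConfigurationError(
                    f"{seq}: habitat1 mean ({m1}) must exceed habitat2 mean ({m2})"
                )
        for rho in (self.texture_correlation_low, self.texture_correlation_high):
            if not 0.0 <= rho < 1.0:
                raise ConfigurationError("texture correlations must lie in [0, 1)")
        if self.bias_amplitude < 0:
            raise ConfigurationError("bias_amplitude must be >= 0")
        if self.tumor_radius_range[0] > self.tumor_radius_range[1] or self.tumor_radius_range[0] <= 0:
            raise ConfigurationError("invalid tumor_radius_range")


@dataclass
class SyntheticPatient:
    id: str
    grade: int  # 0 low, 1 high
    t2w: Volume3D
    dwi: Volume3D
    voi: Mask3D  # drawn in the DWI frame (moves with DWI under misalignment)
    true_habitat_map: dict[str, Mask3D]  # per sequence, clean frame
    covariates: dict[str, float]
    applied_bias: dict[str, Volume3D] | None = None
    applied_transform: dict | None = None
    true_habitat_fraction: dict[str, float] = field(default_factory=dict)


def _substream(root_seed: int, *names) -> np.random.Generator:
    """Named, collision-resistant child stream of the root seed."""
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), *keys]))


def _smooth_noise(rng: np.random.Generator, shape, sigma_vox: float) -> np.ndarray:
    """Gaussian-smoothed white noise, renormalised to unit variance."""
    w = rng.standard_normal(shape)
    if sigma_vox <= 1e-6:
        return w
    s = ndimage.gaussian_filter(w, sigma_vox, mode="reflect")
    return s / max(s.std(), 1e-12)


def _autocorr_sigma(rho: float) -> float:
    """Kernel width (voxels) giving lag-1 autocorrelation rho."""
    if rho <= 0.0:
        return 0.0
    return float(np.sqrt(-1.0 / (4.0 * np.log(rho))))


def _tumor_mask(rng: np.random.Generator, shape, spacing, radius_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Deformed-sphere VOI; returns (boolean mask, centre in voxels)."""
    shape = np.asarray(shape)
    jitter = rng.uniform(-0.07, 0.07, size=3) * shape
    center = shape / 2.0 + jitter
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r = np.sqrt(sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing)))
    pert = _smooth_noise(rng, tuple(shape), sigma_vox=5.0) * 0.12 * radius_mm
    mask = (r - radius_mm + pert) < 0
    # keep the perturbation from disconnecting or emptying the VOI
    mask |= r < 0.4 * radius_mm
    lab, n = ndimage.label(mask)
    if n > 1:
        keep = np.argmax(ndimage.sum(mask, lab, range(1, n + 1))) + 1
        mask = lab == keep
    return mask, center


def _habitat_partition(
    rng: np.random.Generator, voi: np.ndarray, spacing, fraction2: float
) -> np.ndarray:
    """Labels 1 (high signal) / 2 (low-signal blobs) over the VOI voxels."""
    labels = np.zeros(voi.shape, dtype=np.int16)
    labels[voi] = 1
    if fraction2 <= 0:
        return labels
    idx = np.argwhere(voi)
    n_blobs = 1 + min(int(rng.poisson(0.7)), 2)
    centers = idx[rng.choice(len(idx), size=min(n_blobs, len(idx)), replace=False)]
    grids = np.meshgrid(*[np.arange(n) for n in voi.shape], indexing="ij")
    dist = np.full(voi.shape, np.inf)
    for c in centers:
        d = np.sqrt(sum(((g - cc) * s) ** 2 for g, cc, s in zip(grids, c, spacing)))
        dist = np.minimum(dist, d)
    dist = dist + _smooth_noise(rng, voi.shape, 3.0) * 1.0
    # quantile threshold plants the habitat-2 volume fraction exactly
    q = np.quantile(dist[voi], fraction2)
    labels[voi & (dist <= q)] = 2
    if not (labels == 2).any():  # degenerate tiny VOI
        labels[tuple(centers[0])] = 2
    return labels


def generate_patient(config: CohortConfig, index: int, grade: int) -> SyntheticPatient:
    """Generate one clean (artifact-free) patient from its named substream."""
    rng = _substream(config.seed, "patient", index)
    shape, spacing = config.volume_shape, config.spacing
    radius = rng.uniform(*config.tumor_radius_range)
    voi, _ = _tumor_mask(rng, shape, spacing, radius)

    fr2_mean = (config.habitat_fraction_high if grade else config.habitat_fraction_low)[1]
    conc = config.fraction_concentration
    rho_grade = config.texture_correlation_high if grade else config.texture_correlation_low
    rho_patient = float(
        np.clip(rng.normal(rho_grade, config.texture_correlation_jitter), 0.02, 0.88)
    )
    rho_null = config.texture_correlation_low  # regions without a planted effect

    habitat_maps: dict[str, Mask3D] = {}
    fractions: dict[str, float] = {}
    volumes: dict[str, Volume3D] = {}
    for seq in ("T2WI", "DWI"):
        fr2 = float(rng.beta(fr2_mean * conc, (1 - fr2_mean) * conc))
        labels = _habitat_partition(rng, voi, spacing, fr2)
        m1, m2 = config.intensity_means[seq]
        shift = rng.normal(0.0, 0.2 * config.intensity_sd)  # nuisance global offset
        base = np.full(shape, 0.5 * m2)  # background parenchyma, distinct mean
        base += _smooth_noise(rng, shape, 1.0) * 0.4 * config.intensity_sd
        vals = np.where(labels == 1, m1, m2) + shift
        noise_eff = _smooth_noise(rng, shape, _autocorr_sigma(rho_patient)) * config.intensity_sd
        noise_null = _smooth_noise(rng, shape, _autocorr_sigma(rho_null)) * config.intensity_sd
        noise = noise_null
        for hab in (1, 2):
            if (seq, hab) in config.texture_regions:
                noise = np.where(labels == hab, noise_eff, noise)
        base[voi] = (vals + noise)[voi]
        np.clip(base, 1.0, None, out=base)
        volumes[seq] = Volume3D(base, spacing, sequence=seq)
        habitat_maps[seq] = Mask3D(labels, spacing)
        fractions[seq] = float((labels == 2).sum() / voi.sum())

    covs = {"age": float(np.clip(rng.normal(58.6, 9.6), 25, 90))}
    for spec in config.covariate_spec:
        p = spec.prevalence_high if grade else spec.prevalence_low
        covs[spec.name] = float(rng.random() < p)

    return SyntheticPatient(
        id=f"P{index:04d}",
        grade=int(grade),
        t2w=volumes["T2WI"],
        dwi=volumes["DWI"],
        voi=Mask3D((voi).astype(np.int16), spacing),
        true_habitat_map=habitat_maps,
        covariates=covs,
        true_habitat_fraction=fractions,
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate the full cohort; deterministic given ``config.seed``."""
    config.validate()
    g_rng = _substream(config.seed, "grades")
    grades = (g_rng.random(config.n_patients) < config.prevalence_high).astype(int)
    return [generate_patient(config, i, g) for i, g in enumerate(grades)]


def _polynomial_field(rng: np.random.Generator, shape, order: int = 2) -> np.ndarray:
    """Random low-order polynomial field, zero mean, unit max amplitude."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    fld = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i == j == k == 0:
                    continue
                fld += rng.normal() * (X**i) * (Y**j) * (Z**k)
    fld -= fld.mean()
    return fld / max(np.abs(fld).max(), 1e-12)


def apply_artifacts(patient: SyntheticPatient, config: CohortConfig) -> SyntheticPatient:
    """Degrade a clean patient: multiplicative bias + DWI misalignment.

    The VOI was drawn on DWI, so the mask moves with the DWI volume; the
    applied bias fields and transform are stored as ground truth so that
    preprocessing contracts (bias-CV reduction, shift recovery) can be
    tested against them.
    """
    if config.bias_amplitude < 0:
        raise ConfigurationError("bias_amplitude must be >= 0")
    idx = int(patient.id[1:])
    rng = _substream(config.seed, "artifacts", idx)
    shape, spacing = patient.t2w.shape, patient.t2w.spacing

    out = replace(patient)
    biases: dict[str, Volume3D] = {}
    vols = {"T2WI": patient.t2w.copy(), "DWI": patient.dwi.copy()}
    for seq in ("T2WI", "DWI"):
        fld = _polynomial_field(rng, shape)
        bias = 1.0 + config.bias_amplitude * fld
        biases[seq] = Volume3D(bias, spacing)
        if config.bias_amplitude > 0:
            vols[seq] = vols[seq].copy(vols[seq].data * bias)

    shift_vox = np.asarray(config.misalignment_shift) / np.asarray(spacing)
    warp_amp = config.misalignment_warp
    warp = None
    if np.any(shift_vox != 0) or warp_amp > 0:
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        disp = []
        for ax in range(3):
            d = np.full(shape, shift_vox[ax])
            if warp_amp > 0:
                d = d + _smooth_noise(rng, shape, 10.0) * (warp_amp / spacing[ax])
            disp.append(d)
        warp = disp
        # forward model: output(x) = input(x - displacement(x))
        sample = [g - d for g, d in zip(grids, disp)]
        vols["DWI"] = vols["DWI"].copy(
            ndimage.map_coordinates(vols["DWI"].data, sample, order=3, mode="nearest")
        )
        out.voi = patient.voi.copy(
            ndimage.map_coordinates(patient.voi.data, sample, order=0, mode="constant").astype(np.int16)
        )
    out.t2w, out.dwi = vols["T2WI"], vols["DWI"]
    out.applied_bias = biases
    out.applied_transform = {
        "shift_mm": tuple(float(s) for s in config.misalignment_shift),
        "warp_amplitude_mm": float(warp_amp),
        "displacement_vox": warp,
    }
    return out


def covariate_table(cohort: list[SyntheticPatient]) -> pd.DataFrame:
    """Patient covariates + grade label as a tidy DataFrame (index = id)."""
    rows = [{"id": p.id, "grade": p.grade, **p.covariates} for p in cohort]
    return pd.DataFrame(rows).set_index("id")


def generate_reader_tables(
    cohort: list[SyntheticPatient],
    n_readers: int = 2,
    continuous_sd: float = 0.0,
    flip_probability: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired reader tables with a known agreement level.

    Continuous measurements are the true tumour volume (mL) plus i.i.d.
    reader noise; categorical calls are the true grade flipped with the
    stated probability, so the expected ICC and kappa are known in closed
    form (ICC = var_true / (var_true + sd^2); kappa -> 0 at flip 0.5).
    """
    if n_readers != 2:
        raise ConfigurationError("reader tables are defined for exactly 2 readers")
    if not 0.0 <= flip_probability <= 1.0 or continuous_sd < 0:
        raise ConfigurationError("invalid reader-noise settings")
    rng = np.random.default_rng(seed)
    truth_cont = np.array([p.voi.n_voxels * p.t2w.voxel_volume / 1000.0 for p in cohort])
    truth_cat = np.array([p.grade for p in cohort])
    cont = {"id": [p.id for p in cohort]}
    cat = {"id": [p.id for p in cohort]}
    for r in range(n_readers):
        cont[f"reader{r + 1}"] = truth_cont + rng.normal(0.0, continuous_sd, len(cohort))
        flips = rng.random(len(cohort)) < flip_probability
        cat[f"reader{r + 1}"] = np.where(flips, 1 - truth_cat, truth_cat)
    return pd.DataFrame(cont).set_index("id"), pd.DataFrame(cat).set_index("id")


def histogram_is_bimodal(values: np.ndarray, n_bins: int = 48) -> bool:
    """Dip-style check: does a smoothed histogram show two separated modes?"""
    values = np.asarray(values, dtype=float).ravel()
    hist, _ = np.histogram(values, bins=n_bins)
    smooth = ndimage.gaussian_filter1d(hist.astype(float), 1.5)
    peaks, props = signal.find_peaks(smooth, prominence=0.05 * smooth.max())
    return len(peaks) >= 2
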