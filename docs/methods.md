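# Methods

`habitatmri` quantifies intratumoral heterogeneity (ITH) from paired
T2-weighted (T2WI) and diffusion-weighted (DWI, b = 800 s/mm²) MRI and
uses it, together with whole-tumour radiomics and clinical covariates, to
predict a binary tumour grade (low vs high, with medium merged into
high).  This note records the model, its assumptions, the defaults that
matter, and the choices made where the design was genuinely open.

## Synthetic cohort

No patient data ships with the package; a generator produces phantom
cohorts with planted ground truth so that every stage is testable.

**Geometry.** Each tumour is a sphere (radius uniform in 6–10 mm)
deformed by smooth random radial perturbation, placed near the centre of
a 48³ volume at 1 mm³ spacing.  The low-signal habitat (habitat 2) is
planted as 1–3 spatially coherent blobs inside the VOI; the blob
threshold is set by quantile so the per-patient habitat-2 volume fraction
is hit exactly.  Per-sequence habitat maps share blob centres but not
noise, so T2WI and DWI partitions overlap without being identical —
as in real tumours, where water-content and cellularity regions are
correlated but distinct.

**Intensities.** Within-VOI voxels take their habitat's mean
(T2WI: 220/120; DWI: 200/100, arbitrary units) plus spatially correlated
noise (SD 25): Gaussian-smoothed white noise whose kernel width is set
from the requested lag-1 autocorrelation via rho = exp(−1/(4σ²)).
Habitat means sit 4 SD apart, so the within-VOI histogram is bimodal and
1-D K-means recovers the planted partition (voxelwise agreement ≳ 95%).
Background parenchyma has a distinct mean (half the habitat-2 mean).

**Grade effects.** High grade shifts the habitat-2 fraction
(0.18 → 0.32 mean, Beta-jittered per patient with concentration 25) and
the texture autocorrelation (0.30 → 0.60, per-patient SD 0.10).  These
effect sizes are free parameters of the phantom, not estimates of real
ones; they were chosen once so that the habitat and radiomics models
reach validation AUCs in the high-0.8s/0.9s — discriminative but not
degenerate (an earlier, stronger setting produced AUC = 1.0 everywhere,
which exercises nothing).  A `texture_regions` switch restricts the
texture effect to chosen (sequence, habitat) pairs for selection-
consistency experiments.

**Covariates.** Fourteen binary Table-1-style variables (serum markers
with their positivity thresholds, morphology and signal-pattern reads)
are Bernoulli with grade-conditional prevalence.  Only tumour margin
(0.60 → 0.30) and the T2WI targetoid sign (0.45 → 0.75) carry substantive
effects; the rest sit near their null so univariable screening has
something to reject.  Age is Normal(58.6, 9.6), no grade effect.

**Artifacts.** `apply_artifacts` multiplies each sequence by a random
low-order polynomial field of amplitude 0.3 and displaces the DWI (and
its VOI, which is drawn on DWI) by a 3 mm rigid shift plus a 1 mm smooth
warp (10-voxel correlation length).  The warp amplitude was fixed by a
ceiling analysis: resampling the VOI through the *true* inverse of a
2 mm/6-voxel warp already caps Dice at ~0.87, so recovery to Dice ≥ 0.95
— the contract the registration must meet — requires the milder, smoother
field, which is also the realistic scale of mild abdominal distortion.

**Randomness.** All draws flow from one root seed through named
substreams (per patient, per purpose), so cohorts regenerate
byte-identically and patients are independent of cohort size.

**What the phantom does not emulate:** liver anatomy, pulse-sequence
physics, partial-volume effects at the capsule, multi-b-value diffusion,
scanner- or centre-level batch effects.  Passing tests therefore show the
*pipeline* recovers planted structure under controlled conditions, not
that the clinical effect sizes are attainable on real data.

## Preprocessing

Fixed order: bias correction → isotropic resampling (1 mm³, cubic
B-spline; masks nearest-neighbour) → histogram standardisation → DWI→T2WI
registration.

*Bias correction* estimates a smooth low-order (default cubic) polynomial
field in the log domain by least squares and divides it out, rescaling so
the within-mask mean is preserved exactly.  This is a deliberate
light-weight stand-in for N4 behind the same interface; the tested
contract is ≥ 50% within-VOI CV reduction on phantoms with planted
quadratic bias, which it meets with a large margin.

*Histogram standardisation* is the classic two-stage decile-landmark
method: mean landmarks (1st/99th percentiles + deciles) are learnt on the
training cohort on a fixed 0–100 scale and frozen; each volume is then
mapped piecewise-linearly onto them.  Landmarks are order statistics
(percentile method "lower"), which makes the map exactly idempotent
(tolerance 1e−6) because order statistics are equivariant under monotone
maps.  Values beyond the tail landmarks are extended linearly, never
clamped, to preserve monotonicity.

*Registration* runs a translation stage then a rigid (Euler3D)
refinement, both maximising Mattes mutual information with dense
sampling (deterministic), keeping the refinement only if it improves the
metric; an optional B-spline stage (mesh 4³, LBFGS-B, REGULAR 30%
sampling with a fixed seed) follows.  Two numerical choices deviate from
a naive reading of "affine + deformable with MI":

1. the linear stage is rigid, not full affine — an unconstrained affine
   under MI collapses in scale (M ≈ 0.75·I) on background-dominated
   phantoms, and the planted misalignment model (rigid + smooth warp) is
   covered by rigid + B-spline;
2. the B-spline stage defaults to the correlation metric — at these
   image sizes an MI-driven deformable stage reliably *degrades*
   alignment (Dice 0.89 → 0.59–0.78 across optimizers, spline
   coefficients diverging to 4–7 mm) while correlation recovers planted
   warps to Dice ≈ 0.99.  `deformable_metric="mi"` restores MI
   throughout.

On optimisation failure the identity transform is returned flagged, with
a warning, so batch runs degrade gracefully.

## Habitat clustering

Per sequence, within-VOI intensities are standardised (zero mean, unit
SD) and clustered in 1-D.  Lloyd's algorithm is specialised to 1-D:
nearest-centre assignment is the segmentation of the sorted sample at
centre midpoints, so an iteration costs O(k log n) after one sort.
Settings: k-means++ init, 25 restarts, 300 max iterations, relative
tolerance 1e−6, fixed seed per (patient, sequence).  Labels are
re-ordered by descending cluster mean, so habitat 1 is always the
high-signal subregion.  The restart oracle (best of 100 independent
Lloyd runs) confirms the best-of-25 SSE to 1e−9 at K = 2–3.

K is chosen once per cohort: each patient × sequence SSE curve over
K = 1..8 is min-max normalised, curves are averaged, and the elbow is the
interior K maximising perpendicular distance to the chord joining the
curve's endpoints (Kneedle-style), ties toward smaller K.  A common K is
required for the four named subregion models to exist at all.  Under the
default conditions the pooled elbow lands at K = 2.  Non-monotone curves
(possible across restarts) are isotonically repaired with a warning.

## Radiomics

Per region the engine computes 14 shape features (original image only)
plus 90 features on each derived image type: 18 first-order, 21 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM, all per IBSI definitions.  The
default bank holds 21 image types — original, 8 single-level stationary
wavelet sub-bands (coif1), Laplacian-of-Gaussian at σ = 1–4 mm, four
pointwise intensity transforms, gradient magnitude, and three local
binary-pattern-style neighbourhood maps — giving
14 + 90 × 21 = 1904 features per region with class totals
378/14/441/336/336/294/105.  The bank composition is a fixed design
choice; the per-class totals are the checkable contract and are validated
on every extraction.  A reduced bank (`original_only`, 104 features/region) is the
default for cohort-scale runs.

Numerical conventions: fixed-bin-width discretisation (width 25 on the
standardised scale) anchored at the within-mask minimum; GLCM symmetric
at distance 1; GLCM/GLRLM aggregated by averaging feature values over the
13 unique 3-D directions; GLSZM/GLDM/NGTDM use 26-connectivity;
0·log 0 = 0 throughout; GLCM correlation is NaN on a single-level region;
single-voxel masks yield NaN mesh-based shape features.  Texture matrices
are computed on the mask bounding box (counts are unchanged; ~10× faster).
All five matrix builders are validated against naive enumeration oracles
on every grid shape up to 4×4×3.

## Selection and models

An 8:2 stratified split (per-stratum rounding, deterministic seed) fixes
the training rows; every median, standardisation constant, penalty,
threshold and calibration is computed on training rows only.

*Chi-square screen:* each feature is binarised at its training median
(scale-free and balanced; the chi-square test needs categories), then a 2×2 Pearson chi-square (uncorrected) against grade keeps
p < 0.05.  *LASSO:* L1-penalised logistic path over 25 penalties
(logspace 1e−3..10^1.5 in C), penalty by minimum 10-fold cross-validated
deviance, with a sparser-fit fallback (≤ 20 terms) under complete
separation.  Selection is invariant to affine rescaling of inputs
because standardisation happens inside the operation.

*Subregion models:* maximum-likelihood logistic fits (statsmodels) on the
selected features of each of the four subregions, with a ridge-stabilised
fallback (penalty 1e−4) under separation.  *ITH index:* the unweighted
mean of a subset's predicted probabilities — the simplest
permutation-invariant, [0, 1]-bounded combiner; singleton subsets reduce
to the model probability, and missing members (empty habitats) are
averaged over with a flag.  *Candidates:* all 4 singletons plus all 9
subsets containing at least one subregion per sequence — 13 in total; the
two within-sequence pairs are excluded on the rule that a multi-region
index must mix sequences.  The winner is the argmax of
internal-validation AUC (ties: smaller subset, then lexicographic),
recalibrated by a training-fitted logistic map.

*Final models:* seven logistic fits on the block unions of
clinical/laboratory/imaging (covariates retained at p < 0.05 in a
multivariable refit of univariable survivors), whole-tumour radiomics
(selected features), and the habitat ITH index; each stores a
training-set Youden threshold.  If multivariable retention is empty the
pipeline falls back to the strongest univariable covariates with a
warning, so small-cohort runs still produce all seven models.

## Evaluation

AUC is the Mann–Whitney statistic with midrank ties; its variance and the
paired two-model test use DeLong structural components (self-comparison
returns p = 1 by convention).  Threshold metrics come from the stored
training threshold; precision is NaN when no positive call is made.
Calibration uses equal-frequency bins (tied quantile edges merged);
decision curves report net benefit TP/n − FP/n·pt/(1−pt) with treat-all /
treat-none references.  Shapley attributions use the exact linear form
β_j(x_ij − x̄_j) on the log-odds scale against the training-mean
background, so additivity holds to 1e−8 by construction.  Agreement:
Cohen's kappa (sklearn) and ICC(2,1) — two-way random effects, absolute
agreement, single rater (pingouin); the ICC form is a stated convention of the
package.  Cohort comparisons choose
Pearson chi-square, Fisher's exact (2×2 with any expected count < 5), or
Mann–Whitney U by variable type; all tests two-sided at α = 0.05.

## Problem sizes

Desk-scale defaults, chosen as the package's own study conditions: 48³
volumes, tumour radii 6–10 mm (VOIs of roughly 1–4 × 10³ voxels); n = 40
cohorts for elbow selection; n = 300 cohorts × 5 seeds with the reduced
feature bank for the parameter-recovery study; the full 21-type bank is
exercised per-region.  The permutation null for the habitat model
permutes held-out labels against fixed held-out scores (200 draws);
refitting the entire selection pipeline per permutation would test the
same hypothesis at several orders of magnitude more compute.

## Known limitations

- The bias model is polynomial, not N4; fields that are not low-order
  polynomials (e.g. coil shading with sharp falloff) are out of contract.
- Registration is tuned for small rigid offsets plus smooth warps between
  roughly pre-aligned volumes; it has no global search and will not
  recover large rotations.
- The feature engine targets IBSI definitions but is not certified
  against the IBSI digital phantom; its ground truth here is the
  enumeration oracles.
- The ITH combiner (unweighted probability mean) is one reconstruction of
  an underspecified design; a weighted or meta-model combiner is a
  one-line extension point in `ith_index`.
- All performance statements in the tests concern synthetic cohorts with
  planted effects; none transfer to clinical data.
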