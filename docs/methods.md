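# Methods

`nodtex` is a fully synthetic re-creation of a classic CT radiomics
reproducibility experiment: spherical lung-nodule phantoms of known density
are imaged under every combination of slice thickness, tube current–time
product (mAs) and reconstruction kernel, a 20-feature histogram / GLCM /
GLRLM panel is extracted from each segmented nodule, and the effect of each
scan parameter on each feature is quantified by dummy-coded multiple
regression and Cohen's d. Because the original experiment used a physical
anthropomorphic thorax phantom and a clinical scanner, every upstream stage
here is a simulation; the point of the package is that the *downstream*
machinery — segmentation, 3D texture features, and the effect-size
statistics — is exact, tested, and reusable on real volumes.

## The phantom and image-formation model

**Scene.** A lung-like background (default −850 HU, configurable; real
inflated-lung foam sits around −800 to −900 HU) inside a soft-tissue rim
(+40 HU), containing four spherical nodules: 10 mm and 12 mm diameters at
each of two densities, +100 HU ("solid") and −630 HU ("ground-glass"). Per
repetition the four nodules are relocated by an isotropic Gaussian jitter
(default SD 2 mm), emulating the physical repositioning between repeat
scans; the same arrangement is then rendered under all 12 protocols, exactly
as one raw scan reconstructed 12 ways.

**Design.** The full factorial: slice thickness {1.25, 2.5, 5.0} mm × tube
current {30, 120} mAs × kernel {lung, standard} = 12 protocols, each
repeated 10 times by default (120 scans, 480 nodule observations, 240 per
density stratum). Seeding is splittable: a master seed spawns one child seed
per scan through `numpy.random.SeedSequence` spawn keys, so any single scan
is reproducible in isolation and the whole study is byte-reproducible.

**Rendering.** Three steps, in order:

1. *Partial volume.* Spheres are rasterized as fractional occupancy per
   protocol voxel, computed by averaging subsample points on a grid refined
   to ≤ 0.25 mm per axis (block averaging of a supersampled rasterization).
   In-plane pixels are 0.7 × 0.7 mm (a typical thorax FOV on a 512 grid);
   the z spacing equals the slice thickness, so thick slices dilute the
   nodule boundary exactly as the partial-volume effect does.
2. *Point-spread blur.* An in-plane Gaussian PSF: σ = 0.6 mm for the smooth
   "standard" kernel and σ = 0.3 mm for the sharp "lung" kernel (FWHM ≈ 1.4
   and 0.7 mm, typical for thorax reconstructions), the lung kernel adding
   an unsharp-mask high-pass term (gain 0.6 against a 1.0 mm blur) to mimic
   edge enhancement.
3. *Noise.* Zero-mean Gaussian noise with
   σ(T, mAs, kernel) = σ_ref · √(mAs_ref/mAs) · √(T_ref/T) · k(kernel),
   with σ_ref = 12 HU at 120 mAs / 5.0 mm, k(standard) = 1, k(lung) = 2.
   This is the standard quantum-noise scaling (photon count proportional to
   dose and slice thickness) plus a kernel noise multiplier; the constants
   are calibrated only to reproduce the qualitative orderings a scanner
   shows — noise falls with mAs and thickness, sharp kernels are noisier —
   not any measured scanner curve.

Nodule interiors receive a low-amplitude correlated Gaussian random field
(SD 5 HU, correlation length 2 mm, configurable, 0 allowed) so texture
features are non-degenerate; it is redrawn per scan rather than being a
fixed physical texture of each insert, which slightly understates the
between-protocol correlation a physical nodule would show but leaves
per-protocol means untouched. HU values are clamped to the representable
window [−1024, 3071] (4,096 integer levels).

Ground truth: a voxel belongs to a nodule's mask iff its unblurred
occupancy is ≥ 50%. These masks ship with every rendered volume.

**What the simulation does not model:** no sinogram-domain physics, no beam
hardening or streak artifacts, no slice-sensitivity profile (partial volume
is purely geometric block averaging), no vasculature attached to the
nodules, no spatially correlated noise. Consequently, passing tests show
that the analysis machinery is correct and that it responds to
noise/partial-volume effects in the modeled directions — not that real
scanner data would produce any particular coefficient value.

## Segmentation

Seeded region growing with a frozen inclusion rule: a voxel joins the
region iff its HU lies in a fixed interval and it is 26-connected to the
seed through admissible voxels. Freezing the interval before growth makes
the result exactly the 26-connected component of the thresholded volume
containing the seed — order-independent, idempotent, and monotone in the
interval — which we compute via `scipy.ndimage.label`. A `seed_adaptive`
mode derives the interval from the seed's 3×3×3 neighbourhood (mean ±
k·SD), then freezes it. Seeds are placed automatically at the maximal-HU
voxel within 5 mm of the expected centre (ties broken lexicographically).

The default intervals implement the half-contrast (full-width-at-
half-maximum) sizing rule used in nodule volumetry: the active bound is the
midpoint between nodule density and background — [−375, +400] HU for solid
and [−740, −400] HU for ground-glass nodules against a −850 HU background.
The half-contrast contour is the one contour a symmetric in-plane blur does
not move, so the grown region matches the ≥ 50%-occupancy ground truth;
thresholds placed well off the midpoint systematically include only the
high-occupancy core (or the low-occupancy halo) and cap the achievable Dice
overlap regardless of blur. On noise-free renders at 1.25 mm slices the
defaults give Dice ≥ 0.98 and volumes within a few percent of (4/3)πr³ for
both diameters and both densities.

In the pipeline, growth operates on a lightly smoothed copy (in-plane
Gaussian, 1 mm) restricted to a local VOI box around the expected position
(nodule radius + 6 mm). Both are the automated stand-in for the
radiologist's visual inspection and manual editing in the original
workflow: at the noisiest protocol (1.25 mm / 30 mAs / lung, σ = 96 HU)
unsmoothed thresholding percolates through the background, while after
smoothing the background admission probability drops below the 3D
percolation threshold. Features are always extracted from the *unsmoothed*
volume. Masks failing QC (sphericity ≤ 0.6, volume outside [50, 5000] mm³,
boundary leak) are flagged, never edited; if growth fails outright the
ground-truth mask is substituted and flagged as such.

## Texture features

Quantization is a fixed global window, g = floor((HU + 1024)/16), mapping
the 4,096 representable HU levels uniformly onto 256 gray levels. A fixed
window (rather than per-ROI min–max) keeps features comparable across
protocols, which is the entire object of study.

*Histogram (7):* mean, SD, variance, skewness, kurtosis, energy, entropy.
Moments are population moments of the per-voxel quantized values; kurtosis
is excess kurtosis (normal = 0); energy Σp² and Shannon entropy −Σp·log₂p
are over the 256-bin normalized histogram.

*GLCM (8):* contrast, dissimilarity, homogeneity, angular second moment,
energy = √ASM, maximal probability, entropy, correlation. One matrix per
direction: every ordered voxel pair (p, p+d) with both endpoints in the
mask increments counts[g(p), g(p+d)] — single-direction (asymmetric)
accumulation, matching the worked example that defines the matrices;
symmetric accumulation is available behind a flag. Correlation is defined
as 1 when a marginal SD vanishes (all pairs at one gray level).

*GLRLM (5):* long-runs emphasis, gray-level nonuniformity, run-length
nonuniformity, low- and high-gray-level run emphasis. The ROI is swept by
maximal lines parallel to the direction; maximal runs of equal gray value
(broken at mask boundaries) are each counted once, so Σᵢⱼ j·N(i,j) equals
the ROI voxel count in every direction — a conservation law the tests
enforce on random masks. Probabilities are run-count-normalized
(unnormalized nonuniformities would scale with ROI size); gray levels are
weighted 1-based (i′ = i+1) in LGRE/HGRE so gray level 0 stays finite.

Both matrices are computed at voxel distance 1 in the 13 unique offset axes
of the 26-neighbourhood, and each matrix feature is the arithmetic mean
over non-degenerate directions (directions with no pairs/runs are excluded
from the mean, not zero-filled). Offsets are lattice steps, not
physical-distance steps, so anisotropic spacing does not change the
direction set. Implementations are vectorized (shifted-array pair counting;
iterated-shift run-length computation) and are verified voxel-for-voxel
against brute-force enumeration oracles in the test suite.

## Statistics

Within each density stratum (240 observations: both diameters pooled,
matching the per-density reporting of the original study), each feature is
min–max scaled to [0, 1] across the stratum and regressed by OLS on an
intercept plus four dummies: [T=2.5], [T=1.25], [mAs=120],
[kernel=standard], against reference levels 5.0 mm / 30 mAs / lung. The
original report's constants and coefficients all lie within [−0.7, 1.0],
which is only consistent with normalized features; min–max scaling is the
simplest convention that reproduces that range, and the scaling constants
are recorded in the run outputs.

Five pairwise contrasts per feature (5.0 vs 2.5, 5.0 vs 1.25, 2.5 vs 1.25,
30 vs 120 mAs, lung vs standard) are obtained as linear contrasts of the
fitted coefficients with t-tests from the coefficient covariance;
significance is two-sided p ≤ 0.05, unadjusted (a Holm-adjusted column is
emitted for reference but never drives the headline tallies, mirroring the
original analysis). |RC| per contrast is summarized by max / median / min
over the 20 features, where the median is the **lower** median (the 10th of
20 ordered values) — the convention that reproduces the published summary
values from the published coefficient columns in three of the four
verifiable cases; the remaining published value (0.079 for the solid mAs
contrast) matches the upper median instead and is treated as a typo in the
source.

Cohen's d = |m_A − m_B| / s_pooled with the usual pooled SD, classified
small / medium / large at 0.20 / 0.50 / 0.80, with all observations at a
factor level pooled across the other factors; the direction symbol comes
from a Welch two-sample t-test (robust to the unequal variances different
protocols produce) at p ≤ 0.05.

The bundled reference coefficient tables (`nodtex.reference_tables`) are
the published regression coefficients of the original physical experiment.
They are *inputs* for worked examples and arithmetic checks — the physical
scans behind them cannot be re-created, so the package never claims to
reproduce them from simulation; it reproduces their summaries exactly and
produces same-shaped tables from its own synthetic study.

## Numerical conventions and edge cases

- Internal identities are held to tight tolerances: variance = stddev²
  (1e−9), GLCM energy² = ASM (1e−12), probability normalizations (1e−12).
- Zero-variance samples define skewness = kurtosis = 0; zero pooled SD
  defines d = 0 for equal means and flags d = ∞ otherwise.
- A seed voxel failing its own criterion is an error (empty region), as is
  an empty mask or a fully degenerate direction set.
- Lower-median of an even-length vector is the n/2-th order statistic.
- Dummy-coded contrasts satisfy contrast(A,B) = −contrast(B,A) and
  contrast(5.0,1.25) − contrast(5.0,2.5) = contrast(2.5,1.25) exactly.

## Problem sizes

The default study (12 protocols × 10 repetitions × 4 nodules = 480
observations) renders and analyses in well under a minute on one CPU; the
test suite uses 1-repetition smoke studies (48 observations) for
end-to-end checks and 50-replicate Monte-Carlo runs (240 rows each, 20
independent feature columns) for the regression calibration checks, chosen
to make sampling error a small fraction of the tested tolerances.

## Known limitations

- The noise model is white Gaussian in HU; real CT noise is correlated and
  non-stationary, and kernel effects on texture are richer than a Gaussian
  PSF plus unsharp masking.
- Nodule heterogeneity is statistical, not anatomical, and is redrawn per
  scan (see above).
- Effect directions and magnitudes from the synthetic study depend on the
  plumbing constants (PSF widths, noise constants, texture amplitude) and
  should not be read as predictions of any particular scanner's behaviour;
  the invariant content is the machinery and the qualitative orderings.
- The segmentation QC sphericity uses a marching-cubes surface on the
  binary mask, which overestimates area for small masks at thick slices;
  thresholds are chosen leniently (0.6) for that reason.
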