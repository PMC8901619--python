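# Methods

This note documents the models, numerical choices and known limitations of
the package, in the order data flow through the pipeline.

## Image model and thresholding

En-face angiograms are 2-D arrays of normalized intensity in [0, 1]
(8/16-bit TIFF/PNG inputs are divided by their dtype maximum) with a
physical pixel pitch (default 6 µm/px, a 6 × 6 mm scan at 1024² px) and a
device signal-strength index; scans under the quality minimum (default 8)
are rejected, not silently analysed. Normalizing intensities makes all
threshold formulas scale-free.

Three binarization algorithms are assigned per anatomical layer:

* **Li minimum cross-entropy** (superficial plexus). Fixed-point iteration
  t′ = (μ_b − μ_f)/(ln μ_b − ln μ_f) on the raw intensities, tolerance 1e−6,
  at most 100 iterations (non-convergence raises, carrying the last
  iterate). Because the discrete objective is piecewise constant between
  observed intensities, the converged value is polished by a local search
  over neighbouring inter-value cut points (±2% of the intensity range) so
  the returned threshold attains the discrete cross-entropy minimum. Note
  that minimum cross-entropy is origin-dependent: Li thresholds are
  equivariant under intensity scaling but not under shifts (some
  implementations first shift the image to a zero minimum; this one does
  not, and the test suite pins the relationship between both conventions).
* **Otsu** (deep plexus). 256-bin histogram over the intensity range;
  the returned threshold is the bin center maximizing between-class
  variance. Shift- and scale-equivariant up to one bin width.
* **Phansalkar** (choriocapillaris). Per-pixel threshold
  t = μ_w·(1 + p·e^(−q·μ_w) + k·(σ_w/r − 1)) over a circular window,
  mirror-padded at borders. The constants p = 2, q = 10, k = 0.25, r = 0.5
  are the method's published values; the window radius defaults to 15 px
  (≈ 90 µm, one capillary lobule) and everything is exposed in
  configuration. The population (not sample) SD is used.

Foreground is strict `pixel > t` for bright structures; the dark phase
(`pixel ≤ t`) defines flow voids. Global thresholds always lie strictly
inside the intensity range; a constant image raises a no-contrast error.

## Vessel metrics

The binarized plexus map is thinned to 1-px centerlines with
topology-preserving 8-connectivity thinning (scikit-image). Vessel density
and skeleton density are foreground fractions of the mask and skeleton;
the vessel diameter index (VDI) is mask pixels / skeleton pixels, a mean
caliber in pixels, with an optional µm conversion. The pure pixel ratio is
reported: published device VDI values (~10⁶) carry an undocumented
instrument-specific scaling that cannot be reproduced from the definitions,
so absolute device-scale VDIs are out of scope. The whole scan is the ROI —
no foveal-avascular-zone exclusion is applied. Thinning is mildly
anisotropic: under 90° rotations, densities are exactly invariant
(histogram-based thresholds) but skeleton-based metrics move by up to a few
percent.

## Choriocapillaris analysis

Reflectivity is the per-scan mean and population SD of the normalized
signal. Flow voids are connected components of the Phansalkar dark phase;
8-connectivity by default (diagonally touching deficits are physiologically
contiguous), 4-connectivity available. The component-size floor defaults to
none at the function level; the pipeline configuration applies a 144 µm²
floor (one 4-px resolvable element at 6 µm/px) because single-pixel speckle
components otherwise distort the small end of the size distribution.

The size-distribution fit bins void sizes into 10 log₁₀-spaced bins spanning
the observed range (explicit edges may be supplied), drops empty bins
(≥ 3 non-empty required), and regresses log₁₀ count on log₁₀ bin center by
ordinary least squares. Group differences in the intercept use an
equal-slopes pooled model log₁₀ count ~ log₁₀ size + group; since the bin
points of one eye share that eye's realization, standard errors are
cluster-robust over void sets with a t reference distribution — plain OLS
anti-conservatively treats those points as independent (measured type-I
error ≈ 0.13 instead of the nominal 0.05; the clustered version measures
≈ 0.05 with power 1.0 at a 0.5-decade intercept gap, n = 10/10). Group
differences in void-count dispersion use the Brown–Forsythe statistic
(Levene with median centering); with no within-group variability at all the
test returns p = 1 with a warning.

## MRI burden

NOL is the number of connected components of the supplied binary lesion
mask, 26-connectivity by default (6/18 configurable — adjacency conventions
differ between lesion toolboxes). WMI = lesion volume / TIV × 100, with TIV
the sum of the supplied white-matter, grey-matter and CSF volumes. WMI is
log-transformed with the natural log; a zero-lesion participant has WMI 0,
an undefined log, and is flagged and excluded from log-WMI regressions with
a report line rather than dropped silently.

## Cohort statistics

Participants with any screening flag (ocular disease, poor image quality,
neurologic abnormality) are excluded; multi-flag records are excluded once
and counted under every reason. OCT-A metrics are averaged over a
participant's eligible eyes (quality ≥ minimum). CSVD case status is
Fazekas ≥ 1.

Mann–Whitney U uses midranks; the p-value is exact (full enumeration) for
n₁ + n₂ ≤ 12 without ties, otherwise the normal approximation with tie and
continuity corrections. ROC AUC is the midrank concordance probability with
ties at half credit, oriented so AUC ≥ 0.5 (orientation reported); the 95%
CI uses the Hanley–McNeil variance and the p-value is the equivalent
Mann–Whitney's. Regressions put the MRI parameter (log WMI or NOL) as
outcome and one OCT-A metric as predictor — the orientation implied by the
reported coefficient scales — with OLS and t-based CIs, fitted unadjusted
and with age as covariate, for the overall sample, an age-matched subgroup
and cases only. Age matching is greedy nearest-neighbour 1:1 without
replacement. All tests are two-sided at α = 0.05 with no multiple-testing
correction (exploratory design). Collinear designs and single-class ROC
inputs raise informative errors.

## Synthetic-data generators

All generators are pure functions of their seed, and every ground-truth
quantity is measured on the generated object itself, never echoed from the
request.

**Vessel networks.** Reflecting random walkers with occasional branching
grow a connected network; each stroke is stamped with a disk of its drawn
width (uniform over the width range, default 2–6 px) until the vessel
fraction reaches the target (default 0.278, a typical superficial density);
near the target, stroke length and width shrink so the achieved fraction
lands within ±0.02 (a violation raises). The image is the two-level mask
(vessels 0.85, background 0.2) under a σ = 0.5 px Gaussian blur and
additive Gaussian speckle (default SD 0.05). The truth centerline is the
medial axis of the drawn mask — raw walker pixels double-count length where
strokes overlap — and the truth mean width is mask area / centerline
length. Noise-free scans are recovered exactly by the threshold pipeline;
the generator does not emulate projection artifacts, vessel-contrast
gradients, or segmentation errors, so recovery tests bound algorithmic
error, not device error.

**Choriocapillaris scans.** Per-log-bin void counts are
round(10^intercept · size^slope) (defaults slope −1.5, intercept 3.2, sizes
4–300 px over 10 bins); target sizes sit at deterministic log-uniform
quantiles within their bin, so the truth histogram deviates from the law
only by integer rounding. Voids are rasterized as disks and placed
largest-first by rejection sampling with a 4-px margin, keeping them
disjoint even after binarization; recorded sizes are exact rasterized pixel
counts. The background is Gaussian (default 0.9 ± 0.05), void interiors
0.45. Requests whose expected count is < 1 in every bin, or whose total
area exceeds half the image, fail loudly. `intercept=None` produces a
void-free background scan. A fast image-free sampler draws Poisson per-bin
counts from the same law for statistical simulations.

**Lesion volumes.** Disjoint spheres (radii 1–4 voxels) placed with a
2-voxel gap so the implanted count equals the 26-connected component count
exactly; a retry cap failure suggests a larger grid.

**Cohorts.** Group marginals default to the published case/control
means ± SD (age, MoCA, vessel densities, device-scale VDIs,
choriocapillaris reflectivity mean/SD, NOL, WMI). The joint distribution is
a structural model — a genuinely open design choice, surfaced in
`CohortParams` rather than hidden:

* each OCT-A metric declines with age (configurable slopes) and loads
  negatively (0.3 SD) on a shared latent microvascular factor;
* NOL's latent value is μ + 0.4·Δage − 200·(vd_deep − μ_d) + ε, rounded and
  clipped at 0, with the residual scaled so the marginal SD matches the
  configured value (an infeasible combination raises, naming the offending
  pair). The driver metric and slope are configurable; the −200 default
  makes age-adjusted OLS on large cohorts a sharp identification check;
* WMI is log-normal (moment-matched to the configured mean/SD) with
  correlation 0.45 to age and 0.3 to the NOL residual;
* two eyes are generated symmetrically around the participant value with
  within-participant correlation ρ_eye = 0.8, so the eye average equals the
  participant value and configured SDs describe eye-averaged values;
* skeleton densities (not part of the published group table) are vessel
  density divided by a per-participant mean caliber (≈ 4.2 px superficial,
  3.6 px deep);
* Fazekas grades: controls 0, cases 1/2/3 with probabilities
  0.55/0.30/0.15 (the published composition of 11 grade-1 and 9 grade-≥2
  cases among 20);
* flow-void columns come from the per-bin power-law sampler with group
  intercepts 2.8 (controls) vs 2.6 (cases) and per-participant intercept
  jitter 0.06 vs 0.18 — producing both an intercept difference and a higher
  dispersion of void counts in cases.

Truncation bounds: densities and reflectivities to (0, 1), age to
[18, 100], MoCA to [0, 30], NOL to ≥ 0, WMI strictly positive.

## Problem sizes and determinism

Simulated recovery and calibration use 256² vessel scans, 512²
choriocapillaris scans, 64³ lesion grids, study-sized cohorts (20 cases /
10 controls) for the report layer and 2000–5000-participant cohorts for
marginal/slope identification; calibration of the intercept comparison uses
500 null and 200 alternative replicates. The end-to-end demo writes images
for a configurable participant subset (default 3) at reduced sizes. Every
entry point takes a seed; identical (seed, config) runs are byte-identical,
and report bundles embed a SHA-256 hash of the configuration.

## Limitations

* Absolute device-scale VDI and skeleton-density regression coefficients of
  clinical instruments are not reproducible from the metric definitions;
  only the pure pixel-ratio scale is computed.
* The synthetic cohort's correlation structure is a modelling choice; tests
  against it validate the statistical machinery, not any clinical effect
  size.
* Choriocapillaris signal compensation by inner-layer structure is not
  implemented (not part of the quantification pipeline modelled here).
* The exact dispersion-test and per-eye-vs-pooled Spaide-fit conventions
  vary across the literature; both are configuration here, with the
  defaults documented above.
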