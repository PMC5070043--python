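# Methods

## Cortisol awakening response

A subject's series is the three saliva samples at nominal 0, 30 and 60
minutes after awakening. Quality control applies four independent rules,
each with its own reason code: a missing sample; any sample with saliva
volume below 200 µl; any sample reported more than 15 minutes before or
after its nominal time (the 15-minute boundary itself passes; a missing
self-reported time is treated as on time by default, with a strict mode
that excludes instead); and a negative Δ30 = c₃₀ − c₀, the accepted marker
of delayed first-sample collection. Rules are evaluated independently, so
the verdict is idempotent and order-free, and a series can carry several
reasons. Excluded subjects carry no AUC values.

Both of Pruessner's measures are computed for passing series:
AUC with respect to ground, AUC_g = 15·(c₀ + 2c₃₀ + c₆₀), the trapezoid
area of concentration against nominal time over [0, 60] min; and AUC with
respect to increase, AUC_i = AUC_g − 60·c₀. Which one a given analysis
calls "the CAR" is a configuration choice (`auc_variant`); the default is
AUC_i, on the grounds that the quantity of interest is the *response* to
awakening rather than total exposure, and that group means of order 25–320
nmol·min/l sit naturally on the AUC_i scale. Nothing downstream depends on
the choice except the numbers themselves.

Group comparisons default to the pooled-variance two-tailed Student t-test
(df = n₁ + n₂ − 2), which is what the reported degrees of freedom of the
reference cohort match; Welch's form is available as an option. The test
accepts either raw value vectors or (mean, SD, n) summaries, and the two
routes agree to floating point. Outlier screening computes standard scores
z = (x − x̄)/s over the full sample including the candidate (sample SD,
ddof = 1) and flags |z| > 3; flagged subjects are removed and the group
test re-run on n − 1. Degenerate inputs (no spread, both SDs zero with
unequal means) raise rather than returning NaN.

## Receptor-expression-weighted thresholds

The multiple-comparison scheme encodes the prior that a cortisol–structure
association is more plausible where corticosteroid receptors are expressed:
a sample-level table (donor, probe, gene ∈ {GR, MR}, region, normalized
expression) is reduced to one combined score per region in a fixed order —
sampling sites are averaged within (region, donor, probe); probe values are
averaged within (region, donor, gene); donor values are averaged within
(region, gene); and the GR and MR values are pooled by an unweighted mean.
The order matters in unbalanced designs (probe-first averaging is not the
pooled mean) and is tested against a hand-computed oracle. Expression
values are used as given; no re-normalization across donors is applied.

Regions are ranked by combined expression (rank 1 = highest) and mapped to
per-region p thresholds on a ladder with fixed endpoints: rank 1 gets
p_max = 0.01 uncorrected; rank R gets p_min = 0.05/N where N is the number
of voxels in the analysis mask, recomputed per dataset. Interior ranks
interpolate linearly on the p scale — the range of probabilities divided
into equal steps — with a log₁₀-spaced option for users who prefer
near-geometric decay; linear is the default because the endpoints and
"equally sized steps" are stated on the probability scale. Ties in combined
expression receive the mean of their tied ranks and hence share a
threshold, avoiding arbitrary ordering effects; fractional ranks
interpolate on the same ladder. Regions lacking either gene are excluded
from inference and listed as uncovered rather than given a default
threshold. A single covered region receives p_max.

## Voxelwise GLM

Images are smoothed with a separable Gaussian kernel specified by FWHM
(σ = FWHM/(2√(2 ln 2)), converted to voxels via the voxel size; default
8 mm). Boundary handling is replicate (nearest-value) extension, chosen so
that a constant image is an exact fixed point — a deviation from SPM's
implicit-zero padding, which darkens edges and would break the
constant-image invariant the tests rely on. FWHM = 0 is the identity.

Proportional scaling multiplies each subject's volume by
(grand mean of in-mask subject means)/(that subject's in-mask mean), so all
subjects share the in-mask mean afterwards. Normalizing to the grand mean
rather than an arbitrary constant is inconsequential for t statistics
(only relative scale enters) and keeps values on the original scale. The
analysis mask is the set of voxels with a nonzero atlas label and positive
mean GMV across subjects.

The per-voxel model is ordinary least squares, y = Xβ + ε, fitted for all
voxels at once through the normal equations; t = cᵀβ̂/√(s²·cᵀ(XᵀX)⁻¹c) with
s² = RSS/(n − rank X), df shared across the map. Covariates are age,
gender (0/1) and antidepressant use (0/1); group is coded 0 = control,
1 = UHR; CAR is mean-centred before the group×CAR interaction column is
formed, which reduces collinearity with the group main effect and leaves
the CAR and interaction contrasts unchanged. A constant nuisance covariate
(e.g. a cohort with nobody on antidepressants) is collinear with the
intercept and is dropped with a log message rather than failing the fit;
any other rank deficiency raises an error naming the collinear columns.
Noise-free voxels (zero residual relative to the response's own scale)
report a signed-infinity sentinel instead of poisoning the map. The
interaction model requires at least three subjects per group; its t-map is
read in both directions (positive = stronger slope in UHR).

## Flexible thresholding

Critical values are one-sided upper-tail Student t quantiles of each
region's p (the tested contrasts are directional; a two-sided option halves
p). A voxel is significant iff its t exceeds its own region's critical t.
Reports aggregate per region: voxel count, number and maximal size of
26-connected clusters, peak t and peak location in 0-based voxel indices
and mm from the grid corner (mm = index × voxel size — stated to fix the
convention). No cluster-extent threshold is applied by default; a minimum
cluster size is an optional knob. Regions present in the atlas but missing
from the threshold table are an error, or skipped with a warning in
lenient mode (the end-to-end pipeline uses lenient mode because masking can
remove a region entirely).

## Synthetic data

The generators emulate the study conditions rather than realistic anatomy:

* **Atlas** — axis-aligned blocks partitioning a 16³ grid of 2-mm voxels
  into 8 connected regions (largest block halved along its longest axis
  until the count is reached; label order is seed-permuted). Blocks are the
  simplest connected parcellation and suffice for thresholding semantics.
* **Cohort** — 22 UHR and 17 control subjects by default, with AUC_i drawn
  from normal distributions truncated at zero (means 223.84 / 320.97,
  SDs 233.52 / 253.85 nmol·min/l): a waking-response magnitude cannot be
  negative, and a planted negative value would be confounded with the Δ30
  exclusion. Each AUC is converted to a consistent concentration triple
  (c₀ uniform on 4–12 nmol/l, a rise d = AUC_i/37.5 at 30 min, half the
  rise retained at 60 min), so the AUC code path is exercised end to end.
  QC failures of each type (low volume, late sample, negative Δ30, missing
  sample) are planted on distinct subjects, UHR-end first; an optional
  outlier value replaces the first UHR subject's AUC. Transition flags go
  to the lowest-AUC UHR subjects by default (the direction the blunting
  hypothesis predicts), with a random-assignment option for null tests.
  Ages are uniform on 18–30; antidepressant use is Bernoulli(4/22) among
  UHR only.
* **Expression** — every donor (default 6) samples every region once (twice
  for one region, so multi-site averaging is exercised), measured by two
  probes per gene; a measurement is region mean + donor offset + probe
  noise. Zero noise reproduces the region means exactly.
* **GMV forward model** — voxel value = region baseline (600) + region
  slope × CAR + covariate terms + interaction term (UHR only) + i.i.d.
  Gaussian noise (SD 10). The bundled study scenario plants a slope of
  0.05 GMV units per nmol·min/l in the three highest-expression regions.

What passing tests on these data do show: the pipeline recovers planted
effects where they were planted, its false-positive rates match the
assigned per-region thresholds under a null, and every stage is
deterministic under a fixed seed. What they do not show: robustness to
registration error, non-Gaussian scanner noise, spatially varying
smoothness, or anatomically realistic region geometry — all explicitly out
of scope.

## Problem sizes and numerical choices

Simulation-based checks use a 16³ grid, 8 regions and 39 subjects; planted
-effect recovery is evaluated over 200 seeds (≥ 95% of seeds must report
all three planted regions) and null calibration over 500 GLM simulations
per check, with per-region false-positive counts required to sit inside
central 99% binomial intervals. Null calibration omits smoothing (which
correlates voxels and would widen the count distribution beyond binomial)
and scaling; the GLM oracle comparisons use relative tolerance 1e-10
against per-voxel normal-equations solutions. Threshold-ladder exactness is
asserted to 1e-12 at the endpoints for every region count up to 50.

## Known limitations

* The choice between AUC_g and AUC_i as "the" CAR, the linear-vs-log
  threshold spacing and the tie convention are documented defaults, not
  certainties about any particular published analysis.
* The Bonferroni endpoint depends on the mask's voxel count, so threshold
  maps are not transferable across grids without recomputation.
* Expression aggregation consumes a prepared sample-level table; mapping
  donor sampling coordinates into an atlas is out of scope.
* Smoothing spreads planted effects across block boundaries, so adjacent
  null regions can reach significance in effect-recovery scenarios; the
  recovery criterion therefore asks for the planted regions' presence, not
  exclusivity.
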