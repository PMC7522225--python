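# Methods

`retdens` analyses the *distribution* of pixel-wise retinal-layer thickness
rather than scalar summaries of it.  This note records the model, the
numerical choices, what the synthetic cohorts do and do not emulate, and the
known limitations.

## From thickness maps to densities

Each subject contributes, per retinal layer, a 2-d map of thickness in
micrometres with a missing-pixel mask, a fovea centre, a pixel spacing, and
an eye label.  Left-eye maps are mirrored about the vertical axis so anatomy
lines up across eyes; since the analysis treats pixels as an unordered
sample this is a plotting convenience, and a tested invariant is that it
preserves the multiset of non-missing values.  An ETDRS grid (concentric
rings of 1, 3 and 6 mm diameter centred on the fovea) selects the macular
region; a pixel belongs to a region when its centre does, and "inside the
grid" means the full 6 mm disc — the three subfields are labelled but the
analysis pools them into one sample per subject.  When maps arrive as RGB
heatmaps, thickness is recovered by nearest colour against a known colour
bar (squared Euclidean distance in 8-bit RGB; ties to the lower-valued
entry; pixels nearest the reserved background colour, or farther than 3x
the minimum inter-entry distance from every entry, become missing).
Automated fovea detection is out of scope: the centre is a required input.

All subjects in one comparison share a single affine map to the unit
interval, `x = (t - a) / b`, with `a = pooled_min - pad` and
`b = pooled_range + 2 pad`, `pad` = 1% of the pooled range (1 um for a
degenerate range).  Pooling — rather than per-subject normalisation — keeps
between-subject location differences, which are exactly what the classifier
must see; the pad keeps every density strictly inside (0, 1), away from the
boundary of the density manifold where square-root geometry degenerates.
The whole analysis is therefore invariant to consistent rescaling or
shifting of the raw thickness values (tested: an affinely transformed
cohort yields identical unit-interval samples and equal AUCs).

Each subject's density is a Gaussian KDE of the unit-interval sample on a
shared uniform grid (default 512 points; quadrature error is then
negligible relative to sampling noise and the run stays desk-fast),
renormalised to exact unit trapezoidal mass.  The default bandwidth is the
normal-reference (Silverman) rule `0.9 min(sd, IQR/1.349) n^(-1/5)`, with a
0.01 fallback for zero-spread samples.  No boundary correction is applied:
the pad keeps mass off the boundary, and renormalisation absorbs the
residual leak.

## Geometry on the unit Hilbert sphere

The square-root transform `h = sqrt(f)` embeds densities into the positive
orthant of the unit sphere in L2([0, 1]), where the Fisher–Rao metric is
the ordinary L2 metric.  Everything downstream uses the sphere's closed
forms: geodesic distance `d(h1, h2) = arccos <h1, h2>`; exponential map
`exp_h(v) = cos|v| h + sin|v| v/|v|`; inverse-exponential
`log_h1(h2) = theta (h2 - cos(theta) h1)/sin(theta)`.  Inner products use
trapezoidal quadrature on the shared grid and are clipped to [-1, 1] before
`arccos`; angles below 1e-9 take the zero-vector limit of the log map, and
exactly identical grids short-circuit to distance zero to avoid `arccos`
round-off at the diagonal.

The Karcher mean minimises the sum of squared geodesic distances.  It is
computed by tangent-space gradient descent — iterate
`mu <- exp_mu(step * mean_i log_mu(h_i))` — initialised at the normalised
pointwise average (always in the positive orthant), with step 0.5,
tolerance 1e-6 on the gradient norm, and at most 100 iterations;
non-convergence is reported in the result, not raised.  The implementation
is batched: many means (one per LOOCV fold, or one per permutation) iterate
simultaneously as rows of a matrix recursion, which is what makes the
permutation calibration studies cheap.

Numerical caveat, recorded because a test encodes it: when an SRT vanishes
at a domain boundary the product integrand acquires a square-root
singularity and trapezoid convergence drops from O(m^-2) to O(m^-3/2) —
about 1e-4 in a distance at m = 512 per singular endpoint.  Pipeline
densities never vanish (the pad guarantees it); the affected closed-form
stress case is asserted at the a-priori 2e-4 bound instead of 1e-4.

## Tangent PCA and classification

Subjects are linearised at the sample Karcher mean: row i of the tangent
matrix is `log_mean(h_i)` scaled by the square roots of the quadrature
weights, so Euclidean row algebra equals L2 function algebra (row norms are
geodesic distances; this is tested).  Rows are centred before the SVD — on
a discrete grid the tangent vectors at the computed mean average only
approximately to zero, and centring keeps the PCA well defined; the
uncentred variant is a flag.  Principal directions keep the smallest count
of components whose cumulative squared-singular-value fraction reaches
99.99%; signs are fixed (largest-magnitude coordinate positive) for
reproducibility.  Scores use the centred projections; score-space standard
deviations use 1/(n-1).  Principal-direction density paths shoot the
exponential map from the mean by k score-standard-deviations along a
direction and square the result; k = 0 returns the mean density exactly.

Classification is logistic regression on the scores, with a 1e-6 ridge on
the slopes (intercept unpenalised) to tame quasi-separation in small folds.
Evaluation is leave-one-out: by default the Karcher mean, the tangent PCA
and the logistic fit are all recomputed per fold from the n-1 training
subjects, and the held-out subject enters only through projection — a
global-PCA variant exists as a flag but leaks the test subject into feature
construction.  The pooled domain transform is likewise refitted per fold;
since a min–max transform changes only when the held-out subject owns the
pooled extremum, at most three distinct transforms occur and densities are
cached per transform.  The cross-validated probabilities are summarised by
the Mann–Whitney AUC (ties 1/2) with a Wald CI from DeLong's
structural-components variance, clipped to [0, 1]; with three pairwise
comparisons at overall alpha 0.05 the per-comparison CI level is
1 - 0.05/3 = 98.3%.  Sensitivity and specificity use a probability
threshold of 0.5 by default (a Youden-optimal option exists); the Brier
score is the mean squared probability error.  A five-number-summary
baseline (mean, min, max, Q1, Q3 of the raw micrometre values; type-7
quantiles) feeds the same LOOCV logistic path — deliberately *not*
scale-invariant, as a contrast to the density features.

## Permutation test

Group differences are tested on the geodesic distance `d0` between the two
groups' Karcher means.  The null distribution recomputes both means under
random label permutations (default 10,000; seeded).  The conventional
p-value is the fraction of permuted distances at least as large as `d0`
(ties within 1e-9 count as large, so an identity permutation is counted);
an `as_printed` direction counting `d0 > d_perm` is retained because one
published formulation writes the inequality that way, which is inverted
relative to its use — the two directions partition the permutations.  No
add-one correction by default (a Phipson–Smyth flag exists).  Adjusted
p-values multiply by the number of comparisons (3) and cap at 1.

## Synthetic cohorts

Real OCT thickness cohorts for diabetic retinopathy are restricted, so the
generator emulates their reported distributional structure: group sizes
41 controls / 28 NoDR / 38 NPDR; per-layer pixel-thickness mixtures with a
main truncated-normal component peaked near 40 um (scale 6 um) and a
heavier right tail in disease.  The tail component is a Gamma(shape 2,
scale 8 um) shifted to start at 50 um; its mixture weight is solved so that
P(thickness > 50 um) equals the configured tail mass exactly.  Gamma(2) is
used because it starts at zero at the onset, keeping the mixture pdf
continuous — a kernel density estimate can then converge to it uniformly —
while both components keep closed-form CDFs that serve as independent
oracles in the tests.  Calibrated defaults: INL tail mass 0.29 (controls) /
0.39 (NoDR) / 0.40 (NPDR); OPL 0.30 / 0.32 / 0.38; the other six layers are
null layers with group-invariant parameters on plausible per-layer scales.
Two per cent of pixels are missing at random.

Between-subject heterogeneity is applied when a cohort is generated: each
subject receives a normal jitter on the peak location (sd 2 um) and a
logit-normal jitter on the tail mass (sd 0.25), chosen so that per-subject
densities spread visibly around the group mean and group AUCs land in the
0.8–0.95 range rather than saturating at 1 — without it, two subjects with
10^4 pixels each are statistically indistinguishable from their common
group density.  Maps default to 121 x 121 pixels at 0.05 mm/pixel (the
6 mm disc then holds ~11,300 pixels); pixels are independent draws by
default, with an optional smoothed-field mode (Gaussian-blurred white noise
pushed through the mixture quantile function) that looks more OCT-like but
is analytically equivalent because the pipeline treats pixels as an
unordered sample.  Laterality is Bernoulli(0.5).  Everything is a pure
function of the seed.

What the generator does **not** emulate: OCT speckle and acquisition
artefacts, segmentation errors, spatially structured missingness, pathology
that is local rather than distributional (e.g. focal oedema), correlation
of a subject's deviations across layers, and covariate structure (age, sex,
diabetes duration).  Passing tests therefore demonstrate that the pipeline
recovers distributional group contrasts of the calibrated kind — not that
it would achieve any particular AUC on clinical data.

## Problem sizes used in tests and the acceptance script

Chosen as desk-scale defaults: the calibration suite uses 2x10^5 pixel
draws; the permutation calibration uses 500 null cohorts of 15 + 15
subjects (800 pixels each, grid 128) with 200 permutations, and 20 seeded
power runs at 1000 permutations; the end-to-end pattern check runs the full
map-based default cohort once (grid 512) plus nine sample-based replicates
(3000 pixels/subject, grid 256) and requires the expected CI pattern in at
least 9 of the 10 seeded runs.  The acceptance script analyses the default
cohort on INL, OPL and the null layer NFL with 2000 permutations per test.

## Known limitations

* The Karcher mean's gradient iteration has a fixed step (0.5); for
  antipodal-ish configurations (impossible for nonnegative SRTs, which live
  in one orthant) it would need damping.
* DeLong Wald CIs are known to undercover slightly for AUCs near 1 with
  small n; the coverage test targets the moderate-AUC regime.
* Exact reproduction of the clinical tables is impossible without the
  restricted OCT data; the end-to-end checks target the calibrated
  synthetic contrasts and the qualitative significance pattern instead.
* `estimate_pdf` evaluates the KDE only on [0, 1]; a fold transform fitted
  without the extremum-owning subject can push a sliver of that subject's
  mass outside the interval, which renormalisation absorbs (effect is
  bounded by the 1% pad).
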