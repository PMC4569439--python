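# Methods

This note documents the models, estimators, defaults and design choices
behind `habitat-ppa`, and what the synthetic-data tests do and do not show
about real MR data.

## Habitat segmentation

ROI intensities of each channel are linearly min–max rescaled to integer
gray levels 0–255 (a constant ROI is an error — the linear map is
undefined) and modeled as a two-component univariate Gaussian mixture fit
by EM. Initialization splits the sample at the median; iteration stops
when the log-likelihood improves by less than 1e-6 or after 500
iterations. Component standard deviations are floored at 1e-3 gray levels
to prevent collapse onto tied values. The habitat threshold is the
average of the two component means, which is invariant to component
ordering; a pixel exactly at the threshold goes to the **low** habitat (a
tie rule fixed for reproducibility — thresholds are half-integers on
integer data only when the mean of means is, so ties are rare but
possible). On unimodal data the fit terminates with two nearly equal
means and the threshold simply bisects the sample; this is deliberate
(no error), since downstream stages tolerate one habitat being empty.

EM is initialized deterministically rather than with random restarts:
for 1-D data with at most two modes, the median split starts each
component on its own side of the mass and restarts add nondeterminism
without measurable benefit. The `seed` argument is kept in the API for
stability. The fit consumes raw pixel values, not a binned histogram.

## Spatial map

The grid (default box 8×8 pixels) is anchored at the tight bounding box
of the ROI; edge boxes are clipped and centroids use the pixels present.
Coordinates are 0-based pixel indices with a pixel's center at
(x=col, y=row) and Euclidean distances in pixel units. Each (grid box,
habitat) pair with at least one pixel emits one centroid, so a box can
hold up to four points — co-located when a box is wholly inside two
habitats of different channels. The observation window is the ROI
bounding box expanded to whole-pixel edges; the irregular ROI polygon is
not used because all summary-function estimators here are defined on
rectangles. The box size trades quadrat area against the cost and
stability of the per-box centroid estimate and is exposed as a parameter.

## Neighborhoods and diversity indices

One neighbor relation is used for every abundance-based index: x_j is a
neighbor of x_i iff 0 < d(x_i, x_j) ≤ r (closed r-ball, self excluded;
co-located distinct points are *not* neighbors because their distance is
zero). Each index is evaluated on a radius grid — by default 50 evenly
spaced radii from w/100 to w/4, w the shorter window side, the upper
bound limiting edge effects — and summarized by the mean and sample
standard deviation over the radii where it is defined. Radii at which no
point has a neighbor are missing, not zero.

- **Mingling**: mean over points with δ>0 of the fraction of neighbors
  with a different mark.
- **Local Shannon / Simpson**: neighborhood mark proportions p_τ = δ_τ/δ;
  H = −Σ p_τ ln p_τ and the Gini–Simpson form D = 1 − Σ p_τ². The
  Gini–Simpson convention keeps "larger = more diverse", matching
  Shannon's direction.
- **Global Shannon / Simpson**: the same formulas on whole-pattern mark
  proportions (scalar features).
- **ISAR**: for focal mark u, the expected number of *other* marks with at
  least one point within r of a typical u-point (closed ball, zero
  distance included since u ≠ v), averaged over focal marks present. The
  scalar "ISAR" feature is the curve value at the largest radius.
- **MCI**: per point, CI = −(1/δ) · log multinomial pmf of the
  neighborhood mark counts under the whole-pattern mark proportions;
  the curve is the mean of CI over points with δ>0. CI is minimized when
  the neighborhood composition matches the global proportions (verified
  by enumeration over compositions in the tests), so MCI measures how
  surprising local compositions are given the global mix.

## Marked summary functions

G_uv is the empirical CDF over u-points of the nearest-v distance
(self excluded when u = v); F_v is the contact CDF from a 32×32 regular
lattice of test locations in the window; K_uv is
|W|/(n_u n_v) · #{(x,y): d ≤ r}; J_uv = (1−G_uv)/(1−F_v) wherever
F_v < 1 − 1e-9, missing elsewhere (never infinite). The inhomogeneous F
pools all marks, weights each test location's contribution by the
reciprocal of a Gaussian-kernel intensity estimate at its nearest point
(bandwidth default 2 × box size = 16 px), and normalizes the weights so
the curve stays in [0,1]; for homogeneous patterns it reduces to the
plain F.

The **default estimators are uncorrected** — no edge correction — so
every value is exactly reproducible by a brute-force double loop, which
is how the test suite verifies them. Uncorrected estimators are biased
near the window boundary (the uncorrected K falls ~20% below πr² at
r = w/4 on a unit window under CSR), so for calibration and sensitivity
analysis two standard corrections are available behind flags:
`marked_K(..., correction="translation")` (pair weights |W|/|W ∩ W_h|)
and `marked_G/empty_space_F(..., correction="border")` (reduced-sample:
only focal/test locations at least r from the boundary contribute at
radius r). Both are unbiased under CSR and are the forms used in the
CSR-calibration tests; the feature pipeline keeps the uncorrected
defaults so that patient features remain oracle-checkable.

### Assembly of the 27 features

The "for T1 and T2" K/J/G variants average, pointwise in r, the ordered
cross-pair curves of the T1 sub-pattern (T1low/T1high) and the T2
sub-pattern, then the two modality curves; the unsuffixed variants
average across all 12 ordered mark pairs u ≠ v with sufficient points.
Averaging is pair-then-summarize (one curve per feature), and pairs
undefined at a radius are dropped from the pointwise mean at that radius.
Degenerate patterns produce **missing** features — never silent zeros —
with a per-patient diagnostics report; a single-mark pattern yields zero
diversity indices, missing pairwise K/J/G, and still a length-27 vector.

## Survival screening

Each feature is dichotomized and the groups compared by the two-group
log-rank test (lifelines; hypergeometric variance, exact tie handling);
p-values are BH-FDR adjusted across features. The default cutoff
maximizes sensitivity + specificity on the ROC against the 12-month
class (ties toward the smallest threshold; positive class = OS ≤ 12
months, configurable since sensitivity/specificity conventions differ
between reports). **Caveat**: an optimized cutpoint is anti-conservative
for the subsequent log-rank test — the cutoff is chosen to separate a
function of the survival time, the classic maximally-selected-statistic
inflation (measured here: ≈16% rejection at nominal 5% under a null
cohort of n = 40). `feature_screen(..., cutoff_method="median")` provides
a data-independent split whose type-I error is calibrated (measured
≈5–6%); the calibration tests use it, and analyses that care about
per-feature error rates should too. Cutpoint selection is performed by
the log-rank dichotomy itself rather than an external adaptive
partitioning algorithm; the dichotomy is already fixed by the ROC cutoff.

Cohort demographics are summarized per 12-month class with count-weighted
pooled means and a pooled sd via the total sum-of-squares decomposition
(denominator N−1), which reconstructs the totals of the published cohort
table to one decimal place.

## Classification

The learner is deliberately simple and pluggable: standardization + L2
logistic regression, stratified k-fold (default 3) with a fixed seed,
scored out-of-fold, thresholded at the Youden point of the out-of-fold
ROC. A symbolic-regression learner would be interchangeable here; the
feature set, not the learner, is the object of study. Feature selection
takes the top 5 by coefficient of variation computed on raw columns (CoV
on standardized columns is undefined); a column whose mean is within
1e-12 of zero has no usable CoV and sorts last. CoV selection is
unsupervised: it favors whichever features have the widest relative
spread (typically the K/J summaries, whose scale grows with window area)
regardless of outcome association, so planted-signal recovery checks
evaluate the classifier on the full feature set as well.

## Synthetic cohort generator

Per patient: a connected, roughly elliptical ROI (area-preserving random
ellipse with low-order harmonic boundary perturbation, holes filled,
largest component kept) on a 128² image (defaults; tests use 64–96²);
per channel, a Gaussian random field (white noise smoothed with sd
`spatial_smoothness` = 4 px) thresholded at the quantile matching the
channel's high fraction gives spatially coherent low/high labels, and
intensities draw from the corresponding Gaussian (defaults: T1
70/170 ± 15, T2 90/190 ± 15 gray levels; high fractions 0.40/0.50),
clipped to [0, 255]. The per-patient high fractions are jittered
(sd 0.15, clipped to [0.05, 0.95]) — the dominant between-patient source
of spatial-feature variance. Survival is exponential with rate
`baseline_hazard · exp(hazard_coefficient · z)` where z is the
standardized truth-side spatial summary (default: the global Gini–Simpson
index of the noise-free habitat pattern); `baseline_hazard` = 0.06/month
gives mean OS ≈ 16.7 months, near the published cohort mean of 16.9, and
puts roughly 45–50% of patients in the ≤12-month class. Censoring is
independent with probability 0.2 (censored times uniform before the
event). Subtypes are drawn independently of the features with equal
probabilities; ages are N(57.5, 15.7²) clipped to [18, 90]; the male
fraction matches the 49/74 of the emulated cohort. All outputs are pure
functions of (config, seed) via spawned per-patient seed sequences.

What the generator does **not** emulate: scanner artifacts, bias fields,
registration error, irregular or multi-focal tumors, realistic habitat
geometry (no quantitative description of real-tumor habitat shape was
available to target), or subtype–feature association. Passing tests
therefore demonstrate correctness and statistical calibration of the
machinery, not clinical performance on real MRI.

## Problem sizes used in the validation suite

CSR calibration uses 500 patterns of ~200 points; oracle equivalence 50
random instances per statistic; null calibration 200 cohorts of n = 40
patients (64² images, ROI radii 8–12, median-split screen); log-rank
recovery 50 cohorts of n = 40 at hazard coefficient 1.5 (the targeted
feature's dichotomized log-rank fires in >70%); classification recovery
5 cohorts of n = 74 at coefficient 2.5. The recovery coefficients were
fixed from the latent-signal ceiling: the 12-month label is stochastic
given z, and Monte-Carlo evaluation of z itself gives AUC ceilings of
0.87 (coef 1.5) and 0.93 (coef 2.5), so only the latter leaves headroom
for a cross-validated estimate to clear 0.8.

## Known limitations

- 2-D single-slice only; multi-slice volumes are rejected at input.
- Uncorrected estimators understate K/G/F near the window edge; use the
  correction flags for inference against CSR benchmarks.
- The ROC-cutoff screen inherits optimal-cutpoint p-value inflation (see
  above); adjusted p-values control the FDR only with respect to the
  inflated per-feature tests.
- The MCI definition (negative log multinomial likelihood of neighborhood
  composition under global proportions) is one member of the composite-
  information family; alternative normalizations exist.
- No proportional-hazards modeling, mark-connection functions, pair
  correlation functions, or anisotropic statistics.
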