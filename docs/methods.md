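# Methods

This note documents the models implemented in `seedpe`, the choices made
where conventions were open, and what the synthetic generator does and
does not emulate.

## Counting model and the SS/2 rule

A processed pod sample is summarised by bounding-box counts in three
classes: intact pods (IP), whole seeds (WS) and split-seed objects (SS).
Because a dehulled seed separates into two cotyledon halves, each SS
detection is treated as half a seed: the effective split-seed count is
`n_SS_raw / 2` and the sample total is `n_IP + n_WS + n_SS_raw/2`. The
halved value is kept fractional throughout — proportions and totals live
in the rationals and any rounding happens only at display time. Samples
with zero total are flagged and excluded from every model fit rather than
imputed.

For detector output (as opposed to hand annotations), counting is preceded
by the standard post-processing: detections with confidence below 0.1 are
dropped, then greedy per-class non-maximum suppression at IoU 0.5 removes
duplicates. Both thresholds are parameters; the defaults are the values
used to produce the counts this analysis is designed for.

## Traits

With class proportions `P_c = count_c / total`:

- `PE = P_WS + P_SS` — the fraction of seed objects freed from pods;
- `PE_WS = P_WS + P_SS(1−λ)` and `PE_SS = P_WS(1−λ) + P_SS` — penalized
  variants downweighting the non-preferred end product. λ ∈ [0,1],
  default 0.6 (a balanced penalty; configurable per run). The identity
  `PE_WS + PE_SS = (2−λ)·PE` holds algebraically and is enforced by
  property tests at 1e−12.
- `DE = SS/(WS+SS)` — dehulling efficiency among freed seeds, computed
  from counts by default (a mass-based variant accepts masses).
- `NOPGS = total / pod_mass_g`, `NOPGM = total / mixture_mass_g` —
  per-gram object rates of the input sample and the processed mixture.

Dataset-level class composition (`class_percentages`) is reported on raw
box counts by default — the bookkeeping convention for annotation tallies —
with the halved convention available, since sample proportions use it.

## Detection evaluation

IoU is area-based on corner-form continuous boxes with no +1 correction.
NMS is per class (the dominant convention), greedy in descending score,
keeping a box iff its IoU with every kept box of the same class is
strictly below the threshold; score ties keep input order. For ≤6 boxes
the greedy result is verified in tests against brute-force enumeration of
the maximal score-ordered admissible subset.

mIoU is the mean IoU over matched pairs, matching predictions in
descending score order to the unused same-class ground-truth box of
highest IoU, provided IoU ≥ 0.5. This matching rule is declared, not
inferred from any particular tool; IoU ties resolve to the lowest
ground-truth index for reproducibility.

AP follows the COCO convention: 101-point interpolated precision-recall
area, per class, ranked globally by score with matching confined within
images; the headline mAP averages IoU thresholds 0.50:0.05:0.95 and is
macro-averaged over classes (AP50/AP75 at fixed thresholds). Classes with
no ground truth are excluded from macro means with a warning. No cap is
imposed on detections per image.

## Statistical models

**Counts.** `total_objects ~ variety + method + mass + variety:method`
is fit with a Gaussian-identity and a Poisson-log link; the two are
compared on holdout RMSE and MAE (20% holdout). The selected link must be
no worse on both metrics; when they disagree, RMSE decides. The winner is
refit on all data, and a sequential (type I) ANOVA is reported. Rank
deficiency is detected up front and the aliased terms named.

**Proportions.** Class proportions are fit with binomial-logit GLMs
weighted by each sample's total object count (`var_weights`), the only
weighting that respects fractional totals from the SS/2 rule. Reported
diagnostics: likelihood-ratio test against the intercept-only null
(χ² reference), Hosmer–Lemeshow with deciles-of-risk grouping
(g = 10, df = g−2, g reduced with a warning when there are fewer distinct
fitted values), and Nagelkerke's pseudo-R². Complete separation is flagged
from boundary fitted probabilities or exploding coefficients rather than
silently reported.

**Marginal means.** EMMs average model predictions over the observed
reference grid on the link scale, back-transforming with delta-method SEs.
All-pairs contrasts use a single-step multiplicity adjustment based on the
joint distribution of the contrast statistics — multivariate t for
Gaussian fits, its normal limit for logit fits — evaluated by seeded Monte
Carlo (40,000 draws), with a Bonferroni fallback labeled in the output.

**Repeatability.** For a trait measured on g varieties across e
environments (here environment = method × nominal mass, e = 10) with r
replicates per cell,

    R = σ²_G / (σ²_G + σ²_E/e + σ²_GxE/e + σ²_resid/(r·e)).

Components are estimated by REML (crossed random effects for variety,
environment and their interaction) with an expected-mean-squares
method-of-moments alternative that is exact for balanced designs; the two
are required to agree on balanced data in tests. Negative moment estimates
are truncated at zero with a warning. A single environment is rejected as
non-identifiable.

**Dispersion and ordination.** TWGSS is the k-means objective
(sum of squared distances to group centroids), used to compare varietal
compactness in (NOPGS, NOPGM) space between processing methods. PCA
centres and scales each trait to unit variance, uses SVD, drops
zero-variance columns with a warning, and fixes signs by making the
largest-magnitude loading of each component positive.

## Power analysis

Two PE values are compared on the variance-stabilising arcsine scale:
`φ = 2 asin √p`, `h = |φ₁ − φ₂|`, non-centrality
`δ = h·√(n₁n₂/(n₁+n₂))` (the unequal-n form used by standard
two-proportion power routines; the equal-n case reduces to `h·√(n/2)`),
and two-sided power `P = Φ(δ − z_{1−α/2}) + Φ(−δ − z_{1−α/2})`, which is
exactly α at h = 0. Per-sample n is the sample's effective object total,
used unrounded.

The pairwise analysis forms all C(m,2) unordered pairs within each
nominal-mass group and summarises the fraction reaching the target power
(default 0.8) and the count inside the target zone (power ≥ 0.8 and
|PE₁−PE₂| ≤ 0.25 — both configuration defaults, not constants). Because
"the mean difference detected" is ambiguous, two summaries are emitted:
the mean |PE| difference over all powered pairs and over target-zone pairs.

The minimum detectable difference at equal n solves
`power(h(c+d/2, c−d/2), n, n) = 0.8` for d by bisection (bracket
`(0, 2·min(c, 1−c))`, tolerance 1e−6, deterministic), with c = 0.5 the
worst case (maximal binomial variance) and c = 0.85 a best case near the
extreme. The sample-mass planner converts an objects-per-gram rate to
per-gram n values and returns the smallest integer mass whose worst-case
detectable difference meets the target; at 46 objects/g and a 0.25 target
this is 2 g (1 g resolves only 0.288; 2 g resolves 0.205).

Accuracy of the analytic power formula is checked against Monte-Carlo
rejection rates of the arcsine z-test on simulated binomials (100,000
replicates per grid point, seeded): agreement is within ±0.01 for
moderate proportions and n ≥ ~46. The normal approximation degrades near
the proportion boundary at small n (e.g. p ≈ 0.95 at n = 46 deviates by
~0.02) — a known limitation of the arcsine approximation, relevant only
to extreme PE values in tiny samples.

## Synthetic generator

`generate_experiment` emulates the factorial study design: 5 varieties ×
2 methods × 5 nominal masses × 10 replicates (500 samples). Pod mass is
the nominal value plus N(0, 0.02 g) weighing jitter; mixture mass is pod
mass times a method-specific yield (0.85 belt, 0.75 impact, SD 0.03).
Totals are negative-binomial (size 200; Poisson as the limiting case)
around `rate_v · mass + offset_m`, with per-variety rates 60, 32, 60, 42
and 36.6 objects/g — the printed per-variety rates where available, the
last chosen so the mean equals the overall 46.12 — and a −4 offset for
impact dehulling. Class proportions follow logit models: the intact-pod
share rises with mass (slope 0.15/g on the logit scale) around
variety×method centres taken from the study's marginal means; the
split-seed share is a small constant (0.004–0.015) under belt threshing
and declines with mass under impact dehulling (logit slope −0.276/g
around variety-specific centres 0.088–0.338). A per-sample logit jitter
(SD 0.12) adds replicate-level over-dispersion. Counts are multinomial
given the total, and the split-seed count is stored doubled so the SS/2
rule is exercised end to end. Negative binomial rather than Poisson
totals is deliberate: a linear-mean count process with overdispersion is
the simplest structure consistent with a Gaussian link outperforming a
Poisson link on real data of this kind.

What the generator does **not** emulate: image pixels, detector errors in
the counts (counts are exact draws, not detections), spatial or temporal
correlation between replicates, seed-lot heterogeneity within a variety,
and debris/unlabelable material. Passing tests therefore demonstrate the
correctness of the analysis machinery under the stated statistical
structure, not detector robustness on real imagery. One consequence of
the per-variety rate spread (32–60 objects/g): with a common-slope model
formula, the Poisson log link can out-predict the Gaussian on holdout
data from this generator, since the multiplicative structure absorbs
variety-specific growth; the Gaussian-wins comparison is reproduced in
tests on data simulated with a common linear mean.

`generate_detection_scene` lays ~40×40 px boxes on a jittered grid (no
overlap by construction) and derives predictions by translation jitter,
random misses and random false boxes, so evaluator behaviour can be
checked against closed forms (zero jitter → mAP = mIoU = 1; translation t
of a w-box → IoU = (w−t)/(w+t)).

## Problem sizes and numerics

The test suite and analysis drivers use the full 500-sample design for
single fits, 50–100 replicate simulations for recovery checks (balanced
10×8×4 designs for variance components, moment estimator), 100,000
replicates per grid point for the power Monte-Carlo, and 10,000 random
count vectors for trait identities. Bisection tolerance is 1e−6;
identity assertions use 1e−12; stochastic recovery checks are designed
around nominal coverage (e.g. CI coverage in ≥4 of 5 replicates) rather
than single-draw assertions. All simulations are seeded and
deterministic.

## Known limitations

- The arcsine power approximation is inaccurate for proportions near 0/1
  at small n (see above); exact binomial power is out of scope.
- The single-step contrast adjustment is Monte-Carlo based; adjusted
  p-values carry ~1/√40000 noise (seeded, hence reproducible).
- The method-of-moments variance components assume balance; unbalanced
  designs fall back to mean cell size with a warning, and REML should be
  preferred there.
- DE from counts treats every split half equally; heavily fragmented
  seeds (>2 pieces) bias DE and PE_SS upward, and nothing in the count
  data can correct for fragments lost with processing debris.
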