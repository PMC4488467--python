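# Methods

This note documents the models, conventions and design choices behind
`vespawing`: what the synthetic generator simulates, how the morphometric
and statistical procedures are defined, which constants are calibrated and
how, and what the shipped tests do and do not demonstrate.

## The study design being emulated

The pipeline reproduces a within-colony quantitative-genetics design for
social wasps: two mature colonies, each headed by one multiply-mated queen;
workers genotyped at five polymorphic microsatellite loci
(LIST2004, RUFA05, RUFA13, RUFA19, VMA3) and partitioned into patrilines
(paternal full-sib groups); each worker's right forewing digitized at 19
two-dimensional landmarks; and a measurement-error study in which 39 wings
from the first colony are mounted twice and each picture digitized twice.
Default sample sizes are 116 and 112 genotyped workers, with a per-locus
amplification-failure probability of 0.04 (so a handful of workers fail the
"at most one missing locus" filter) and a wing-damage probability of 8/228
(so on average 8 of 228 genotyped specimens contribute no wing).

Patriline proportions default to (43, 34, 22, 17)/116 for Colony 1 and
(48, 43, 15, 6)/112 for Colony 2. The first set is taken directly from the
per-patriline sample counts of the emulated design; for the second only the
extremes are pinned down by the reported frequency range (42.86% and 5.36%
of 112), so the middle two counts are chosen to complete the total — a
documented, essentially inconsequential choice, since no statistic tested
here is sensitive to the middle counts.

## Pedigree model and paternity inference

Haplodiploidy makes sibship reconstruction nearly deterministic once the
queen is known: every daughter carries one of the queen's two alleles plus
her father's single allele at each locus. Per worker and locus the
*paternal candidate set* is

* the worker allele absent from the queen, when there is exactly one;
* both worker alleles, when both are queen alleles (the paternal allele is
  then ambiguous);
* unconstrained, when the locus is missing;
* empty — a maternity violation, reported as an error naming the specimen —
  when both worker alleles are non-queen.

Workers are partitioned into the **minimum number of fathers** such that
within each group the per-locus intersection of candidate sets is
non-empty. The search is exact: workers with identical candidate profiles
are merged (always safe, since constraints are per-locus intersections),
then iterative deepening over the father count k with a first-fit
depth-first search over profiles in canonical (sorted specimen id) order.
Trying existing groups in creation order makes the returned minimal
partition the lexicographically first one, hence deterministic and
invariant to input order. The profile cap defaults to 256 (the search is
effectively instant on identifiable pedigrees; the cap guards against
pathological inputs).

Allele frequencies for the non-detection probability ∏ⱼ Σᵢ q²ᵢⱼ are counted
from the inferred paternal haplotypes (one count per father per locus,
ambiguity sets counted fractionally). No small-sample or likelihood-based
adjustment is applied; consequently the non-detection value is a descriptive
output, not a calibrated one. Likelihood-based sibship reconstruction with
genotyping-error models, multi-queen and inbreeding scenarios are out of
scope.

## The synthetic generator

All shape structure is built directly in the 34-dimensional tangent space
of a fixed 19-landmark template wing (an elongate, deliberately asymmetric
configuration; only relative shape structure matters anywhere downstream).
An orthonormal basis of the orthogonal complement of the similarity
transformations (x/y translation, scaling, rotation) maps tangent vectors
to landmark displacements, so a tangent vector of norm m sits, to first
order, at Procrustes distance m from the template — generator magnitudes
and estimated distance statistics share one scale.

Log centroid size: `logCS = mu + c + p + e` with colony, patriline and
individual deviates drawn with variances 2.54e-4, 4.04e-4 and 15.42e-4
(the published variance components) about a grand mean of 3.0 (centroid
size ≈ 20 wing units).

Tangent shape: colony effect (random unit direction × delta_colony =
1.33e-2) + patriline effect (random unit direction per patriline ×
delta_patriline) + shared allometric direction × 0.1 × (logCS − mu) +
isotropic individual noise (sigma_individual per coordinate). Group effects
as *random unit directions* match the finding that colony and patriline
differences point in essentially unrelated directions (angles near 90°);
isotropic Gaussian noise at every level is the simplest model consistent
with the statistics computed. Observation adds mounting noise (7e-4) then
digitization noise (1e-4) per tangent coordinate — their ratio mirrors the
published measurement-error mean-square ladder (individual ≫ mounting ≫
digitization) — then a random pose (rotation + translation) so the raw
files genuinely exercise the superimposition, and finally the damage flag.
Fathers are redrawn until pairwise *identifiable* (some locus where they
differ and at least one of the two alleles is absent from the queen), the
regime the whole design presupposes.

### Calibration of the dispersion constants

The two estimated distance statistics are biased relative to the injected
truth: the within-patriline statistic is a chi-type mean over 34
dimensions around an *estimated* mean, and the between-patriline statistic
adds group-mean sampling noise and allometric separation on top of the
injected displacement. `scripts/calibrate_defaults.py` therefore solves for
`sigma_individual` and `delta_patriline` by simulation so that the
*estimated* statistics, averaged over studies at the default design, hit
the published values 0.00951 (within) and 0.01422 (between). The frozen
constants are sigma_individual = 1.37e-3 and delta_patriline = 9.60e-3; a
60-study verification gives within 0.00951, between 0.01414, and a
recovered intra-patriline size variance of 1.52e-3 against the injected
1.542e-3.

### What the generator does not emulate

Real venation data have anisotropic, spatially correlated landmark noise,
landmark-specific digitization error, left–right asymmetry, and patriline
effects that need not be mutually orthogonal; allele frequencies here are
symmetric-Dirichlet draws rather than empirical. Tests passing on this
generator therefore demonstrate correctness of the *procedures* and
internal consistency of the calibrated pipeline — not that any biological
effect size would be recovered from a particular real dataset.

## Morphometric conventions

* **Partial Procrustes.** Every configuration is centered and scaled to
  unit centroid size; rotations only (wings are consistently right
  forewings, so reflections are never fitted); no cos-ρ rescaling. This
  yields exactly 2k − 4 = 34 positive PCA eigenvalues on generic data.
* **GPA.** Iterative: rotate all configurations to the running consensus
  (closed-form 2D rotation via SVD with the reflection branch excluded),
  recompute, re-center and re-scale the consensus, stop when its change is
  below 1e-10 (error on non-convergence). The consensus orientation is
  fixed by rotating its major principal axis onto x and flipping 180° so
  the first landmark has positive x — with rotations only, one sign cannot
  also be fixed, so "positive x" replaces a full quadrant convention. All
  downstream statistics are rotation-invariant; the convention only makes
  outputs byte-reproducible.
* **Tangent projection.** Orthogonal (not stereographic): subtract the
  component along the unit consensus vector; the consensus maps to zero
  and tangent distance agrees with Procrustes distance to second order.
* **Procrustes distance.** Square root of the minimized residual sum of
  squares after centering, unit scaling and optimal rotation of one
  configuration onto the other. Note that d = √(2 − 2·trace) amplifies
  ~1e-16 rounding in the trace to ~1e-8 in the distance; "zero" distances
  are therefore only zero to about 1e-7.
* **TPS files.** Coordinates in file units, y axis up, no image-row
  flipping (digitizers differ); `SCALE=` multiplies coordinates when the
  `scale_coordinates` flag is set (default). Scaling changes sizes by a
  constant and shapes not at all, so the flag only shifts the grand mean of
  logCS.

## Statistical conventions

* **Nested size ANOVA.** Sequential decomposition colony →
  patriline(colony); both mean squares tested against the residual mean
  square, matching the df structure of the emulated tables and common
  practice in this workflow. Zero-residual designs return NaN F flagged
  rather than an error.
* **Variance components.** Descriptive: pooled within-patriline variance;
  pooled unweighted variance of patriline means about their colony
  mean-of-means; variance of colony means about their grand mean.
  Components undefined at a level (fewer than two groups) are NaN.
* **Procrustes ANOVA.** Observation-level sums of squared deviations of
  each stratum's mean tangent vector from its parent stratum's mean, so
  strata sum exactly to the total SS; df are the univariate nested level
  increments × 34. This convention reproduces the published top-stratum
  (patriline) df of 102 = 3 × 34; the published lower-strata df are not
  reconstructible from the stated 39 × 2 × 2 design under any standard
  convention we could find, so lower strata are validated by SS
  conservation and calibration instead. Balanced designs only.
* **MANCOVA.** Sequential (Type I) SSCP in the order Size, Colony,
  Patriline(colony), Size×Colony, Size×Patriline — the order that
  reproduces the published df structure exactly (residual 204, Size F on
  (34, 171), Patriline F on (204, 1056) at n = 220, p = 34). Term ranks
  are detected by SVD of each design block residualized against the
  preceding terms; fully aliased terms raise, listing the term. Pillai
  trace V with s = min(p, q), m = (|p − q| − 1)/2, n′ = (ν − p − 1)/2,
  F = ((2n′ + s + 1)/(2m + s + 1)) · (V/s)/(1 − V/s) on
  (s(2m + s + 1), s(2n′ + s + 1)) df. At p = 1 this reduces exactly to the
  sequential univariate ANCOVA F (tested).
* **Hotelling T².** Pooled covariance; F = T²(n₁+n₂−p−1)/((n₁+n₂−2)p) on
  (p, n₁+n₂−p−1) df; singular pooled covariance raises.
* **CVA with leave-one-out.** Equal priors, assignment by Mahalanobis
  distance to group means in the pooled within-group covariance, refit at
  every fold. No regularization — a singular covariance raises with advice
  to use fewer PCs, matching the deliberate PC-sweep design (2..34).
* **Common allometric component.** Shapes are centered by group means
  (pooled within-group), every coordinate regressed jointly on logCS; the
  slope vector is the CAC; corrected data are the residuals with group
  means re-added so downstream group tests still see group structure.
  Group-centered pooling is the default reading of "pooled" here; raw
  pooling would simply skip the centering.
* **Angle permutation test.** Observed angle between two group-difference
  vectors; null draws 4 distinct specimens and takes the angle between the
  two disjoint-pair difference vectors — the closest literal construction
  of "pairs of shapes randomly drawn from the sample". One-sided toward
  small angles with add-one smoothing: p = (1 + #{null ≤ θ})/(n + 1);
  10,000 draws by default.
* **Welch t.** scipy's unequal-variance t with Satterthwaite df (the
  non-integer published df identify this convention).
* **Distance summaries.** Patriline mean shapes are tangent means mapped
  back to configurations. The between statistic pools *within-colony*
  patriline pairs only — cross-colony pairs would be inflated by the colony
  effect that dominates PC1 — and the within statistic pools all specimens
  from patrilines with ≥ 2 members (singletons excluded with a warning).

## Pipeline choices

The "two main patrilines" per colony are the two largest by measured-wing
count (ties broken by label); the balanced subsamples (default 34 per
patriline, reduced symmetrically when a patriline is smaller) are drawn by
a seeded permutation of the canonical specimen order — a reproducible
stand-in for an unstated sampling rule, not a claim about the original
draw. Hotelling tests per colony use PCA scores of the subsample, capped
at min(34, n₁+n₂−4) variables so the pooled covariance stays numerically
positive definite. All randomness flows from one seed through
`numpy.random.SeedSequence` spawning, so identical (config, seed) runs
produce byte-identical artifacts; the manifest records SHA-256 digests to
prove it.

Problem sizes used by the shipped checks: the acceptance script and the
calibration tests average 20 simulated studies at the full default design
(228 genotyped workers, ≈220 measured wings, 156 error-study records);
structural df checks run once at the published design sizes. A full
default-configuration pipeline run completes in a few seconds on one CPU.

## Known limitations

* The exact minimal-father partition replaces likelihood-based sibship
  software; on low-information pedigrees (few loci, low polymorphism,
  heavy missingness) the minimal partition can merge true fathers, and no
  genotyping-error model is included.
* Procrustes-ANOVA significance is not assessed (no permutation test);
  the table reports SS/df/MS only.
* Data-dependent statistics of the original specimens (F, t, T², PC
  percentages, CVA rates, angles) are not reproduction targets — the
  specimens are not available; only structural/arithmetic quantities and
  generator-calibrated statistics are checked.
* Sliding semilandmarks, missing-landmark estimation, 3D data and
  thin-plate-spline deformation grids are out of scope.
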