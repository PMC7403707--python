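# Methods

## Design and data model

A reciprocal transplant comparison consists of four experimental units —
population A in environment A (AinA), AinB, BinB and BinA — each an
individuals-by-traits matrix with n ≥ 3 individuals and d ≥ 2 traits, every
trait classified as morphology or phenology.  Population A is taken to be
the likely ancestral population; comparisons where that assignment is
uncertain carry an `ancestral_ambiguous` flag that feeds the sensitivity
analysis.  Input is tidy CSV (one row per individual); in a multi-study
table, a trait column that is entirely empty within a comparison is treated
as "not measured there" rather than as missing data, while partially missing
rows are dropped listwise (no imputation: centroids and covariance matrices
need complete rows).

## Standardization

Each trait is z-scored per comparison using the grand mean over all four
units and the pooled *within-unit* SD (within-unit sums of squares over all
four units, denominator Σ(nᵢ − 1)).  Pooling within units preserves the
between-unit mean shifts that the plasticity and divergence vectors measure,
while making traits of different units and scales commensurable — angles are
meaningless on heterogeneous raw scales.  Per-unit scaling was rejected
because it would distort the vectors themselves.  A trait with zero pooled
SD is an error, not silently dropped.  The transformation parameters are
stored on the comparison for reporting.

## Vector geometry

All statistics are computed on standardized data.  Centroids are arithmetic
means; P-matrices are sample covariances with denominator n − 1 (n ≥ 3
enforced).  The four named vectors are plasticity_A = AinA→AinB,
plasticity_B = BinB→BinA, total_difference = AinA→BinB and
evolutionary_divergence = AinB→BinB.  Statistics:

* ∠pp, ∠pt, ∠pe — directed angles in [0°, 180°].  ∠pp compares the two
  plasticity vectors *as defined above*, without reversing either, so
  conserved plasticity (both populations responding identically to the same
  environmental contrast) appears near 180°.
* ∠p_max_e, ∠p_max_p — undirected angles in [0°, 90°] between a vector and
  the leading eigenvector of a P-matrix (AinB's for divergence, AinA's for
  plasticity); 45° is the random expectation.
* projection fraction — 100·(plasticity·t̂)/‖total‖; the classification is
  *opposite* if the angle exceeds 90°, else *overshoot* if the fraction
  exceeds 100%, else *undershoot*; an angle of exactly 90° (fraction 0)
  counts as undershoot.
* log length difference ln‖p_B‖ − ln‖p_A‖; eigenvalue ratio λ₂/λ₁ as a
  P-matrix shape summary; variance change as the trace ratio of foreign vs
  home P-matrices, meta-analyzed as ln(trace ratio) and back-transformed to
  percent for reporting.  Trace was chosen as the total-variance scalar
  because it is the standard summary and invariant to orthogonal rotation;
  determinant or mean variance would be defensible alternatives.

Numerical choices: angles are computed in radians from dot products clipped
to [−1, 1] and reported in degrees; vectors with norm ≤ 1e−12 make an angle
undefined (recorded as missing, not fatal, at the comparison level).
Eigenvectors are sign-normalized (largest-magnitude component positive) and
eigenvalue ties (≤ 1e−12) are ordered by the magnitude of the loading on the
first trait, so outputs are deterministic across platforms.

## Monte-Carlo sampling variances

Sampling uncertainty of every statistic comes from a parametric bootstrap:
each unit is resampled as n new individuals from MVN(observed centroid,
observed P), all four units jointly, and the statistic recomputed per
replicate (default 10,000 replicates, one joint simulation shared by all
statistics of a comparison).  The bootstrap-of-individuals was chosen over
direct Wishart draws of P because it is well defined for any n ≥ 3,
including n − 1 < d.  The Monte-Carlo *mean* is the point estimate entering
the meta-analysis (the plug-in observed value is stored alongside); the MC
variance is the effect's sampling variance.  A replicate with an undefined
statistic (zero vector) yields NaN; effects with more than 10% undefined
replicates are rejected as unstable.  Angles are analyzed on the linear
degree scale — the distributions are bounded, not circular.  Per-comparison
seeds derive from a master seed plus a CRC-32 of the comparison id, so runs
are reproducible and independent of comparison order.

Effects computed from overlapping experimental units (e.g. several
comparisons sharing a unit in a multi-environment study) are not
independent: the sampling covariance matrix sets V[i,j] = r·√(vᵢvⱼ) with
r = 0.5 whenever effects i and j share at least one unit, zero otherwise.
A non-PSD result is projected to the nearest PSD matrix by eigenvalue
clipping, with a warning.

## Multilevel meta-analysis

Model: y = Xβ + u + e + ε with u ~ N(0, τ²·S), e ~ N(0, τ²_obs·I) and
ε ~ N(0, V) fixed.  S is either the same-study indicator matrix or a
phylogenetic correlation matrix expanded to the effect level; an
observation-level random effect is always included.  Variance components
are estimated by REML (Harville formulation, so log-likelihoods are directly
comparable with metafor's `rma.mv`), optimized on the log-σ² scale by
L-BFGS-B from four starting points with a 1e−8 objective tolerance;
components below 1e−8 of the outcome variance are snapped to the τ² = 0
boundary.  β is GLS at the optimum with Wald 95% CIs (symmetric, normal);
no Knapp–Hartung adjustment.  With τ² fixed at 0 and diagonal V the fit
reduces to the classical inverse-variance weighted mean (asserted to 1e−8
in tests, and cross-checked against metafor on identical data).

The phylogenetic correlation matrix is derived from a dated ultrametric
tree (newick): entry (i, j) is the shared root-to-MRCA branch length over
total depth, the Brownian-motion trait covariance.  The tree must be
strictly bifurcating and ultrametric to a 1e−6 relative tolerance; species
names are matched case-insensitively with underscores as spaces.

Random-effect structures are compared by AICc = −2ℓ + 2p + 2p(p+1)/(k−p−1),
where p counts fixed effects plus estimated variance components (this count
is stated explicitly because conventions differ); k ≤ p + 1 yields +∞ with
a warning.  Within 2 AICc units the conventional study-level structure wins
the tie.  Meta-regressions use main effects only — number of traits,
proportion morphology, and the local-adaptation Hedges' g — with continuous
moderators z-scored, and report predicted means at moderator mean ± 1 SD.

## Local adaptation

A comparison qualifies when at least one fitness measure is higher in at
least one native unit than in the transplanted unit sharing its environment
(Hedges' g > 0 for BinB vs AinB or AinA vs BinA).  The moderator exported
to the meta-regression is the B-environment contrast (BinB vs AinB, the
derived population's home) of the measure flagged primary in the input
(first listed otherwise); multiple fitness measures are never averaged.

## Synthetic data generator

The generator emulates the compiled plant reciprocal-transplant literature
this framework targets.  Unit centroids are built as AinA = base, AinB =
base + plasticity_A, BinB = AinB + divergence, BinA = BinB + plasticity_B
(default "mirror": plasticity_B = −plasticity_A, i.e. conserved plasticity,
true ∠pp = 180°); individuals are MVN with a P-matrix of controllable
eigenvalues and orientation, shared by all four units.  Because the
analysis pipeline standardizes traits, ground truth is defined on the
standardized scale (traits divided by the true within-unit SDs); the
`from_angle_pt` / `from_angle_pe` constructors lay out vectors in that
space so the named true angle is hit exactly.  Note that an axis-aligned
P-matrix becomes isotropic after standardization, leaving P_max undefined —
conditions exercising the P_max statistics use a rotated P.

Fitness is normal with unit SD and a mean offset equal to the target
Hedges' g (the estimator's small-sample correction makes ĝ unbiased for the
offset), 30 observations per unit by default.

Meta-level defaults: 34 single-species studies; a study has more than one
comparison with probability 0.32, in which case the count is 2 + Geom(0.5)
capped at 15 (so most studies contribute exactly one comparison, range
1–15); trait counts per study are round(N(3.82, 1.91)) clipped to [2, 9];
per-comparison true target angles are μ + N(0, τ²_study) + N(0, τ²_obs)
clipped to the valid range, with defaults τ²_study = 400 and τ²_obs = 100
deg² (between-study SD 20°, within-study SD 10° — heterogeneity of the
order seen in compiled angle data); 20 individuals per unit; plasticity and
total-difference lengths of 2 SD units.  A matching random ultrametric
species tree (coalescent-style pairwise merging, scaled to depth 1) is
attached, and the whole bundle round-trips through the CSV/newick formats
the readers consume.

What the generator does **not** emulate: non-normal trait distributions
(skew, zero inflation), unequal P-matrices across units, missing data
patterns, or correlated fitness and trait measurements.  Passing tests
therefore demonstrate correctness of the estimators under the stated
sampling model, not robustness to those real-data features.

## Problem sizes used in the test suite

The parameter-recovery check uses 100 replicate meta-datasets of k = 40
single-comparison studies (true ∠pt = 30°, τ²_study = 25, τ²_obs = 10,
100 individuals per unit, 400 MC replicates per effect) and requires
absolute bias below 2° and empirical 95% CI coverage within [88%, 99%].
Calibration checks use 100,000 random pairs per dimension (±0.5°
tolerance, ~0.12° MC standard error).  Oracle and cross-validation checks
are exact to the stated tolerances (1e−8 / 1e−9).  Monte-Carlo variance
monotonicity is checked across per-unit sample sizes {10, 50, 250}.

## Known limitations

* CIs for pooled angle means are symmetric Wald intervals; near the 0°/180°
  boundaries a transform-based interval would respect the range, but no
  specific transform is implemented.
* The eigen-ratio correlation defaults to Pearson with a Monte-Carlo
  percentile CI; Spearman or Fisher-z variants are easy to add but not
  built in.
* Sampling variances are Monte-Carlo only; no analytic (delta-method)
  fallback.
* The ancestral-order sensitivity analysis flips ambiguous comparisons
  independently with probability 1/2 per comparison; joint (per-study)
  flipping is not implemented.
* Angles are treated as linear quantities on [0°, 180°]; no circular
  statistics.
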