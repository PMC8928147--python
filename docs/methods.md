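# Methods

## Diversity metrics

**Alpha.** Observed richness counts features with abundance strictly
greater than zero. Chao1 uses the bias-corrected estimator
s + F1(F1 − 1)/(2(F2 + 1)), where F1 and F2 are singleton and doubleton
counts; the correction is defined for F2 = 0 and reduces to s when
F1 = 0. Chao1 demands integer counts and rejects fractional input, since
singletons are undefined otherwise. Shannon entropy uses the natural
logarithm (a table value of ≈ 4.1 at ~780 features is only consistent
with nats, not bits). Simpson defaults to the Gini–Simpson form
1 − Σp², which lies in [0, 1] and increases with diversity; the inverse
(1/Σp²) and dominance (Σp²) forms are selectable. Faith's PD sums the
branch lengths of the minimal subtree spanning the observed leaves *and
the root* of the supplied rooted tree. Including the root path is one of
two defensible conventions (the verbal "span the members of the set"
definition is ambiguous when a single taxon is observed); it matches
scikit-bio's behaviour and makes PD strictly monotone in the observed
set.

**Beta.** Bray–Curtis is computed on counts as given (the definition
uses sample totals; no proportion normalisation is applied, so it is not
invariant to library size — deliberately). Jaccard binarises at
abundance > 0. Weighted UniFrac is Σ b_e·|A_e/A_T − B_e/B_T| with an
absolute value in the bracket — without it the sum is sign-dependent and
not a distance — and is *raw* (unnormalised) by default, with
normalisation by Σ b_e·(A_e/A_T + B_e/B_T) behind a flag. Unweighted
UniFrac divides the branch length found on paths to exactly one sample's
taxa by the branch length on paths to either sample's taxa. Both
UniFracs are evaluated through a boolean edge-by-leaf incidence matrix
(one matrix product maps all samples onto edges), which makes the
resampling engine cheap; tests verify the implementation against a naive
per-edge tip-set enumeration and against scikit-bio.

**Centroid distances.** Member-to-centroid distances embed the
dissimilarity matrix by principal coordinates, retaining
negative-eigenvalue axes as imaginary coordinates; a sample's squared
distance to its group centroid is the real-axis part minus the
imaginary-axis part, clipped at zero before the square root. This is the
standard dispersion-analysis treatment (as in vegan's `betadisper`) for
semi-metric dissimilarities such as Bray–Curtis.

## Group tests

Kruskal–Wallis is computed with midrank ties and the usual tie
correction H/(1 − Σ(t³−t)/(N³−N)) (resampled diversity values tie
often), with a χ²(k−1) p-value. When every observation is identical the
statistic is undefined under the correction and is reported as H = 0,
p = 1. Effect sizes: η² = (H − k + 1)/(N − k); for two groups, Cohen's
d from group means and SDs.

PERMANOVA partitions squared dissimilarities: SS_T = (1/n)Σ_{i<j} d²_ij,
SS_W = Σ_g (1/n_g)Σ_{i<j∈g} d²_ij, SS_B = SS_T − SS_W, and pseudo-F =
[SS_B/(g−1)]/[SS_W/(n−g)]. On univariate Euclidean input this is
algebraically the classical one-way ANOVA F, which the tests exploit as
an oracle. The permutation p-value uses the (b+1)/(k+1) convention
(minimum attainable p is 1/(k+1); a literal b/k would allow p = 0).
Default permutations: 9,999; the test suite uses 99–999 for speed.
Effect sizes: f² = SS_B/SS_W and ω² = (SS_B − df_B·MS_W)/(SS_T + MS_W).
The ω² denominator is the standard total-plus-residual form; an
"effect-plus-residual" denominator can exceed 1 and is not used.
Exchangeability caveat: duplicated rows arising from with-replacement
resampling are permuted as ordinary units.

## Analytic power

Cohen's d uses the equal-weight pooled SD √((s1² + s2²)/2). With group
sizes of comparable magnitude the difference from the n-weighted pooled
SD is negligible, and the equal-weight form is what reproduces the
published worked-example values this package tests against.

Two-sample t-test power comes from the noncentral t distribution with
ncp = d·√(n1·n2/(n1+n2)) and df = N − 2. Wilcoxon–Mann–Whitney power
follows the G*Power A.R.E. convention: the same machinery with the ncp
kernel *and* the df multiplied by the asymptotic relative efficiency
(3/π ≈ 0.955 for a normal parent; the distribution-free minimum 0.864 is
selectable). Setting A.R.E. = 1 recovers the t-test exactly. For a
two-group comparison the Kruskal–Wallis test is the WMW test, so this
also serves as two-group KW power; analytic KW power for k > 2 is out of
scope. One-way ANOVA power uses the noncentral F with λ = f²·N and
df = (g − 1, N − g).

A-priori sizing for t/WMW searches the smallest integer per-group n
(respecting the allocation ratio) with power ≥ target, and reports the
achieved power (e.g. d = 0.5, one tail, α = 0.05, power 0.8 → 53 + 53 =
106 with actual power 0.803). ANOVA sizing follows the G*Power ANOVA
convention of searching the smallest *total* N in steps of one — that
routine takes total sample size, not per-group size — and reports
per-group n as N//g together with the continuous balanced solution. At
f = 0.38, α = 0.01, power 0.8 this gives total N = 85 (power 0.804),
i.e. 42 per group, where a strictly balanced integer search would give
43 (power at 42+42 is 0.7985, a hair under target).

## Empirical power

From pools X1 and X2 sharing a feature set, each grid point (per-group
size n) draws K replicate pairs of n rows with replacement, applies the
test at level α, and reports EPr = #rejections/K with a 95 % Wilson
interval. Defaults mirror the intended use: n = 5…50 step 5, K = 1000
for alpha/Kruskal–Wallis, K = 100 with 999 permutations for
beta/PERMANOVA, α = 0.01. Degenerate replicates (all values tied; zero
within-group dissimilarity) count as non-rejections — the denominator K
is fixed. One master seed spawns an independent stream per
(n, replicate), so curves are bit-reproducible and order-insensitive.

Because every resampled row is an exact copy of a pool row, per-sample
alpha values and pairwise dissimilarities are computed once on the pools
and sliced per replicate. This is an identity, not an approximation
(duplicate draws receive the zero distances recomputation would give),
and the tests assert bit-equality between the sliced path and full
recomputation from the subsampled tables.

## Synthetic communities

The generator emulates a sparse stool-like amplicon dataset: 169 samples
by 1,995 features at default. Feature proportions follow a log-normal
rank-abundance curve (σ = 3.0 in log space); per-sample compositions are
Dirichlet with total concentration 100 around those proportions (gamma
draws; shapes far below one underflow to zero, which is the intended
sparsity mechanism); sequencing depths are negative binomial (mean
2,000, dispersion 5); counts are multinomial. These defaults were
calibrated once so the mean per-sample observed richness lands near 70
of the 1,995 features — the scale of the community the pipeline is
designed around — and are not adjusted per analysis. A log-normal
counts model is available as an alternative. The phylogeny is a random
rooted bifurcation (sequential random joins, exponential branch lengths,
rate 1); none of the properties under test depend on the tree prior.

Scenario 1 (presence/absence) zeroes a uniformly chosen fraction of
features in every sample of X2, so X2's supports are subsets of X1's.
Scenario 2 (differential abundance) multiplies a uniformly chosen
fraction (default one-fourth) of features by 1 + q/100 in every sample,
preserving presence/absence exactly — which is precisely why purely
qualitative metrics (Jaccard, unweighted UniFrac) sit at null
calibration under Scenario 2 while quantitative metrics gain power, and
why the contrast reverses under Scenario 1.

`two_group_alpha_effect` dials in a target Cohen's d on an alpha metric
by sharpening group 2's proportions (p_i^τ, renormalised) with a
bisection on τ, both groups sharing one rank-abundance curve and
phylogeny; it returns the realised d (tolerance 15 %). This is the
bridge for the cross-check that empirical Kruskal–Wallis power matches
analytic WMW power (within 0.1 at n = 30 in the tests).

**What the generator does not model:** taxonomic or phylogenetic signal
in abundances (the tree is independent of the rank-abundance curve),
batch effects, compositional sequencing artefacts, or the correlation
structure of real gut data. Passing null-calibration and
power-consistency tests on these communities validates the machinery,
not any claim about effect sizes in a particular real dataset —
empirical power on real pilot data remains dataset-specific.

## Problem sizes and numerical choices

The test and acceptance runs use scaled-down communities (60–100 samples
by 80–150 features) and reduced replicate counts where the property
under test does not depend on scale — null calibration, determinism and
oracle equivalence are scale-free, and the chosen sizes keep the whole
suite under half a minute. Distances are computed in double precision;
distance-matrix symmetry is validated at 1e-10 and IO round-trips at
1e-12. Ties in minima and set operations need no tie-breaking. Sample
sizes are integers everywhere except the continuous ANOVA solution
reported alongside the integer search.

## Known limitations

* No rarefaction or depth normalisation is applied anywhere; metrics are
  computed on tables as given. Depth-sensitive metrics (richness, Chao1)
  therefore conflate depth differences with community differences if the
  pools differ systematically in library size.
* PERMANOVA p-values assume exchangeability; with-replacement duplicates
  mildly violate it (documented, kept, because resampling with
  replacement is the estimator's definition here).
* Analytic Kruskal–Wallis power for more than two groups, ANOSIM,
  Hill numbers, and generalised UniFrac are out of scope.
* The η² worked-example value 0.66 sometimes quoted for H(1) = 14.68,
  N = 70 is not reproducible from η² = (H − k + 1)/(N − k), which gives
  0.201; the implementation follows the formula.
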