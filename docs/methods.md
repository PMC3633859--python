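# Methods

## Model and statistic

The screen targets the following contrast. Under the null hypothesis a
quantitative trait is purely polygenic: many additive, independent loci
of small effect plus independent environment. Under the alternative at
least one locus of modest-to-large effect contributes, and a
trait-influencing allele with a visible effect is necessarily rare.
Carriers of such an allele concentrate in one tail of the trait
distribution and, within a family study, carriers are clustered in
families — so the individuals in that tail are more closely related
than the polygenic model predicts.

The statistic is the mean pairwise kinship coefficient among the n_tail
most extreme subjects. Kinship φ_ij is computed exactly from the
pedigree by the standard tabular recursion in topological order
(founders: φ_ii = 1/2, φ_ij = 0; non-founder i with parents f, m:
φ_ij = (φ_fj + φ_mj)/2 for any j preceding i, φ_ii = (1 + φ_fm)/2),
which handles arbitrary inbreeding. Founders are assumed unrelated and
non-inbred; each input family must be self-contained. Only ranks of
the trait enter the statistic, so it is invariant under monotone
transforms.

The test is one-sided (excess relatedness), run on both tails and on a
grid of tail sizes (default 1, 2, 4, 6, 8%). Tail counts are resolved
per trait on the non-missing sample by round-half-up of n × fraction,
which reproduces the canonical counts 15/30/59/89/118 at n = 1,481; a
count below 2 is an error. Boundary ties are broken by individual id
and flagged with a warning. The minimum p per side (p_min) is reported
per trait; no correction is applied across tail sizes or sides within
a trait (a deliberate reproduction of the screen's original design —
the report says so in a header comment), while the correction across
traits uses the Li–Ji effective number of tests (sum over absolute
eigenvalues λ of the trait correlation matrix of 1{λ≥1} + frac(λ),
ceiling-rounded) and Bonferroni on p_min.

## Null generation

The null distribution of the statistic is conditional on the observed
pedigrees and on h², and is built by simulation (default 10,000
replicates). Polygenic traits are simulated by Mendelian sampling in
topological order rather than by a Cholesky factor of the covariance:
founders draw additive values from N(0, h²); a non-founder with parents
f, m draws the parental mid-value plus a Mendelian deviation with
variance (h²/2)(1 − (F_f + F_m)/2), where F is a parent's inbreeding
coefficient; environment is independent N(0, 1 − h²). This is O(n) per
replicate, exact for inbred pedigrees, and the equivalence of the
implied covariance 2Φh² + (1 − h²)I with a direct multivariate-normal
construction is verified by test, not assumed. One set of replicates
is shared by all tails and both sides of a trait; replicates are drawn
from a single vectorized generator stream per (seed, task), so a run is
bit-reproducible from its master seed.

Empirical p-values are raw exceedance proportions (#null ≥ observed)/N;
an observation beating every replicate is displayed as a bound
("< 1/N"), never as zero. Statistic values are compared with a 1e-9
absolute tolerance and rounded to 9 decimals before support counting,
because on simple pedigrees the statistic lives on a lattice (multiples
of 0.25/C(n_tail, 2)) and float summation order must not split ties.

Because the empirical CDF is discrete, the rejection region at level α
is the smallest realized null value whose exceedance proportion is ≤ α;
the achieved size is reported, and when even the largest realized value
is too frequent the test is reported infeasible together with the
minimum achievable size. With this counting convention the exceedance
at the null minimum is always 1, so as α → 1 the threshold settles on
the second-smallest distinct value.

## Rare-variant alternative

A single additive biallelic locus is gene-dropped: founders receive two
alleles iid Bernoulli(q) (Hardy–Weinberg proportions), each offspring
inherits one uniformly chosen allele per parent; no conditioning on the
variant segregating. The per-allele effect is a = sqrt(v / (2q(1−q)))
so the locus explains the fraction v of total trait variance in a
random-mating population (v may also be given as a fraction of genetic
variance, converted as v·h²). The trait is
±a·(copies − 2q) + polygenic background with variance h² − v +
environment with variance 1 − h²; the variant term is mean-centered,
which keeps total variance 1 and cannot affect a rank-based statistic.
Power experiments score the tail on the variant's direction of effect
only (the screen itself always tests both sides), build one null per
(cohort, h²), and report per-tail power with binomial Monte-Carlo
standard errors plus carrier enrichment of the tail. The tail size
that maximizes power tends to match the expected carrier frequency
2q(1−q) + q².

## Trait preparation and h²

Pipeline order is fixed: rank-based inverse normal transform (Blom
offset (r − 3/8)/(n + 1/4), average ranks for ties) applied when a
Shapiro-Wilk check rejects normality at 0.01 or on request; then OLS
residualization on an intercept plus covariates (categoricals expanded
to indicators), residuals re-standardized; stratified analyses are
independent runs on subsets sharing the pedigree. Missing values stay
missing and are excluded before tail counts are resolved.

h² enters only through the null simulation. It can be supplied
directly, or estimated by maximum likelihood under the polygenic
covariance σ²(2Φh² + (1 − h²)I), with σ² and a GLS mean profiled out in
the eigenbasis of 2Φ (one eigendecomposition per subject set, reused
across traits and replicates); the estimate comes from a grid over
[0, 0.99] refined by bounded minimization, with a profile-likelihood
95% interval. This estimator is a self-contained stand-in validated by
parameter recovery on simulated data (bias < 0.05 at 500 sib-pair
families); it is a single-variance-component model, not a full REML
with covariate-by-strata structure.

## Synthetic cohorts and what they do and do not show

Two generators mirror the simulation designs the test was characterized
on: disjoint four-person nuclear families (two founder parents, two
full sibs, all study subjects; 371 families = 1,484 individuals) and
sibling-pair cohorts (one full-sib pair per family as study subjects,
parents present only as connectors; 741 families = 1,482 subjects).
Defaults elsewhere follow the same characterization: h² = 0.4,
tail grid 1–8%, α = 0.05, 10,000 null and 1,000 alternative
replicates. These cohorts have only kinship values {0, 0.25} among
study subjects, so they probe the discrete-null pathologies sharply but
say nothing about deep multi-generation pedigrees, where the statistic
takes many more values and power degrades as distant relationships
multiply. Passing tests on these cohorts therefore validate the
machinery (kinship, simulation, thresholds, calibration), not
field performance on complex real pedigrees, which additionally involve
pedigree errors, shared environment, and ascertainment that the
generators do not emulate.

Two of the reported diagnostics are extreme-value statistics of a
1,000-replicate null and are intrinsically seed-sensitive; the package
reports them as computed rather than smoothing them away. The distinct
-value count in the top quintile (nuclear cohort, 1% tail) is
essentially (largest number of related tail pairs realized) minus a
constant; its modal value across seeds is 5 with 4 and 6 also realized,
and it is reported as the modal count over 10 independent nulls. The
sib-pair minimum achievable test size is the frequency of the largest
realized statistic value: in roughly two thirds of seeds a rare
three-sib-pair tail appears once or twice (minimum size 0.001–0.003)
and in the remainder the largest value is the two-sib-pair lattice
point with frequency ≈ 0.015–0.026. Both behaviors follow
quantitatively from closed-form bivariate-normal tail-co-membership
probabilities (sib trait correlation 2φh² = 0.2), which is how the
simulator was cross-checked.

## Numerical and design choices

- Kinship by recursion, not matrix powers: identical results, O(n²)
  deterministic, clearer contract. Matrices are dense; cohorts in the
  thousands of subjects are well within desk scale.
- Null replicates vectorized across a single generator stream instead
  of per-replicate substreams: two orders of magnitude faster for
  10,000-replicate nulls, still reproducible from one master seed.
- Null distributions are cached on disk keyed by (pedigree content
  hash, subject set, h² to 3 decimals, replicate count, seed), making
  multi-trait screens with shared h² cheap; a flag bypasses the cache.
- Problem sizes in the test suite are scaled to keep the full run in
  about a minute (e.g., 100–500 families, 300–5,000 replicates for
  calibration checks, 10⁵ replicates only for closed-form variance
  checks on small cohorts); the headline experiments run at full size
  (10,000 null replicates) in the acceptance script and one dedicated
  test.
- Every output file carries the tool version, a resolved-config hash,
  and the master seed in a `#` header comment.

## Known limitations

- Autosomal kinship only; no X-linked coefficients, no Jacquard
  identity states, no pedigree trimming or splitting (inputs are
  assumed already trimmed to tractable families).
- Single-locus alternative; no allelic heterogeneity, dominance,
  epistasis, linked markers, or ascertainment.
- The h² estimator is a single-component ML profile, and heritability
  estimated on a trait that actually carries a major variant absorbs
  part of that variance into the polygenic null, which is mildly
  conservative for the screen.
- The across-trait correction ignores the within-trait search over
  tails and sides, by design; interpret p_min_corrected accordingly.
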