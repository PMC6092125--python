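# Methods

## Model and assumptions

`coaltrait` treats a quantitative trait as the sum of contributions from `L`
unlinked loci. Each locus has a genealogy drawn from the multispecies
coalescent (MSC) along a fixed, rooted, bifurcating species tree whose branch
lengths are in coalescent units (multiples of 2N generations of a reference
population of size N). One haploid lineage is sampled per species — the
species trait value is a population mean, so within-species sampling and
segregating variation are not modelled. Within a population carrying `k`
lineages and a population-size multiplier `f`, the waiting time to the next
coalescence is exponential with rate `k(k−1)/2 · 1/f` per coalescent unit;
lineages that fail to coalesce are passed to the parent population, and
everything coalesces in the root population eventually.

Mutations are neutral and additive: on a gene-tree branch of length `ℓ` the
mutation count is Poisson(`ℓ·θ/2`) — with θ = 4Nμ per locus, 2Nμ = θ/2 is the
mutation rate per coalescent unit — and each mutation's effect is an
independent Normal(0, σ²_M/L) draw inherited by every species descending from
that branch. The ancestral state contributes 0, so the root trait value is 0
and trait values are deviations from the ancestral mean. No dominance,
epistasis, selection, recombination within loci, or gene flow.

The infinitesimal `σ²_M/L` scaling keeps the expected trait variance constant
in `L`, so locus-number comparisons isolate the effect of genetic architecture
from trait scale. σ²_M defaults to 1; the trait scale is arbitrary and all
fitted quantities are reported on the simulated scale.

## Closed-form expectations and the population-size multiplier

For the three-species tree ((A,B),C), internal branch `t`, terminal branch
`t_e`, the plain closed forms (`coal_var`, `coal_cov_sisters`,
`coal_cov_nonsisters`) are the textbook single-population-size expressions
with prefactor `pref = (θ/2)·σ²_M` and `x` the internal branch in local
coalescent units. The bracketed sister-covariance expression has a removable
singularity at x = 0, handled by its continuity limit 1/3; algebraically the
whole expression equals `x + e^(−x)/3`, which the tests verify to 1e-12 at a
thousand random points.

When ancestral populations are scaled by `f` (terminal populations unchanged),
every coalescent waiting time accrues path length `f` times faster in
reference units while the fixed branch lengths do not. `coal_vcv_3taxon`
therefore evaluates the closed forms at `x = t/f` and multiplies all
waiting-time terms by `f`, leaving the terminal-branch term alone:

    Var      = pref · (t_e + f·[x + 1 + e^(−x)/3])
    Cov(A,B) = pref · (t + f·e^(−x)/3)
    Cov(A,C) = pref · f·e^(−x)/3

Two consequences that the test suite checks against the simulator: all entries
grow with `f` (the deep-coalescence effect — larger ancestral populations mean
taller gene trees), and the sister/non-sister covariance gap stays pinned at
`pref·t`, so the *normalized* covariances converge as discordance rises — the
hemiplasy signature.

## ILS conditions and calibration

ILS levels are specified as target gene-tree discordance fractions, not as raw
multipliers. For three taxa the multiplier solving `(2/3)·e^(−t/f) = d` is
analytic (`calibrate_multiplier`); target 0 maps to `f = 1` by convention (the
unscaled tree's residual discordance, (2/3)e⁻⁴ ≈ 1.2% on the study tree, is
the attainable floor). For larger trees no closed form exists;
`calibrate_multiplier_mc` bisects geometrically on `f ∈ [1, 10⁶]` against the
Monte-Carlo discordance fraction (topology-key mismatch over `n_sims` gene
trees), stopping when the objective is within 2 Monte-Carlo standard errors of
the target or after 40 iterations. Discordance is monotone in `f`, so noisy
bisection converges to MC accuracy; calibration sims default to 10,000
(SE ≈ 0.005 at mid-range targets).

## Estimation

`BrownianMotionModel.fit()` computes maximum-likelihood estimates for one
observation per species: the trait vector is multivariate normal with mean
`root_state·1` and covariance `σ²·T_λ`, where Pagel's λ multiplies the
off-diagonal entries of `T`. For fixed λ, the root state and rate have
closed-form GLS/ML solutions (rate with denominator `n`, hence the familiar
`(n−1)/n` downward bias that the tests verify); λ is profiled over [0, 1] by
bounded scalar optimization (tolerance 1e-8) with both boundaries checked
explicitly, since with five species the profile often peaks at 0 or 1. ML
rather than REML matches the default behaviour of the standard comparative
fitting tools. Covariance solves use Cholesky factorization and raise a
diagnostic error on failure — no silent regularization. Degenerate input
(identical trait values) yields `σ̂² = 0` with the likelihood flagged as
degenerate rather than a numerical overflow.

With only five tips, the λ̂ sampling distribution under pure BM is strongly
bimodal: roughly 45% of replicates at the upper boundary, a third at zero,
median ≈ 0.97 but mean ≈ 0.64. Summaries of λ̂ should therefore be read as
distributions, not means; the acceptance checks use the median and the
boundary masses.

## Phylogenetic ANOVA

`phylo_anova` compares two species groups with the ordinary one-way F
statistic (df 1, n−2) referred to an empirical null of F statistics from
trait vectors simulated under BM on the species tree. The null rate is fixed
at σ² = 1 because F is scale-invariant, decoupling the null from any estimated
rate. The p-value uses the add-one rule, `p = (1 + #{F_sim ≥ F_obs})/(1 + m)`,
so p is never 0 and ties count toward rejection. Zero within-group sum of
squares yields F = +inf, which is treated as maximally extreme.

The pair-vs-rest screen (`count_significant_groupings`) runs all C(5,2) = 10
groupings per replicate. Because the null distribution depends only on the
tree and the grouping — not on the observed data — the default implementation
simulates each grouping's null once and shares it across replicates. This
leaves the mean significant count unbiased while making the
10-groupings × 1000-replicates screen effectively instantaneous; fully
independent nulls per replicate are available via `share_null=False`. Defaults:
1000 null simulations, α = 0.05.

## Threshold traits

Liabilities are the simulated trait values. The cutoff for a condition is the
pooled sample mean plus one sample standard deviation (ddof = 1), pooled over
all species and replicates of that (condition × locus-count) cell, so
higher-discordance cells get proportionally higher cutoffs and the pattern
table is invariant to rescaling a cell's liabilities. Values strictly above
the cutoff code as 1; ties code as 0.

A pattern is uninformative when fewer than two tips carry either state;
congruent when the '1' set is exactly a species-tree clade (one 0→1 gain,
root state 0); incongruent otherwise. The alternative convention, in which the
complement of a clade also counts (free root state), is exposed as
`allow_complement` and off by default — on the five-taxon caterpillar it would
additionally make patterns like 00011 congruent. The exhaustive 2⁵-pattern
test pins the classification against Fitch parsimony scores.

## Pipeline and reproducibility

`run_experiment` crosses ILS conditions with locus counts, simulating one
trait dataset per cell and running all applicable analyses (λ fits need ≥ 4
tips, the ANOVA screen and threshold tally need the 5-species design). Each
cell's seed derives from the root seed and the cell's own coordinates (target
discordance, locus count), so any subset of cells reproduces exactly the same
numbers as a full run. Replicate rows are bit-for-bit reproducible from the
stored per-replicate seeds; genealogies and mutations use separate RNG streams
so gene-tree topologies do not depend on θ. Defaults follow the study design
(1000 replicates per condition, five locus counts, θ = 4); the `--fast`
profile caps cells at 200 replicates and 200 null simulations for quick runs.

## What the simulations do and do not show

The generator reproduces the study conditions: ultrametric three- and
five-species trees with coalescent-unit branch lengths, discordance tuned by
ancestral population size, Gaussian additive mutational effects, one sampled
lineage per species. Real data additionally feature estimated (not known)
species trees, within-species variation and measurement error, selection,
non-Gaussian and non-additive genetic architectures, and discordance caused by
introgression or gene-tree estimation error — none of which are modelled.
Passing tests therefore demonstrate correctness of the MSC trait model and the
documented behaviour of comparative methods under it, not robustness of those
methods on empirical datasets.

## Problem sizes used by the test suite

Analytic identities are checked to 1e-12; optimizers against grid searches to
1e-6 in log-likelihood. Monte-Carlo checks state their tolerances as multiples
of empirical standard errors: simulator-vs-theory moments use 1000 replicates
of 25 loci per condition (3 SE); estimator calibration uses 2000 BM replicates
(3 SE); ANOVA test size uses 1000 replicates with 1000-simulation nulls (band
0.03–0.07 at α = 0.05); the discordance trend battery runs the full five
conditions at 1000 replicates for L = 5 and L = 100, allowing adjacent wiggles
within two combined SEs while requiring the overall movement across the
discordance range to exceed one combined SE.
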