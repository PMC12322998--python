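# Methods

## The statistic

For each gene, mRNA and protein abundances (log2 scale) are paired per
sample; a sample contributes to a gene iff both layers are quantified for
that gene (pairwise-complete filtering, maximizing the per-gene n). Within
each condition the coupling is summarized by Spearman's rank correlation
(average ranks for ties, i.e. Pearson on midranks), and the statistic of
interest is the difference

Δ_corr = ρ_tumor − ρ_normal ∈ [−2, 2].

A correlation is only reported when the condition has at least `min_n`
paired points for the gene. The default `min_n = 15` reflects the smallest
group size at which rank correlations are stable enough to difference;
per-cohort overrides (e.g. 10 for cohorts with small normal pools such as
endometrial tumors) keep small cohorts analyzable at a known cost in
variance. A Spearman correlation over a constant vector is reported as
undefined (NaN), never as 0 — coercing it to 0 would fabricate a coupling
signal; such genes are excluded from Δ_corr for that condition.

Tumor and normal correlations are computed over disjoint sample sets;
patient pairing between a tumor and its adjacent normal, where it exists,
is deliberately not used (the statistic is a group-level contrast, not a
paired difference).

## Permutation inference

The null hypothesis is that the tumor/normal label is uninformative for a
gene's coupling. It is materialized directly: labels are reshuffled across
the gene's paired observations, preserving group sizes and never breaking
the within-sample (mRNA, protein) pair; each relabeling yields a "false"
Δ_corr. With the null multiset {Δ*} in hand,

z = (Δ_obs − mean(Δ*)) / sd(Δ*),  p = 2·(1 − Φ(|z|)),

with the p-value floored at the smallest positive normal float. The normal
approximation (rather than the empirical rank of Δ_obs) is used because the
permuted Δ_corr distribution is close to normal at the group sizes where
the test applies and because it gives p-value resolution below
1/(n_perm+1), which matters for FDR correction over thousands of genes.
The empirical p, (1 + #{|Δ*| ≥ |Δ_obs|})/(n_perm + 1), is available
alongside (`report_empirical`). The test is two-sided: both gains and
losses of coupling are of interest.

Engine details:

- **Antithetic pairs.** Each random shuffle contributes two null values:
  the tumor block read from the head and from the tail of the shuffled
  sample order. Each member is marginally a uniform size-preserving
  relabeling, so the null law is unchanged, but the pooled multiset exactly
  negates under a global tumor/normal label swap. Consequently Δ_obs and z
  negate and p is invariant under relabeling the conditions — numerically,
  not merely in distribution. `n_perm` (default 10,000) is rounded up to
  even.
- **Exhaustive mode.** When C(n, n_tumor) ≤ 10,000 the null is enumerated
  over all label assignments instead of sampled. The z → p mapping is the
  same code in both modes.
- **Degenerate nulls.** If sd(Δ*) = 0, p = 1 when Δ_obs equals the point
  mass and 1/(n_perm+1) otherwise — conservative, and no division by zero.
  Permutations producing an undefined correlation (constant subvector, only
  possible with heavily tied data) are redrawn, with a total budget of
  10·n_perm draws; past the budget the gene is reported untestable.
- **Reproducibility.** Each gene's permutation stream is seeded from the
  global seed plus a CRC-32 of the gene symbol, so results do not depend on
  gene iteration order or parallelization. A `shared_permutations` option
  derives the stream from the global seed alone, so genes with identical
  paired sample sets see identical relabelings (preserving the inter-gene
  correlation structure of the null); the default is independent streams.

BH correction is applied per cohort across all testable genes; families
are never pooled across cohorts. The significance call is q < α (default
0.05) **and** |Δ_corr| ≥ 0.2 — the effect-size gate keeps trivially small
but well-measured shifts out of downstream gene lists.

## Differential-expression comparator

Per gene and layer: two-sided Wilcoxon rank-sum p (exact enumeration when
both groups have ≤ 8 observations and no cross-group ties; otherwise the
normal approximation with tie and continuity correction — the two agree to
about 0.01 at the crossover size) and mean log2 fold-change, computed as a
difference of means because inputs are contractually log2-scale (a
`linear_input` option applies log2 first). BH is per layer per cohort; the
DE flag is q < 0.05 and |log2FC| > 1. The four-way overlap
(DE-only / Δ_corr-only / both / neither) treats a gene as DE when flagged
in either layer, since the comparison is between gene sets.

## Trans-mutation screen

Within a cohort's tumors, the top-k (default 10) most frequently mutated
genes are selected among genes with at least `min_n` mutant **and** `min_n`
wild-type tumors (ties broken by count descending, then symbol ascending).
For each such driver, every quantified gene — including the driver itself,
labeled *cis* — is tested for a coupling difference between mutant and
wild-type tumors using the identical permutation engine (the grouping mask
is the only difference; a regression test asserts bit-identical results
through both vocabularies). Mutation status is binary: any retained record
mutates the sample; variant-class multiplicity and zygosity are ignored. BH
is applied within each driver's trans set, never across drivers;
significance is q < 0.05 (no effect-size gate, matching the screen's
exploratory role).

## Over-representation analysis

Significant-gene lists (both Δ_corr signs pooled by default; single-sign
options exist) are tested against GMT gene sets with the one-sided
hypergeometric upper tail P(X ≥ k), after intersecting query and sets with
the background universe — by default the genes quantified well enough to be
tested in that cohort, which is the correct conditioning for
coverage-limited proteomics. BH across tested sets. Depletion is not
tested. This is a local, network-free ORA; external enrichment services
with proprietary statistics will give numerically different p-values.

## Synthetic cohorts

The generator draws each gene × condition block from a bivariate Gaussian
whose Pearson parameter is r = 2·sin(π·ρ_s/6), the exact inverse of the
population Spearman correlation of a bivariate normal — so simulated
coupling targets are exact in population and verifiable by convergence.
Defaults emulate the shape of a typical tumor/normal proteogenomic cohort:
~100 tumor + ~30 normal samples, thousands of genes, per-gene coupling
targets from a mixture (60% U(0, 0.7), 25% U(−0.2, 0.2), 15% U(−0.5, 0))
spanning weakly negative to strongly positive values. Tumor samples can
carry log2 abundance shifts, uniform stage labels (tumors only; normals
are unstaged, as in clinical annotation), and Bernoulli driver mutations;
mutation-linked genes switch their copula parameter within mutant tumors,
giving the trans screen a controllable positive case.

What the generator does **not** emulate: TMT batch structure and
normalization artifacts, heavy-tailed or skewed marginals, and
missing-not-at-random proteome dropout — missingness here is masked
independently per cell (MCAR). Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under clean
conditions, not robustness to every real-data pathology; rank statistics
are insensitive to monotone marginal distortions, which covers much, but
not all, of the gap.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen to give
stable Monte-Carlo verdicts: 500-gene null cohorts at n = 30+30 with 1,000
permutations for calibration checks (binomial bands at 2 standard errors),
200-gene cohorts at n = 50+50 for effect recovery (the finite-n downward
bias of the sample Spearman correlation — about 0.01 at n = 50 for
ρ_s = 0.6 — is visible but well inside the ±0.05 recovery band), 20-run
repetitions for run-level rates, and exhaustive enumeration oracles at
3+3 and 4+4. Oracle agreement checks (rank-Pearson Spearman, step-up BH,
hypergeometric enumeration) are asserted to 1e-12.

Other numerical choices: ties get average ranks everywhere; computed
correlations are clipped to [−1, 1] to absorb last-ulp excursions; BH
step-up is delegated to statsmodels and cross-checked against an
independent hand-coded reference; the hypergeometric tail is evaluated via
the survival function with log-space internals.

## Known limitations

- The z-based p-value is mildly anti-conservative in the far tails when
  the permuted null deviates from normality; the empirical p option bounds
  this at the cost of resolution.
- Stage-stratified correlations drop a (cohort, stage) stratum with fewer
  than 10 genes having a defined correlation; a `stage_min_genes` knob
  allows a sample-count reinterpretation of that rule.
- `shared_permutations` only reproduces literally shared relabelings for
  genes with identical pairwise-complete sample sets; with per-gene
  missingness the streams are shared but the effective relabelings differ.
- The ORA universe is gene-symbol based; no identifier mapping or alias
  resolution is attempted anywhere in the package.
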