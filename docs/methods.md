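# Methods

This note documents the models and procedures implemented in `coexnet`,
the defaults and numerical choices that matter, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
more than one construction was defensible.

## Association measures

All measures operate on a genes × samples matrix from which zero-variance
genes have been removed (`filter_zero_variance`; a constant gene has an
undefined correlation denominator and carries no ranking information).
Standard deviations use the sample (n−1) denominator throughout —
correlation, per-sample scaling, shrinkage estimation — matching the
default of mainstream statistical software.

**PCC / SCC.** Pearson correlation is computed blockwise on standardized
rows (`block_size` rows at a time, default 2048), so peak memory beyond
the output is O(block × N). Spearman is Pearson on within-gene sample
ranks with average ranks for ties.

**HRR.** For each gene A the correlations CC(A, ·) are ranked decreasingly
with rank 0 reserved for A itself, and HRR(A,B) = max(rank_A(B),
rank_B(A)); lower is better, diagonal 0. Ranking uses *signed*
correlations by default (a strongly negative correlate is a poor partner);
ranking |CC| instead is a one-line change in the caller by passing
`abs(cc.values)`, deliberately not a separate code path. Ties in CC are
broken by ascending partner index, so each row's off-diagonal ranks are
exactly the permutation {1, …, N−1} and any top-k cut is reproducible.
Ties are measure-zero on real-valued expression data; the rule only
matters for degenerate or duplicated profiles.

**Mutual information.** The Kraskov–Stögbauer–Grassberger estimator
(variant 1) with Chebyshev joint metric, k = 3 neighbors by default; units
nats, negative estimates clipped to 0. The estimator assumes continuous
data; a seeded jitter of relative scale 1e-10 breaks exact ties (on counts
or quantized intensities) without affecting the estimate otherwise. The
diagonal is stored as +inf — self-MI of a continuous variable is unbounded
— and is excluded from thresholding. Validated against the closed form
−½ln(1−ρ²) for bivariate Gaussians and the independence limit.

**Shrinkage partial correlation.** The sample correlation matrix R is
shrunk toward the identity, R* = (1−λ)R + λI, with the analytic
Schäfer–Strimmer intensity λ* = Σ Var̂(r_ij) / Σ r_ij² (off-diagonal
sums), clamped to [0.01, 1] so R* is invertible even when genes greatly
outnumber samples. Partial correlations come from the precision matrix:
PC(i,j) = −Ω_ij/√(Ω_ii Ω_jj), Ω = R*⁻¹. In the n ≫ p regime the result
agrees with unshrunk inverse-correlation PC to 0.02; the first-order
formula R_xy.z = (R_xy − R_yz R_xz)/√((1−R_yz²)(1−R_xz²)) is exposed
separately (`first_order_pc`) and doubles as an independent oracle in the
tests.

## Networks

`top_pairs` cuts a score matrix to exactly k best pairs (highest
correlation/MI or lowest HRR), reporting the k-th score as the implied
dynamic threshold; ties at the cut are resolved lexicographically so the
list size is exact. The default top-K is capped at 2% of all possible
pairs — a 10-million-pair list among 33,604 transcripts covers 1.77% of
pairs, and larger fractions defeat the purpose of thresholding. Nested
sub-networks take the best ⌊fraction·k⌋ records for fractions
1/5/10/20/40/60/80%.

`trim_to_vertex_count` adds edges best-first and stops *before* the first
edge that would exceed the vertex budget (the budget is an upper bound;
`allow_overshoot` admits that one edge instead). Cross-platform
intersection keeps unordered gene pairs present in both edge sets; because
"common vertices" is ambiguous, both |V(a) ∩ V(b)| and the vertex count of
the common-edge subgraph are reported.

## Evaluation against annotations

The reference set removes electronically inferred (IEA) annotations and
terms outside 5–100 genes: small terms cannot vote, large terms are
non-specific.

**Edge confusion.** Every unordered pair over a gene universe (the
dataset's genes; by default network vertices ∪ annotated genes) is
classified: network edges sharing a term are TP, edges without a shared
term FP, co-annotated non-edges FN, the rest TN. Curves over increasing
network sizes are partial — they stop at the largest list evaluated — and
the trapezoid AUROC covers only the observed FPR range.

**Neighbor-voting AUROC.** Per term, annotated network genes are split
into 3 seeded folds; each fold's labels are hidden and every gene is
scored by the fraction of its neighbors among still-visible annotated
genes; the fold AUROC separates hidden positives from never-annotated
genes. Term AUROC = mean over folds, NV AUROC = mean over terms; terms
with fewer annotated network genes than folds are skipped and listed with
NaN. Midrank (Mann–Whitney) tie handling everywhere — neighbor-vote scores
are heavily tied on sparse graphs, and midranks make the degree-regular
null exactly 0.5.

**Global AUROC.** One pooled ROC over all (gene, term) instances scored by
the gene's neighbor vote for the term. Two calibration steps keep the
pooled statistic at 0.5 under random label attribution, which the raw
pooled construction is not: (i) the vote is divided by the leave-one-out
pool size (an annotated gene's own label is never available to its
neighborhood, leaving m−1 rather than m annotated genes among the other
genes — without the correction positives are systematically underscored);
(ii) scores are standardized to midranks within each term before pooling
(terms of different sizes otherwise place their instances on different
score scales, biasing the pooled ROC toward large terms). Both corrections
leave perfectly separated networks at AUROC 1.0.

**Node-degree AUROC.** Per term, genes ranked by degree alone; the mean
over terms measures how much apparent predictivity is available from
hubness rather than function-specific wiring.

**Pair enrichment.** Per term, the exact hypergeometric upper tail of
co-annotated edges among network edges, with population all pairs over the
annotated universe. Benjamini–Hochberg at α = 0.05 by default; raw-p
counting (`correction="none"`) is available because "significantly
enriched" is often reported uncorrected, and both counts are in the
output.

## Pathway-Level Coexpression

Extraction keeps edges touching at least one guide gene plus edges between
two associated genes when those survive the network threshold, then
removes non-guide vertices of degree 1 (connected to a single guide) in
one pass. The prune is deliberately not recursive — the removal rule
targets genes "connected to only one guide gene", not a cascading peel —
and `iterative_prune=True` provides the recursive variant. Pruning happens
before community detection.

Communities are detected with fast-greedy (Clauset–Newman–Moore)
agglomerative modularity maximization as implemented in networkx;
modularity Q = Σ_c [e_c/m − (d_c/2m)²] is recomputed in-package from the
labels and cross-checked against networkx in the tests.

The sub-pathway × community contingency table counts guide genes only;
communities without guides are dropped (they carry no information about
guide partitioning), as are sub-pathways with no guide in the graph. The
Pearson Chi² gets a Monte-Carlo p-value from 2,000 fixed-margin random
tables (Patefield sampling via `scipy.stats.random_table`), p = (1 +
#{χ²_sim ≥ χ²_obs})/(replicates + 1). The normalization divides by χ²_max
= N_g(n_present − 1): any table in which each present sub-pathway occupies
its own distinct community attains this value exactly, for arbitrary row
sizes, so the normalized statistic lies in [0, 1] with 1 iff the partition
is ideal up to column permutation. The published description of the
denominator ("maximal expected value, the ideal partition") admits other
readings, so the raw χ² and p are always emitted alongside the normalized
value. Statistics with p > 0.05 are reported as 0; degenerate tables
(single row or column) as (0, 1, 0).

## Sample quality control

Arrays pooled from many experiments are screened by two tests: an
upper-quartile dispersion test (a sample whose 75th-percentile value
deviates from the cohort median of 75th percentiles by more than `mad_k` =
5 median absolute deviations) and a two-sample Kolmogorov–Smirnov test of
the sample against the pooled remaining samples (reject at `ks_alpha` =
1e-3). A sample is discarded only when both tests flag it — either test
alone fires on benign biological variation. The thresholds are our
defaults (the combination of tests is standard, the cutoffs are not) and
both are configurable; the KS test uses the asymptotic p-value, adequate
at the gene counts (thousands) where the test is meaningful.

## Synthetic data

`simulate_expression` plants modules with a single latent factor each:
expr = √ρ·z_m + √(1−ρ)·ε, giving expected within-module PCC exactly ρ and
cross-module PCC 0 at O(genes × samples) cost. Defaults used across the
tests and the acceptance script: ρ = 0.7, 200 samples, 20–50-gene modules
— a regime where sampling error on a correlation is ~0.05 and module
recovery is expected but not trivial. The `nb_counts` mode maps the latent
values through a per-gene log-normal base expression to negative-binomial
counts (dispersion 0.1, variance μ + 0.1μ², median library ≈ 10⁶), with
log-mean tracking the latent values one-to-one so the module structure
survives the count layer and the TPM → log2 path can be exercised.

The generator emulates block-correlated modules, module-aligned annotation
terms (optionally rewired by `noise_frac`) and guide sets whose
sub-pathway labels are the planted modules. It does **not** emulate
microarray probe effects, batch structure, scale-free degree
distributions, overlapping modules, or non-monotone gene relationships —
so passing tests demonstrate correctness of the statistical machinery and
recoverability of modular signal, not performance on the full complexity
of real transcriptome compendia.

## Problem sizes and determinism

Tests and the acceptance script run at 30–500 genes and 40–200 samples
with 20-seed replication where a claim is distributional; these sizes make
every statistic exercised at full precision while keeping the whole suite
in seconds. Every stochastic stage (fold splits, Monte-Carlo tables,
simulation, jitter) consumes an explicit seed and is bit-reproducible
given it; the Monte-Carlo p varies across seeds within binomial error
√(p(1−p)/2000).

## Known limitations

* The MI matrix is O(G² · n log n); for transcriptome-scale G it is the
  slowest measure by far, as in the original estimator.
* The shrinkage λ floor of 0.01 biases partial correlations slightly
  toward zero when n ≫ p; lower the floor for small, well-conditioned
  problems.
* Fast-greedy community detection has a known resolution limit on very
  small or very large communities; alternative algorithms are out of
  scope.
* The leave-one-out/midrank calibration of the global AUROC makes its
  absolute values comparable across networks but not numerically identical
  to implementations that pool raw neighbor-vote fractions.
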