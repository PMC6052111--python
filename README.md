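# coexnet

Gene co-expression network construction, evaluation and pathway-level
analysis.

`coexnet` is for transcriptomics researchers who build genome-wide
co-expression networks from expression matrices (RNA-seq counts/TPM or
microarray intensities) and want to (i) compare association measures, (ii)
quantify how well the resulting networks recover known gene function, and
(iii) query them with pathway guide genes to reconstruct sub-pathway
structure.

## What it computes

**Six association measures.** Pearson (PCC) and Spearman (SCC) correlation,
their highest-reciprocal-rank ranked forms, k-nearest-neighbor mutual
information (Kraskov estimator, nats) and shrinkage partial correlation
(Schäfer–Strimmer). For HRR, each gene's correlations are ranked
decreasingly (self-rank 0, best partner rank 1) and

```
HRR(A, B) = max(rank_A(B), rank_B(A))
```

so a pair scores well (low) only when each gene is among the other's top
correlates. Score matrices are cut to the k best pairs (the implied
threshold is reported) and to nested 1/5/10/20/40/60/80% sub-networks.

**Guilt-by-association evaluation.** Against a size- and evidence-filtered
annotation reference (GAF or two-column; IEA removed; 5–100 genes per term):
edge confusion (TP/FP/FN/TN over gene pairs) with partial TPR-vs-FPR
curves, a pooled global AUROC, a 3-fold cross-validated neighbor-voting
(NV) AUROC, a node-degree AUROC (hubness control), and hypergeometric
enrichment of co-annotated pairs among edges. AUROC 0.5 = random label
attribution, > 0.6 = moderate predictivity.

**Pathway-Level Coexpression (PLC).** The subnetwork around a pathway's
guide genes (edges touching a guide, plus associate–associate edges present
at the threshold; non-guide degree-1 vertices pruned) is partitioned with
fast-greedy modularity maximization, and the guide distribution over
sub-pathway × community cells is scored with a Monte-Carlo Pearson Chi²
normalized by its ideal-partition maximum `N_g (n − 1)`:
1 = exact sub-pathway partitioning, 0 = random scattering (or Monte-Carlo
p > 0.05). Networks from different platforms are merged by edge
intersection after trimming both to a common vertex budget.

Five pathway definitions ship with the package (phenylpropanoids 43 genes /
4 sub-pathways, fatty acid 97/6, carbohydrate 202/8, terpenes 64/6,
cytokinin signaling 37); their gene identifiers are synthetic stand-ins but
the counts and sub-pathway structure match the published pathway
descriptions.

## Worked example

```python
import coexnet as cx

# 100 genes in five 20-gene modules with within-module correlation 0.7
mat, truth = cx.simulate_expression(
    n_genes=100, n_samples=200, module_sizes=[20]*5, rho=0.7, seed=1)

# PCC -> HRR -> 500 best pairs
scores = cx.hrr_matrix(cx.pearson_matrix(mat))
network = cx.build_graph(cx.top_pairs(scores, 500))

# function recovery: neighbor-voting AUROC against module-aligned terms
ann = cx.simulate_annotations(truth, terms_per_module=2, seed=1)
_, nv = cx.neighbor_voting_auroc(network, ann, folds=3, seed=1)
print(f"NV AUROC           {nv:.3f}")

# PLC: 30 guide genes, 5 sub-pathways (one per planted module)
pathway = cx.simulate_pathway(truth, [0, 1, 2, 3, 4],
                              guides_per_module=6, seed=1)
report = cx.plc_report(network, pathway, ann=ann, seed=1)
print(f"guides in network  {report.n_guides_in_network}/{report.n_guides_total}")
print(f"modularity Q       {report.modularity_q:.3f}")
print(f"normalized chi2    {report.normalized_chi2:.3f}  (p = {report.chi2_pvalue:.4f})")
```

prints

```
NV AUROC           0.960
guides in network  30/30
modularity Q       0.800
normalized chi2    1.000  (p = 0.0005)
```

The network predicts the hidden module-aligned annotations almost perfectly
(NV AUROC 0.96), all 30 guides survive extraction, and the fast-greedy
communities reproduce the planted sub-pathways exactly (normalized Chi² 1.0
at Monte-Carlo p ≈ 5e-4, modularity 0.80).

The same pipeline is available from the shell: `coexnet simulate`,
`coexnet normalize`, `coexnet qc`, `coexnet distance`, `coexnet network`,
`coexnet evaluate`, `coexnet plc`, `coexnet intersect` and `coexnet grid`
(the full dataset × distance × threshold sweep). See `coexnet --help`.

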