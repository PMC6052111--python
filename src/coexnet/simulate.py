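"""Synthetic expression data with planted modular co-expression structure.

The generator plants gene modules driven by shared latent factors:

    expr_g = sqrt(rho) * z_m + sqrt(1 - rho) * eps_g

with ``z_m`` a per-module standard-normal factor over samples and ``eps_g``
independent unit noise, so the expected within-module Pearson correlation is
``rho`` and the across-module correlation is 0. Background genes are pure
noise. The ``nb_counts`` mode pushes the latent values through an
exponential mean to negative-binomial counts, emulating the overdispersed
count scale of RNA-seq so the TPM / log2 normalization path can be
exercised. Matching annotation sets (terms aligned with modules, optionally
rewired) and pathway definitions (guides sampled from modules with the
module as sub-pathway label) provide ground truth for every evaluation
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from coexnet.annotation import AnnotationSet
from coexnet.errors import ParameterError
from coexnet.expression import ExpressionMatrix
from coexnet.pathway import PathwayDefinition


@dataclass
class SyntheticTruth:
    """Planted structure of a simulated expression matrix."""

    module_of_gene: dict[str, int]  # background genes map to -1
    module_sizes: list[int]
    rho: float
    noise_sd: float
    mode: str
    seed: int
    dispersion: float | None = None

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def module_genes(self, module: int) -> list[str]:
        return sorted(g for g, m in self.module_of_gene.items()
                      if m == module)


def simulate_expression(n_genes: int, n_samples: int,
                        module_sizes: list[int], rho: float,
                        noise_sd: float = 1.0, mode: str = "gaussian",
                        seed: int = 0, dispersion: float = 0.1,
                        ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a gene x sample matrix with planted correlation modules.

    Parameters
    ----------
    n_genes, n_samples : int
        Matrix dimensions; genes beyond ``sum(module_sizes)`` are
        uncorrelated background.
    module_sizes : list of int
        Number of genes in each planted module.
    rho : float in (0, 1)
        Target within-module Pearson correlation (exact in expectation).
    noise_sd : float
        Scale applied to the unit-variance gene signals (does not change
        correlations).
    mode : {"gaussian", "nb_counts"}
        ``gaussian`` returns the latent values; ``nb_counts`` maps them
        through ``exp`` to negative-binomial counts (variance
        mu + dispersion * mu^2) with library sizes around one million.
    """
    sizes = list(module_sizes)
    if any(s < 1 for s in sizes):
        raise ParameterError("module sizes must be positive")
    if sum(sizes) > n_genes:
        raise ParameterError(
            f"module sizes sum to {sum(sizes)} > n_genes={n_genes}"
        )
    if not 0.0 < rho < 1.0:
        raise ParameterError(f"rho={rho} outside (0, 1)")
    if mode not in {"gaussian", "nb_counts"}:
        raise ParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    module_of_gene: dict[str, int] = {}
    values = np.empty((n_genes, n_samples))
    row = 0
    for m, size in enumerate(sizes):
        z = rng.standard_normal(n_samples)
        eps = rng.standard_normal((size, n_samples))
        values[row:row + size] = (
            np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
        )
        for g in gene_ids[row:row + size]:
            module_of_gene[g] = m
        row += size
    n_bg = n_genes - row
    if n_bg:
        values[row:] = rng.standard_normal((n_bg, n_samples))
        for g in gene_ids[row:]:
            module_of_gene[g] = -1
    values *= noise_sd
    truth = SyntheticTruth(
        module_of_gene=module_of_gene, module_sizes=sizes, rho=rho,
        noise_sd=noise_sd, mode=mode, seed=seed,
        dispersion=dispersion if mode == "nb_counts" else None,
    )
    if mode == "nb_counts":
        # log-mean tracks the latent values one-to-one so the module
        # correlation survives the count layer; per-gene base expression
        # chosen so the median library lands near 1e6 counts.
        base = rng.lognormal(mean=np.log(1e6 / n_genes), sigma=1.0,
                             size=(n_genes, 1))
        mu = base * np.exp(values)
        r = 1.0 / dispersion
        p = r / (r + mu)
        values = rng.negative_binomial(r, p).astype(float)
    tag = "synthetic_counts" if mode == "nb_counts" else "synthetic"
    mat = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                           values=values, stage_tag=tag)
    return mat, truth


def simulate_annotations(truth: SyntheticTruth, terms_per_module: int = 2,
                         noise_frac: float = 0.0, seed: int = 0,
                         min_term_size: int = 5, max_term_size: int = 100,
                         ) -> AnnotationSet:
    """Annotation terms aligned with the planted modules.

    Each module yields ``terms_per_module`` terms annotating a random
    subset of its genes with sizes inside ``[min_term_size,
    max_term_size]`` (mirroring the 5-100-gene reference filter); a
    fraction ``noise_frac`` of the gene-term assignments is then rewired to
    uniformly random genes, degrading the module-term alignment.
    """
    if not 0.0 <= noise_frac < 1.0:
        raise ParameterError(f"noise_frac={noise_frac} outside [0, 1)")
    rng = np.random.default_rng(seed)
    all_genes = sorted(truth.module_of_gene)
    pairs: list[tuple[str, str]] = []
    for m in range(truth.n_modules):
        genes = truth.module_genes(m)
        if len(genes) < min_term_size:
            warnings.warn(
                f"module {m} has {len(genes)} genes < min term size "
                f"{min_term_size}; skipped", stacklevel=2,
            )
            continue
        for t in range(terms_per_module):
            hi = min(len(genes), max_term_size)
            size = int(rng.integers(min_term_size, hi + 1))
            members = rng.choice(genes, size=size, replace=False)
            pairs.extend((g, f"TERM:M{m:02d}T{t:02d}") for g in members)
    if not pairs:
        raise ParameterError("no module large enough to carry a term")
    if noise_frac > 0:
        n_rewire = int(round(noise_frac * len(pairs)))
        idx = rng.choice(len(pairs), size=n_rewire, replace=False)
        for i in idx:
            _, term = pairs[i]
            pairs[i] = (all_genes[rng.integers(len(all_genes))], term)
    # deduplicate (rewiring can collide), keep deterministic order
    pairs = sorted(set(pairs))
    return AnnotationSet.from_pairs(
        pairs, min_genes=2, max_genes=max_term_size,
        filter_record={"synthetic": True, "noise_frac": noise_frac,
                       "seed": seed},
    )


def permute_annotations(ann: AnnotationSet, genes: list[str],
                        seed: int = 0) -> AnnotationSet:
    """Rewire every gene-term assignment to a uniformly random gene.

    The per-term annotation counts are preserved while any alignment
    between terms and network structure is destroyed: the null model under
    which every guilt-by-association AUROC should average 0.5.
    """
    rng = np.random.default_rng(seed)
    pool = list(genes)
    pairs: list[tuple[str, str]] = []
    for term, members in sorted(ann.term_to_genes.items()):
        chosen = rng.choice(pool, size=min(len(members), len(pool)),
                            replace=False)
        pairs.extend((g, term) for g in chosen)
    return AnnotationSet.from_pairs(
        pairs, min_genes=1, max_genes=10**9,
        filter_record={"permuted": True, "seed": seed},
    )


def simulate_pathway(truth: SyntheticTruth,
                     modules_as_subpathways: list[int],
                     guides_per_module: int, seed: int = 0,
                     name: str = "synthetic_pathway") -> PathwayDefinition:
    """Sample guide genes from planted modules, one sub-pathway per module.

    The sub-pathway label of each guide is its planted module, so the ideal
    contingency table of a perfect community recovery is block-diagonal and
    the normalized Chi² ground truth is 1.
    """
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    for m in modules_as_subpathways:
        genes = truth.module_genes(m)
        if guides_per_module > len(genes):
            raise ParameterError(
                f"module {m} has {len(genes)} genes < "
                f"guides_per_module={guides_per_module}"
            )
        chosen = rng.choice(genes, size=guides_per_module, replace=False)
        for g in chosen:
            mapping[str(g)] = f"subpathway_{m:02d}"
    return PathwayDefinition(name=name, gene_to_subpathway=mapping)
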