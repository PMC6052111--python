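"""Pathway-Level Coexpression (PLC): guide-gene subnetworks and their scoring.

A global network is queried with a pathway's guide genes: edges touching at
least one guide are kept, edges between two associated (non-guide) genes are
retained when present in the thresholded network, and non-guide vertices of
degree 1 (connected to a single guide) are pruned. Communities are detected
with the fast-greedy modularity-maximizing algorithm and the distribution of
guide genes over (sub-pathway x community) cells is compared to the ideal
one-sub-pathway-per-community partition via a Monte-Carlo Pearson Chi²
normalized to [0, 1]:

    normalized Chi² = Chi²_obs / (N_g * (n_present - 1))

where N_g is the number of guide genes in the subnetwork and n_present the
number of sub-pathways represented. The denominator is the exact Pearson
Chi² of any table in which each present sub-pathway occupies its own
distinct community, so the statistic reaches 1 exactly at the ideal
partition; a statistic whose Monte-Carlo p exceeds 0.05 is reported as 0
(indistinguishable from a random scattering of guides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from coexnet.annotation import AnnotationSet
from coexnet.errors import (
    DegenerateTableError,
    EmptyPlcError,
    LabelError,
    ParameterError,
)
from coexnet.network import Network, topology_stats
from coexnet.pathway import PathwayDefinition


@dataclass
class Partition:
    """A community labelling of a graph together with its modularity Q."""

    labels: dict[str, int]
    modularity_q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, c in self.labels.items():
            out.setdefault(c, set()).add(g)
        return out


@dataclass
class ContingencyTable:
    """Guide-gene counts over sub-pathways (rows) x communities (columns)."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[int]

    @property
    def n_guides(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class PlcReport:
    """Metrics of one PLC subnetwork (one pathway x one global network)."""

    pathway: str
    n_guides_total: int
    n_guides_in_network: int
    guide_fraction: float
    n_vertices: int
    n_edges: int
    mean_degree: float
    modularity_q: float
    chi2: float
    chi2_pvalue: float
    normalized_chi2: float
    nv_auroc: float | None = None
    missing_guides: list[str] = field(default_factory=list)
    notes: str = ""

    def to_row(self) -> dict:
        return {
            "pathway": self.pathway,
            "guides_total": self.n_guides_total,
            "guides_in_network": self.n_guides_in_network,
            "guide_fraction": self.guide_fraction,
            "vertices": self.n_vertices,
            "edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "modularity": self.modularity_q,
            "chi2": self.chi2,
            "chi2_pvalue": self.chi2_pvalue,
            "normalized_chi2": self.normalized_chi2,
            "nv_auroc": self.nv_auroc,
            "notes": self.notes,
        }


def extract_plc(net: Network, pathway: PathwayDefinition,
                iterative_prune: bool = False) -> Network:
    """Extract the guide-gene subnetwork of a global network.

    Candidate vertices are the guides plus their direct neighbors
    (associated genes); all network edges with both endpoints in the
    candidate set are kept, including associate-associate edges present at
    the threshold. Non-guide vertices of degree 1 — connected to only one
    guide gene — are then removed in a single pass (``iterative_prune``
    repeats the pass until stable), and isolated vertices are dropped.
    """
    guides = set(pathway.guide_genes)
    present = guides & set(net.graph.nodes)
    if not present:
        raise EmptyPlcError(
            f"no guide gene of pathway {pathway.name!r} in the network"
        )
    candidates = set(present)
    for g in present:
        candidates.update(net.graph.neighbors(g))
    sub = nx.Graph(net.graph.subgraph(candidates))
    while True:
        drop = [v for v in sub.nodes
                if v not in guides and sub.degree(v) <= 1]
        sub.remove_nodes_from(drop)
        if not iterative_prune or not drop:
            break
    sub.remove_nodes_from([v for v in sub.nodes if sub.degree(v) == 0])
    prov = dict(net.provenance)
    prov.update({
        "plc_pathway": pathway.name,
        "guides_missing": sorted(guides - present),
    })
    return Network(graph=sub, provenance=prov)


def modularity(net: Network, partition: Partition) -> float:
    """Newman modularity Q of a partition:

        Q = sum_c [ e_c / m - (d_c / 2m)^2 ]

    with m total edges, e_c intra-community edges and d_c the summed degree
    of community c. Q is 0 for the all-in-one partition and approaches 1
    for strong, well-separated communities.
    """
    missing = set(net.graph.nodes) - set(partition.labels)
    if missing:
        raise LabelError(f"partition misses vertices: {sorted(missing)[:5]}")
    m = net.n_edges
    if m == 0:
        return 0.0
    e_c: dict[int, int] = {}
    d_c: dict[int, int] = {}
    for u, v in net.graph.edges:
        cu, cv = partition.labels[u], partition.labels[v]
        if cu == cv:
            e_c[cu] = e_c.get(cu, 0) + 1
    for v, d in net.graph.degree:
        c = partition.labels[v]
        d_c[c] = d_c.get(c, 0) + d
    q = 0.0
    for c in set(partition.labels.values()):
        q += e_c.get(c, 0) / m - (d_c.get(c, 0) / (2.0 * m)) ** 2
    return q


def detect_communities(net: Network, seed: int = 0) -> Partition:
    """Fast-greedy (Clauset-Newman-Moore) modularity maximization.

    Agglomerative greedy merging of communities by best modularity gain;
    deterministic for a fixed vertex order (the ``seed`` argument is part
    of the stable API but the algorithm itself is deterministic).
    Communities are numbered 0.. in decreasing size order.
    """
    if net.n_vertices == 0:
        raise EmptyPlcError("cannot partition an empty network")
    if net.n_edges == 0:
        comms = [{v} for v in sorted(net.graph.nodes)]
    else:
        comms = list(nx.community.greedy_modularity_communities(net.graph))
    comms = sorted(comms, key=lambda c: (-len(c), sorted(c)[0]))
    labels = {g: i for i, comm in enumerate(comms) for g in sorted(comm)}
    part = Partition(labels=labels, modularity_q=0.0)
    part.modularity_q = modularity(net, part)
    return part


def guide_contingency(partition: Partition,
                      pathway: PathwayDefinition) -> ContingencyTable:
    """Cross-tabulate guide genes: sub-pathways (rows) x communities (cols).

    Rows are the sub-pathways with at least one guide in the partitioned
    graph; columns are the communities containing at least one guide
    (guide-free communities carry no information about guide partitioning).
    Entries count guide genes only.
    """
    rows: dict[str, dict[int, int]] = {}
    for gene, sub in pathway.gene_to_subpathway.items():
        if gene in partition.labels:
            c = partition.labels[gene]
            rows.setdefault(sub, {}).setdefault(c, 0)
            rows[sub][c] += 1
    if not rows:
        raise EmptyPlcError(
            f"no guide gene of pathway {pathway.name!r} in the partition"
        )
    row_labels = sorted(rows)
    col_labels = sorted({c for r in rows.values() for c in r})
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for i, r in enumerate(row_labels):
        for j, c in enumerate(col_labels):
            counts[i, j] = rows[r].get(c, 0)
    return ContingencyTable(counts=counts, row_labels=row_labels,
                            col_labels=col_labels)


def normalized_chi2(table: ContingencyTable, replicates: int = 2000,
                    seed: int = 0, alpha: float = 0.05
                    ) -> tuple[float, float, float]:
    """Monte-Carlo Pearson Chi² of a guide contingency table, normalized.

    Returns ``(chi2, p, normalized)``. The p-value is estimated from
    ``replicates`` random tables with the observed margins fixed
    (Patefield sampling):  ``p = (1 + #{chi2_sim >= chi2_obs}) /
    (replicates + 1)``.  The normalization divides by
    ``N_g * (n_present - 1)``, the exact Chi² of the ideal partition in
    which each present sub-pathway occupies its own community, so the
    normalized value lies in [0, 1] and equals 1 only at the ideal
    partition. Whenever p > ``alpha`` the normalized statistic is reported
    as 0; degenerate tables (a single row or column) are reported as
    (0, 1, 0).
    """
    counts = np.asarray(table.counts, dtype=float)
    n_g = counts.sum()
    if n_g < 2:
        raise DegenerateTableError(
            f"need >= 2 guide genes in the table, got {int(n_g)}"
        )
    if replicates < 100:
        import warnings

        warnings.warn(
            f"replicates={replicates} gives a coarse Monte-Carlo p",
            stacklevel=2,
        )
    n_rows, n_cols = counts.shape
    if n_rows < 2 or n_cols < 2:
        return 0.0, 1.0, 0.0
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected = np.outer(row, col) / n_g
    chi2_obs = float(((counts - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(row.astype(int), col.astype(int))
    sims = sampler.rvs(replicates, random_state=rng)
    chi2_sim = ((sims - expected) ** 2 / expected).sum(axis=(-2, -1))
    p = float((1 + np.count_nonzero(chi2_sim >= chi2_obs - 1e-12))
              / (replicates + 1))
    chi2_max = n_g * (n_rows - 1)
    norm = min(chi2_obs / chi2_max, 1.0) if chi2_max > 0 else 0.0
    if p > alpha:
        norm = 0.0
    return chi2_obs, p, norm


def plc_report(net: Network, pathway: PathwayDefinition,
               ann: AnnotationSet | None = None, seed: int = 0,
               replicates: int = 2000, folds: int = 3) -> PlcReport:
    """Extract, partition and score one PLC subnetwork end to end.

    Runs ``extract_plc -> detect_communities -> guide_contingency ->
    normalized_chi2`` and, when an annotation set is supplied, the
    neighbor-voting AUROC of the subgraph; assembles everything with the
    subgraph topology into a :class:`PlcReport`.
    """
    sub = extract_plc(net, pathway)
    ts = topology_stats(sub)
    present = [g for g in pathway.guide_genes if g in sub.graph]
    notes = []
    if ts.n_edges == 0:
        chi2 = p = 0.0
        norm = 0.0
        q = 0.0
        notes.append("empty subgraph after pruning")
        p = 1.0
    else:
        part = detect_communities(sub, seed=seed)
        q = part.modularity_q
        table = guide_contingency(part, pathway)
        if min(table.counts.shape) < 2:
            chi2, p, norm = 0.0, 1.0, 0.0
            notes.append("degenerate contingency (single row or column)")
        else:
            chi2, p, norm = normalized_chi2(table, replicates=replicates,
                                            seed=seed)
    nv = None
    if ann is not None and ts.n_edges > 0:
        try:
            from coexnet.evaluate import neighbor_voting_auroc

            _, nv = neighbor_voting_auroc(sub, ann, folds=folds, seed=seed)
        except Exception as exc:  # undefined on tiny subgraphs
            notes.append(f"NV AUROC unavailable: {exc}")
    n_total = pathway.n_genes
    return PlcReport(
        pathway=pathway.name,
        n_guides_total=n_total,
        n_guides_in_network=len(present),
        guide_fraction=len(present) / n_total if n_total else 0.0,
        n_vertices=ts.n_vertices,
        n_edges=ts.n_edges,
        mean_degree=ts.mean_degree,
        modularity_q=q,
        chi2=chi2,
        chi2_pvalue=p,
        normalized_chi2=norm,
        nv_auroc=nv,
        missing_guides=sub.provenance.get("guides_missing", []),
        notes="; ".join(notes),
    )
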