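"""Thresholding score matrices into networks and network set operations.

A score matrix is first cut to an :class:`EdgeList` of the k best pairs
(correlation above, or HRR rank below, the implied dynamic threshold), then
optionally subset to the best 1/5/10/20/40/60/80% of that list, and finally
materialized as an undirected :class:`Network`. Networks from different
platforms (e.g. microarray vs RNA-seq) are merged by edge intersection after
trimming both to a common vertex budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from coexnet.distance import ScoreMatrix
from coexnet.errors import ParameterError


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


@dataclass
class EdgeList:
    """Deduplicated, best-first sorted (gene_a, gene_b, score) records.

    ``gene_a < gene_b`` lexicographically in every record; the sort is
    descending for higher-better scores and ascending for lower-better
    (HRR) scores, with lexicographic pair-id tiebreak so any head of the
    list is reproducible.
    """

    records: list[tuple[str, str, float]]
    orientation: str = "higher_better"
    threshold: float | None = None  # score of the worst retained pair

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["gene_a", "gene_b", "score"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.10g")

    @classmethod
    def read(cls, path, orientation: str = "higher_better") -> "EdgeList":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_a": str,
                                                   "gene_b": str})
        records = [
            (*_canonical(str(a), str(b)), float(s))
            for a, b, s in frame.itertuples(index=False)
        ]
        return cls(records=records, orientation=orientation)


@dataclass
class Network:
    """Undirected co-expression network with per-edge scores."""

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {_canonical(u, v) for u, v in self.graph.edges}

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edges(self, path) -> None:
        rows = sorted(
            (*_canonical(u, v), d.get("score", float("nan")))
            for u, v, d in self.graph.edges(data=True)
        )
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


@dataclass
class TopologyStats:
    """Vertex/edge counts and the degree distribution of a network."""

    n_vertices: int
    n_edges: int
    mean_degree: float
    degree_sequence: list[int]


def top_pairs(scores: ScoreMatrix, k: int) -> EdgeList:
    """The k best gene pairs of a score matrix (dynamic thresholding).

    Best means highest score for correlations/MI and lowest rank for HRR.
    Ties at the cut are broken by lexicographic pair id so exactly k pairs
    are always returned. The score of the k-th pair is recorded as the
    implied threshold.
    """
    n = scores.n_genes
    total = n * (n - 1) // 2
    if not 1 <= k <= total:
        raise ParameterError(f"k={k} outside [1, {total}]")
    iu, ju = np.triu_indices(n, k=1)
    vals = scores.values[iu, ju]
    finite = np.isfinite(vals)
    iu, ju, vals = iu[finite], ju[finite], vals[finite]
    if k > len(vals):
        raise ParameterError(
            f"k={k} exceeds the {len(vals)} finite-scored pairs")
    lower = scores.orientation == "lower_better"
    key = vals if lower else -vals
    # partial selection then a full sort of the head keeps this O(P + k log k)
    if k < len(vals):
        part = np.argpartition(key, k - 1)[:k]
    else:
        part = np.arange(len(vals))
    ids = np.array(scores.gene_ids, dtype=object)
    pairs = [
        (*_canonical(ids[iu[t]], ids[ju[t]]), float(vals[t])) for t in part
    ]
    pairs.sort(key=lambda r: ((r[2] if lower else -r[2]), r[0], r[1]))
    # ties straddling the cut: re-rank all pairs tied with the k-th score
    kth = pairs[-1][2]
    tied = np.flatnonzero(vals == kth)
    if len(tied) > sum(1 for r in pairs if r[2] == kth):
        head = [r for r in pairs if r[2] != kth]
        tied_pairs = sorted(
            (*_canonical(ids[iu[t]], ids[ju[t]]), float(vals[t]))
            for t in tied
        )
        pairs = head + tied_pairs[: k - len(head)]
    return EdgeList(records=pairs, orientation=scores.orientation,
                    threshold=kth)


def subset_fraction(edges: EdgeList, fraction: float) -> EdgeList:
    """The best ``floor(fraction * len)`` records (at least one)."""
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"fraction={fraction} outside (0, 1]")
    m = max(1, math.floor(fraction * len(edges)))
    head = edges.records[:m]
    return EdgeList(records=list(head), orientation=edges.orientation,
                    threshold=head[-1][2] if head else None)


def build_graph(edges: EdgeList, provenance: dict | None = None) -> Network:
    """Materialize an edge list as an undirected scored graph."""
    g = nx.Graph()
    for a, b, s in edges.records:
        g.add_edge(a, b, score=s)
    return Network(graph=g, provenance=dict(provenance or {}))


def topology_stats(net: Network) -> TopologyStats:
    """Vertex count, edge count, mean degree (2E/V) and degree sequence."""
    v = net.n_vertices
    e = net.n_edges
    degs = sorted((d for _, d in net.graph.degree), reverse=True)
    return TopologyStats(
        n_vertices=v,
        n_edges=e,
        mean_degree=(2.0 * e / v) if v else 0.0,
        degree_sequence=degs,
    )


def trim_to_vertex_count(edges: EdgeList, target_vertices: int,
                         allow_overshoot: bool = False) -> Network:
    """Build a network best-edge-first until the vertex budget is reached.

    Edges are added in list order; construction stops at the first edge
    that would push the vertex count above ``target_vertices`` (that edge is
    not added), so the result never exceeds the budget. With
    ``allow_overshoot`` the stopping edge is admitted, allowing at most
    ``target_vertices + 1`` vertices.
    """
    if target_vertices < 1:
        raise ParameterError("target_vertices must be >= 1")
    g = nx.Graph()
    seen: set[str] = set()
    for a, b, s in edges.records:
        new = (a not in seen) + (b not in seen)
        if len(seen) + new > target_vertices:
            if allow_overshoot:
                g.add_edge(a, b, score=s)
                seen.update((a, b))
            break
        g.add_edge(a, b, score=s)
        seen.update((a, b))
    return Network(graph=g, provenance={"trimmed_to": target_vertices})


def intersect_networks(a: Network, b: Network) -> tuple[Network, dict]:
    """Edge-wise intersection of two networks sharing a gene namespace.

    The intersection keeps the unordered pairs present in both edge sets
    (scores from ``a``); its vertex set is the union of surviving edge
    endpoints. The report counts both common-edge endpoints and the plain
    vertex-set overlap ``|V(a) ∩ V(b)|``, which differ whenever shared
    vertices have no shared edge.
    """
    common = a.edge_pairs() & b.edge_pairs()
    g = nx.Graph()
    for u, v in sorted(common):
        g.add_edge(u, v, score=a.graph[u][v].get("score", float("nan")))
    report = {
        "edges_common": len(common),
        "vertices_common": len(set(a.graph.nodes) & set(b.graph.nodes)),
        "vertices_in_common_edges": g.number_of_nodes(),
    }
    return Network(graph=g, provenance={"intersection": True}), report
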