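"""Network evaluation against a functional-annotation reference.

Four complementary guilt-by-association evaluations are provided:

* **edge confusion / ROC over thresholds** — each network edge is a
  positive prediction; it is true when both genes share an annotation term.
  Confusions at increasing network sizes trace a (partial) TPR-vs-FPR curve.
* **global AUROC** — every (gene, term) instance is scored by the fraction
  of the gene's neighbors carrying the term; one pooled ROC over all
  instances summarizes whether neighborhoods predict annotations.
* **neighbor-voting (NV) AUROC** — per term, annotated genes are hidden in
  a seeded k-fold cross-validation and re-predicted from the visible labels
  of their direct neighbors; the per-term AUROCs (hidden positives vs
  never-annotated genes) are averaged into one network score.
* **node-degree AUROC** — per term, genes are ranked by degree alone; a
  high value flags networks whose apparent predictivity is a hub artifact
  rather than function-specific wiring.

All AUROCs use the midrank (Mann-Whitney) convention, which handles the
heavy score ties of sparse graphs; 0.5 means random label attribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from coexnet.annotation import AnnotationSet
from coexnet.errors import ParameterError, UndefinedStatisticError
from coexnet.network import Network

_canonical = lambda a, b: (a, b) if a < b else (b, a)  # noqa: E731


@dataclass
class ConfusionCounts:
    """Edge-level confusion over all unordered pairs of the universe."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def tpr(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def fpr(self) -> float:
        neg = self.fp + self.tn
        return self.fp / neg if neg else float("nan")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class RocCurve:
    """Ordered (FPR, TPR) points anchored at the origin, trapezoid AUROC.

    ``partial`` marks curves whose largest FPR < 1 (e.g. built from the
    10-million-best-pairs lists only); ``auroc`` then covers only the
    observed FPR range.
    """

    points: list[tuple[float, float]]
    auroc: float
    partial: bool


def _co_annotated_pairs(ann: AnnotationSet,
                        universe: set[str]) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    for genes in ann.term_to_genes.values():
        members = sorted(g for g in genes if g in universe)
        pairs.update(combinations(members, 2))
    return pairs


def edge_confusion(net: Network, ann: AnnotationSet,
                   universe: set[str] | None = None) -> ConfusionCounts:
    """Classify every unordered gene pair as TP/FP/FN/TN.

    ``universe`` is the gene set the classification ranges over — normally
    all genes of the expression dataset the network was built from; when
    omitted it defaults to the union of the network's vertices and the
    annotated genes. Positives are pairs sharing at least one term and
    predictions are the network's edges restricted to the universe, so
    TP + FP + FN + TN = C(U, 2).
    """
    net_genes = set(net.graph.nodes)
    ann_genes = set(ann.gene_to_terms)
    if not net_genes & ann_genes:
        raise UndefinedStatisticError("no annotated gene in the network")
    universe = set(universe) if universe is not None \
        else net_genes | ann_genes
    u = len(universe)
    positives = _co_annotated_pairs(ann, universe)
    edges = {p for p in net.edge_pairs()
             if p[0] in universe and p[1] in universe}
    tp = len(edges & positives)
    fp = len(edges) - tp
    fn = len(positives) - tp
    tn = u * (u - 1) // 2 - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def roc_from_thresholds(confusions: list[ConfusionCounts]) -> RocCurve:
    """Partial ROC curve from confusions at increasing network sizes."""
    pts = [(0.0, 0.0)]
    last_fpr = 0.0
    for c in confusions:
        if c.fpr < last_fpr - 1e-12:
            raise ParameterError(
                "confusions must be ordered by increasing FPR "
                "(increasing network size)"
            )
        pts.append((c.fpr, c.tpr))
        last_fpr = c.fpr
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=pts, auroc=auc, partial=bool(xs[-1] < 1.0))


def _auroc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Midrank Mann-Whitney AUROC of positives over negatives."""
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUROC needs positives and negatives")
    ranks = stats.rankdata(np.concatenate([pos_scores, neg_scores]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _network_arrays(net: Network, ann: AnnotationSet):
    nodes = sorted(net.graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v in net.graph.edges:
        adj[index[u], index[v]] = adj[index[v], index[u]] = 1.0
    deg = adj.sum(axis=1)
    terms = ann.terms
    labels = np.zeros((n, len(terms)))
    for j, t in enumerate(terms):
        for g in ann.term_to_genes[t]:
            if g in index:
                labels[index[g], j] = 1.0
    return nodes, adj, deg, terms, labels


def global_auroc(net: Network, ann: AnnotationSet) -> float:
    """Pooled AUROC over all (gene, term) instances.

    Each instance is scored by the gene's neighbor vote for the term — the
    count of neighbors annotated with the term over the gene's degree —
    and instances where the gene itself carries the term are the
    positives. Two calibration steps keep the pooled statistic honest at
    0.5 under random label attribution: the vote is divided by the
    leave-one-out pool size (an annotated gene's own label is never
    available to its neighborhood, leaving m-1 rather than m annotated
    genes among the others), and scores are standardized to midranks
    within each term before pooling (terms of different sizes otherwise
    put all their instances on different score scales, which biases the
    pooled ROC). One ROC over the pooled instances yields a single
    network-level number.
    """
    if net.n_edges == 0:
        raise UndefinedStatisticError("empty network")
    _, adj, deg, _, labels = _network_arrays(net, ann)
    if labels.sum() == 0:
        raise UndefinedStatisticError("no annotated (gene, term) instance")
    n = adj.shape[0]
    safe_deg = np.where(deg > 0, deg, 1.0)
    pool = np.maximum(labels.sum(axis=0)[None, :] - labels, 1.0)
    scores = (adj @ labels) / safe_deg[:, None] / pool
    scores = stats.rankdata(scores, axis=0) / n
    pos = labels > 0
    return _auroc(scores[pos], scores[~pos])


def neighbor_voting_auroc(net: Network, ann: AnnotationSet,
                          folds: int = 3, seed: int = 0
                          ) -> tuple[pd.DataFrame, float]:
    """Cross-validated neighbor-voting AUROC per term and its network mean.

    Per term, the annotated network genes are split into ``folds`` seeded
    groups; in each fold the group's labels are hidden and every gene is
    scored by the fraction of its neighbors among the still-visible
    annotated genes. The fold AUROC separates hidden positives from genes
    never annotated with the term; the term AUROC averages folds and the
    NV AUROC averages terms. Terms with fewer than ``folds`` annotated
    network genes are skipped (listed with NaN in the table).
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if net.n_edges == 0:
        raise UndefinedStatisticError("empty network")
    nodes, adj, deg, terms, labels = _network_arrays(net, ann)
    safe_deg = np.where(deg > 0, deg, 1.0)
    rng = np.random.default_rng(seed)
    rows = []
    for j, term in enumerate(terms):
        members = np.flatnonzero(labels[:, j] > 0)
        never = np.flatnonzero(labels[:, j] == 0)
        if len(members) < folds or len(never) == 0:
            rows.append((term, len(members), float("nan")))
            continue
        perm = rng.permutation(members)
        fold_aucs = []
        for f in range(folds):
            hidden = perm[f::folds]
            visible = np.setdiff1d(members, hidden)
            vis_vec = np.zeros(len(nodes))
            vis_vec[visible] = 1.0
            score = (adj @ vis_vec) / safe_deg
            fold_aucs.append(_auroc(score[hidden], score[never]))
        rows.append((term, len(members), float(np.mean(fold_aucs))))
    table = pd.DataFrame(rows, columns=["term_id", "n_genes_in_network",
                                        "auroc_fold_mean"])
    evaluated = table["auroc_fold_mean"].dropna()
    if evaluated.empty:
        raise UndefinedStatisticError(
            f"no term with >= {folds} annotated genes in the network"
        )
    return table, float(evaluated.mean())


def degree_auroc(net: Network, ann: AnnotationSet) -> float:
    """Mean per-term AUROC of a degree-only ranking of network genes.

    Every term uses the identical node-degree score, so this measures how
    much annotation recovery is available from hubness alone; on a
    degree-regular graph all scores tie and the midrank AUROC is exactly
    0.5.
    """
    if net.n_edges == 0:
        raise UndefinedStatisticError("empty network")
    _, _, deg, terms, labels = _network_arrays(net, ann)
    aucs = []
    for j in range(len(terms)):
        pos = labels[:, j] > 0
        if pos.sum() == 0 or (~pos).sum() == 0:
            continue
        aucs.append(_auroc(deg[pos], deg[~pos]))
    if not aucs:
        raise UndefinedStatisticError("no evaluable term")
    return float(np.mean(aucs))


def pair_enrichment(net: Network, ann: AnnotationSet, alpha: float = 0.05,
                    correction: str = "bh"
                    ) -> tuple[pd.DataFrame, int]:
    """Hypergeometric enrichment of co-annotated gene pairs among edges.

    The population is all C(U, 2) unordered pairs over the annotated
    universe U; for each term, K co-annotated pairs are the successes,
    the n network edges within the universe are the draws, and k of them
    co-annotated with the term are observed:
    ``p = P(X >= k) = hypergeom.sf(k-1, M, K, n)``. Benjamini-Hochberg
    adjustment by default; ``correction="none"`` counts raw p-values.
    Returns the per-term table and the significant-term count at ``alpha``.
    """
    if correction not in {"bh", "none"}:
        raise ParameterError(f"unknown correction {correction!r}")
    universe = sorted(ann.gene_to_terms)
    uset = set(universe)
    m_pop = len(universe) * (len(universe) - 1) // 2
    net_edges = {p for p in net.edge_pairs()
                 if p[0] in uset and p[1] in uset}
    n_draws = len(net_edges)
    rows = []
    for term in ann.terms:
        genes = ann.term_to_genes[term]
        gsize = len(genes)
        big_k = gsize * (gsize - 1) // 2
        if big_k == 0:
            continue
        k_obs = sum(1 for a, b in net_edges if a in genes and b in genes)
        p = float(stats.hypergeom.sf(k_obs - 1, m_pop, big_k, n_draws))
        rows.append((term, k_obs, n_draws, big_k, m_pop, p))
    table = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "M",
                                        "p_value"])
    if table.empty:
        return table.assign(p_adjusted=[]), 0
    if correction == "bh":
        table["p_adjusted"] = _benjamini_hochberg(
            table["p_value"].to_numpy())
        n_sig = int((table["p_adjusted"] <= alpha).sum())
    else:
        table["p_adjusted"] = table["p_value"]
        n_sig = int((table["p_value"] <= alpha).sum())
    return table, n_sig


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return np.minimum(adj, 1.0)
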