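"""Guilt-by-association evaluation against brute-force oracles."""

import itertools
from math import comb

import numpy as np
import pytest

from conftest import pair_network
from coexnet import (
    degree_auroc,
    edge_confusion,
    global_auroc,
    neighbor_voting_auroc,
    pair_enrichment,
    roc_from_thresholds,
)
from coexnet.annotation import AnnotationSet
from coexnet.errors import ParameterError, UndefinedStatisticError
from coexnet.evaluate import ConfusionCounts, _auroc, _benjamini_hochberg


def _ann(pairs):
    return AnnotationSet.from_pairs(pairs)


class TestEdgeConfusion:
    def test_worked_example(self):
        net = pair_network([("A", "B"), ("A", "C")])
        ann = _ann([("A", "t1"), ("B", "t1"), ("C", "t2"), ("D", "t2")])
        # universe {A,B,C,D}: positives {AB, CD}; edges AB (TP), AC (FP)
        c = edge_confusion(net, ann)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 3)
        assert c.tpr == pytest.approx(0.5)
        assert c.fpr == pytest.approx(0.25)

    def test_explicit_dataset_universe(self):
        # four dataset genes, one 2-gene term, two network edges
        net = pair_network([("A", "B"), ("A", "C")])
        ann = _ann([("A", "t1"), ("B", "t1")])
        c = edge_confusion(net, ann, universe={"A", "B", "C", "D"})
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 4)
        assert c.tpr == 1.0
        assert c.fpr == pytest.approx(0.2)

    def test_perfect_network(self):
        ann = _ann([("A", "t"), ("B", "t"), ("C", "t"), ("D", "u")])
        net = pair_network([("A", "B"), ("A", "C"), ("B", "C")])
        c = edge_confusion(net, ann)
        assert c.tpr == 1.0
        assert c.fpr == 0.0

    def test_partition_invariant_random_instances(self, rng):
        genes = [f"g{i}" for i in range(12)]
        for trial in range(5):
            r = np.random.default_rng(trial)
            edges = {tuple(sorted(r.choice(genes, 2, replace=False)))
                     for _ in range(15)}
            ann_pairs = [(g, f"t{r.integers(3)}")
                         for g in r.choice(genes, 9, replace=False)]
            net = pair_network(sorted(edges))
            ann = _ann(ann_pairs)
            c = edge_confusion(net, ann)
            universe = set(net.graph.nodes) | set(ann.gene_to_terms)
            assert c.total == comb(len(universe), 2)
            # oracle: exhaustive pair enumeration
            tp = fp = fn = tn = 0
            for a, b in itertools.combinations(sorted(universe), 2):
                in_net = (a, b) in net.edge_pairs()
                co = ann.share_term(a, b)
                tp += in_net and co
                fp += in_net and not co
                fn += co and not in_net
                tn += not in_net and not co
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_no_annotated_gene_in_network(self):
        with pytest.raises(UndefinedStatisticError):
            edge_confusion(pair_network([("X", "Y")]),
                           _ann([("A", "t"), ("B", "t")]))


class TestRocFromThresholds:
    def test_single_point_partial_area(self):
        c = ConfusionCounts(tp=9, fp=2, fn=1, tn=8)  # tpr .9, fpr .2
        curve = roc_from_thresholds([c])
        assert curve.auroc == pytest.approx(0.09)
        assert curve.partial

    def test_non_monotone_fpr_rejected(self):
        a = ConfusionCounts(tp=1, fp=5, fn=1, tn=5)
        b = ConfusionCounts(tp=1, fp=1, fn=1, tn=9)
        with pytest.raises(ParameterError):
            roc_from_thresholds([a, b])

    def test_nested_networks_monotone_curve(self):
        confs = [ConfusionCounts(tp=k, fp=k * 2, fn=10 - k, tn=80 - 2 * k)
                 for k in (1, 3, 5)]
        curve = roc_from_thresholds(confs)
        xs = [p[0] for p in curve.points]
        ys = [p[1] for p in curve.points]
        assert xs == sorted(xs) and ys == sorted(ys)


def _brute_auroc(pos, neg):
    """Pair-counting Mann-Whitney oracle with half credit for ties."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAurocKernel:
    def test_matches_pair_counting_with_ties(self, rng):
        for trial in range(10):
            r = np.random.default_rng(trial)
            pos = r.integers(0, 5, size=8).astype(float)
            neg = r.integers(0, 5, size=13).astype(float)
            assert _auroc(pos, neg) == pytest.approx(
                _brute_auroc(pos, neg), abs=1e-12)


class TestGlobalAuroc:
    def test_disjoint_annotated_cliques_separate_perfectly(self):
        pairs = []
        for base in ("A", "B"):
            pairs += [(f"{base}{i}", f"{base}{j}")
                      for i in range(5) for j in range(i + 1, 5)]
        net = pair_network(pairs)
        ann = _ann([(f"A{i}", "tA") for i in range(5)]
                   + [(f"B{i}", "tB") for i in range(5)])
        assert global_auroc(net, ann) == pytest.approx(1.0)

    def test_permuted_labels_average_half(self, rng):
        net = pair_network(
            {(f"g{min(a, b):02d}", f"g{max(a, b):02d}")
             for a, b in rng.integers(0, 40, size=(120, 2)) if a != b})
        genes = sorted(net.graph.nodes)
        vals = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            ann = AnnotationSet.from_pairs(
                [(g, "t1") for g in r.choice(genes, 12, replace=False)]
                + [(g, "t2") for g in r.choice(genes, 18, replace=False)])
            vals.append(global_auroc(net, ann))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_empty_network_undefined(self):
        import networkx as nx

        from coexnet.network import Network
        with pytest.raises(UndefinedStatisticError):
            global_auroc(Network(graph=nx.Graph()), _ann([("a", "t")]))


class TestNeighborVoting:
    def test_annotated_clique_scores_one(self):
        pairs = [(f"c{i}", f"c{j}") for i in range(6)
                 for j in range(i + 1, 6)]
        pairs += [("x0", "x1"), ("x1", "x2"), ("x2", "x3")]
        net = pair_network(pairs)
        ann = _ann([(f"c{i}", "term") for i in range(6)])
        table, nv = neighbor_voting_auroc(net, ann, folds=3, seed=0)
        assert nv == pytest.approx(1.0)
        assert table.loc[0, "n_genes_in_network"] == 6

    def test_fold_scores_match_enumeration_oracle(self):
        # 9-gene toy: term genes {a0,a1,a2} forming a triangle plus a
        # 6-vertex ring of unannotated genes attached at a0
        ring = [(f"r{i}", f"r{(i + 1) % 6}") for i in range(6)]
        net = pair_network([("a0", "a1"), ("a1", "a2"), ("a0", "a2"),
                            ("a0", "r0")] + ring)
        ann = _ann([("a0", "t"), ("a1", "t"), ("a2", "t")])
        seed = 7
        table, nv = neighbor_voting_auroc(net, ann, folds=3, seed=seed)
        # oracle: replay the seeded fold split and score by hand
        rng = np.random.default_rng(seed)
        nodes = sorted(net.graph.nodes)
        members = np.array([nodes.index(g) for g in ["a0", "a1", "a2"]])
        perm = rng.permutation(members)
        adj = {g: set(net.graph.neighbors(g)) for g in nodes}
        never = [g for g in nodes if g not in {"a0", "a1", "a2"}]
        fold_aucs = []
        for f in range(3):
            hidden = [nodes[i] for i in perm[f::3]]
            visible = {g for g in ["a0", "a1", "a2"] if g not in hidden}

            def score(g):
                return len(adj[g] & visible) / len(adj[g])
            fold_aucs.append(_brute_auroc([score(h) for h in hidden],
                                          [score(n) for n in never]))
        assert nv == pytest.approx(np.mean(fold_aucs), abs=1e-12)

    def test_invariant_under_gene_relabeling(self, rng):
        base_edges = {(f"g{min(a, b):02d}", f"g{max(a, b):02d}")
                      for a, b in rng.integers(0, 30, size=(80, 2))
                      if a != b}
        genes = sorted({g for e in base_edges for g in e})
        ann_genes = genes[:9]
        mapping = {g: f"z{i:02d}" for i, g in
                   enumerate(rng.permutation(genes))}
        net1 = pair_network(sorted(base_edges))
        net2 = pair_network(sorted(
            tuple(sorted((mapping[a], mapping[b])))
            for a, b in base_edges))
        ann1 = _ann([(g, "t") for g in ann_genes])
        ann2 = _ann([(mapping[g], "t") for g in ann_genes])
        _, nv1 = neighbor_voting_auroc(net1, ann1, seed=3)
        _, nv2 = neighbor_voting_auroc(net2, ann2, seed=3)
        # same seeded split sizes, isomorphic graphs: identical AUROC
        # distribution; with one term and 3 folds the value is the mean
        # over the same multiset of hidden-set sizes
        assert nv1 == pytest.approx(nv2, abs=0.12)

    def test_small_terms_skipped(self):
        net = pair_network([("a", "b"), ("b", "c"), ("c", "d")])
        ann = _ann([("a", "tiny"), ("b", "tiny"),
                    ("a", "ok"), ("b", "ok"), ("c", "ok")])
        table, _ = neighbor_voting_auroc(net, ann, folds=3, seed=0)
        tiny = table.set_index("term_id").loc["tiny", "auroc_fold_mean"]
        assert np.isnan(tiny)


class TestDegreeAuroc:
    def test_hub_annotations_score_high(self):
        net = pair_network([("hub1", f"x{i}") for i in range(8)]
                           + [("hub2", f"x{i}") for i in range(8)]
                           + [("x0", "x1")])
        ann = _ann([("hub1", "t"), ("hub2", "t")])
        assert degree_auroc(net, ann) > 0.95

    def test_degree_regular_graph_exactly_half(self):
        ring = [(f"r{i}", f"r{(i + 1) % 8}") for i in range(8)]
        net = pair_network(ring)
        ann = _ann([("r0", "t"), ("r3", "t"), ("r5", "t")])
        assert degree_auroc(net, ann) == 0.5

    def test_random_annotations_on_hub_graph_average_half(self, rng):
        net = pair_network([("hub", f"x{i}") for i in range(15)]
                           + [(f"x{i}", f"x{i + 1}") for i in range(14)])
        genes = sorted(net.graph.nodes)
        vals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            ann = _ann([(g, "t")
                        for g in r.choice(genes, 5, replace=False)])
            vals.append(degree_auroc(net, ann))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)


class TestPairEnrichment:
    def test_hypergeometric_hand_example(self):
        # universe 6 genes (M=15 pairs), term {A,B,C} (K=3), network of 3
        # edges with 2 co-annotated -> p = (C(3,2)C(12,1)+C(3,3))/C(15,3)
        ann = AnnotationSet.from_pairs(
            [("A", "t"), ("B", "t"), ("C", "t"),
             ("D", "u"), ("E", "u"), ("F", "u"), ("A", "u")])
        net = pair_network([("A", "B"), ("A", "C"), ("A", "D")])
        table, _ = pair_enrichment(net, ann, correction="none")
        p = table.set_index("term_id").loc["t", "p_value"]
        assert p == pytest.approx(37 / 455)

    def test_zero_overlap_never_significant(self):
        ann = AnnotationSet.from_pairs(
            [(g, "t") for g in "ABC"] + [(g, "u") for g in "DEF"])
        net = pair_network([("A", "D"), ("B", "E")])
        table, n_sig = pair_enrichment(net, ann)
        assert (table["p_value"] == 1.0).all() or \
            (table.loc[table["k"] == 0, "p_value"] >= 0.999).all()
        assert n_sig == 0

    def test_extreme_tail_identity(self):
        ann = AnnotationSet.from_pairs(
            [(g, "t") for g in "ABC"] + [(g, "u") for g in "DEF"])
        net = pair_network([("A", "B"), ("A", "C"), ("B", "C")])
        table, _ = pair_enrichment(net, ann, correction="none")
        p = table.set_index("term_id").loc["t", "p_value"]
        assert p == pytest.approx(1 / comb(15, 3))

    def test_matches_exhaustive_combinatorial_sum(self, rng):
        genes = [f"g{i}" for i in range(8)]  # M = 28
        ann = AnnotationSet.from_pairs([(g, "t") for g in genes[:4]]
                                       + [(g, "u") for g in genes])
        edges = {tuple(sorted(p)) for p in
                 rng.choice(genes, size=(6, 2)) if p[0] != p[1]}
        net = pair_network(sorted(edges))
        table, _ = pair_enrichment(net, ann, correction="none")
        row = table.set_index("term_id").loc["t"]
        m_pop, big_k, n, k = int(row["M"]), int(row["K"]), int(row["n"]), \
            int(row["k"])
        oracle = sum(
            comb(big_k, i) * comb(m_pop - big_k, n - i)
            for i in range(k, min(n, big_k) + 1)
        ) / comb(m_pop, n)
        assert row["p_value"] == pytest.approx(oracle, abs=1e-12)


def test_benjamini_hochberg_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=25)
    ours = _benjamini_hochberg(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, theirs, atol=1e-12)
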