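"""Gene-set dedup, negative selection, model training, CV and expansion."""

import math

import numpy as np
import pytest

from endosig.expand import (
    CVReport,
    ExpansionModel,
    cross_validate,
    dedup_gene_sets,
    expand_gene_set,
    qualify_gene_set,
    select_negatives,
    train_expansion_model,
)
from endosig.netio import GeneSet

from .conftest import make_net


def brute_components(n_sets, edges):
    """Tiny union-find oracle for overlap-graph components."""
    parent = list(range(n_sets))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        parent[ri] = rj
    return len({find(i) for i in range(n_sets)})


class TestDedup:
    def test_containment_collapses_to_larger_set(self, geneset):
        a = geneset("A", {"1", "2", "3", "4", "5"})
        b = geneset("B", {"1", "2", "3"})
        out = dedup_gene_sets([a, b])
        assert [s.id for s in out] == ["A"]

    def test_disjoint_sets_both_kept(self, geneset):
        out = dedup_gene_sets([geneset("A", {"1"}), geneset("B", {"2"})])
        assert {s.id for s in out} == {"A", "B"}

    def test_chain_merges_transitively(self, geneset):
        # A~B and B~C but A and C disjoint: connectivity, not pairwise overlap
        a = geneset("A", {"1", "2", "3"})
        b = geneset("B", {"2", "3", "9", "8"})
        c = geneset("C", {"9", "8", "7"})
        overlap = lambda x, y: len(x.genes & y.genes) / min(len(x), len(y))
        edges = [
            (i, j)
            for i, x in enumerate([a, b, c])
            for j, y in enumerate([a, b, c])
            if i < j and overlap(x, y) >= 0.6
        ]
        assert brute_components(3, edges) == 1  # oracle agrees it is one component
        out = dedup_gene_sets([a, b, c])
        assert len(out) == 1 and out[0].id == "B"  # largest set represents

    def test_tie_broken_by_smallest_id(self, geneset):
        a = geneset("Z", {"1", "2"})
        b = geneset("A", {"1", "2"})
        out = dedup_gene_sets([a, b])
        assert [s.id for s in out] == ["A"]

    def test_empty_set_rejected(self, geneset):
        with pytest.raises(ValueError, match="empty"):
            dedup_gene_sets([geneset("A", set())])


def hypergeom_tail_oracle(universe, n_seeds, n_ann, overlap):
    """P(X >= overlap) by direct summation of hypergeometric mass."""
    total = 0.0
    for k in range(overlap, min(n_seeds, n_ann) + 1):
        total += (
            math.comb(n_seeds, k)
            * math.comb(universe - n_seeds, n_ann - k)
            / math.comb(universe, n_ann)
        )
    return total


class TestSelectNegatives:
    def _net(self, n=1000):
        # a sparse ring so every gene is a node; topology is irrelevant here
        genes = [f"g{i}" for i in range(n)]
        return make_net([(genes[i], genes[(i + 1) % n]) for i in range(n)])

    def test_disjoint_annotation_supplies_negatives(self, geneset):
        net = self._net(1000)
        seeds = geneset("seeds", {f"g{i}" for i in range(10)})
        other = geneset("other", {f"g{i}" for i in range(100, 140)})
        assert hypergeom_tail_oracle(1000, 10, 40, 0) >= 0.05
        negs = select_negatives(seeds, {"other": other}, net)
        assert negs.genes == other.genes

    def test_significantly_overlapping_annotation_excluded(self, geneset):
        net = self._net(1000)
        seeds = geneset("seeds", {f"g{i}" for i in range(10)})
        shared = geneset("shared", {f"g{i}" for i in range(8)} | {"g500", "g501"})
        clean = geneset("clean", {f"g{i}" for i in range(200, 240)})
        # oracle: sharing 8 of 10 seeds in a 1000-gene universe is very unlikely
        assert hypergeom_tail_oracle(1000, 10, 10, 8) < 0.05
        negs = select_negatives(seeds, {"shared": shared, "clean": clean}, net)
        assert negs.genes == clean.genes

    def test_annotations_identical_to_seeds_error(self, geneset):
        net = self._net(100)
        seeds = geneset("seeds", {f"g{i}" for i in range(10)})
        with pytest.raises(ValueError, match="more annotation sets"):
            select_negatives(seeds, {"same": seeds}, net)


class TestTrainModel:
    def test_separable_cliques_rank_correctly(self, two_cliques):
        net, p_nodes, n_nodes = two_cliques
        pos = GeneSet("pos", genes=frozenset(p_nodes[:9]))
        neg = GeneSet("neg", genes=frozenset(n_nodes[:9]))
        model = train_expansion_model(net, pos, neg, seed=0)
        probs = model.predict(net, [p_nodes[9], n_nodes[9]])
        assert probs[p_nodes[9]] > probs[n_nodes[9]]

    def test_identical_adjacency_rows_score_equally(self):
        # x and y are twin leaves of the same hubs: identical feature rows
        net = make_net(
            [("x", "h1"), ("x", "h2"), ("y", "h1"), ("y", "h2"), ("h1", "p1"), ("h2", "n1"), ("p1", "p2"), ("n1", "n2")]
        )
        model = train_expansion_model(
            net, GeneSet("p", genes={"p1", "p2"}), GeneSet("n", genes={"n1", "n2"}), seed=0
        )
        probs = model.predict(net, ["x", "y"])
        assert probs["x"] == pytest.approx(probs["y"], abs=1e-12)

    def test_stronger_regularization_shrinks_coefficients(self, two_cliques):
        net, p_nodes, n_nodes = two_cliques
        pos = GeneSet("pos", genes=frozenset(p_nodes[:9]))
        neg = GeneSet("neg", genes=frozenset(n_nodes[:9]))
        norm = lambda reg: np.linalg.norm(
            train_expansion_model(net, pos, neg, reg=reg, seed=0).coefficients
        )
        assert norm(2.0) < norm(1.0)

    def test_overlapping_classes_rejected(self, two_cliques):
        net, p_nodes, _ = two_cliques
        with pytest.raises(ValueError, match="overlap"):
            train_expansion_model(
                net,
                GeneSet("p", genes=frozenset(p_nodes[:5])),
                GeneSet("n", genes=frozenset(p_nodes[4:8])),
            )


class TestCrossValidate:
    def _sets(self, two_cliques):
        net, p_nodes, n_nodes = two_cliques
        return net, GeneSet("p", genes=frozenset(p_nodes)), GeneSet("n", genes=frozenset(n_nodes))

    def test_perfect_separation_scores_positive(self, two_cliques):
        net, pos, neg = self._sets(two_cliques)
        report = cross_validate(net, pos, neg, k=3, seed=1)
        assert all(s > 0 for s in report.fold_scores)
        assert report.n_positives == 10

    def test_balanced_perfect_fold_scores_exactly_one(self, two_cliques):
        # prior = 0.5 per fold and perfect ranking: log2(1 / 0.5) = 1
        net, pos, neg = self._sets(two_cliques)
        report = cross_validate(net, pos, neg, k=5, seed=1)
        assert report.fold_scores == pytest.approx([1.0] * 5)
        assert report.median_score == pytest.approx(1.0)

    def test_deterministic_and_order_invariant(self, two_cliques):
        net, pos, neg = self._sets(two_cliques)
        r1 = cross_validate(net, pos, neg, k=3, seed=4)
        # rebuild the same sets from a different iteration order
        pos2 = GeneSet("p", genes=frozenset(sorted(pos.genes, reverse=True)))
        r2 = cross_validate(net, pos2, neg, k=3, seed=4)
        assert r1.fold_scores == r2.fold_scores

    def test_too_few_genes_per_class(self, two_cliques):
        net, pos, _ = self._sets(two_cliques)
        with pytest.raises(ValueError, match="k"):
            cross_validate(net, pos, GeneSet("n", genes={"n0", "n1"}), k=3)


class TestQualify:
    @pytest.mark.parametrize(
        "n_genes,median,expected",
        [(14, 2.0, False), (20, 0.99, False), (15, 1.0, True)],
    )
    def test_gate_boundaries(self, n_genes, median, expected):
        seeds = GeneSet("s", genes=frozenset(f"g{i}" for i in range(n_genes)))
        cv = CVReport([median] * 3, median, n_genes)
        assert qualify_gene_set(seeds, cv) is expected


def constant_probability_model(net, prob):
    """A hand-built model scoring every gene of an edgeless net at `prob`."""
    n = net.n_nodes
    return ExpansionModel(
        feature_genes=net.node_order,
        coefficients=np.zeros(n),
        intercept=float(np.log(prob / (1 - prob))),
        regularization_strength=1.0,
        scaler_mean=np.zeros(n),
        scaler_scale=np.ones(n),
    )


class TestExpand:
    def _edgeless(self):
        return make_net([], nodes=[f"g{i}" for i in range(6)])

    def test_probability_below_threshold_not_added(self):
        net = self._edgeless()
        model = constant_probability_model(net, 0.79)
        seeds = GeneSet("s", genes={"g0"})
        expanded, _ = expand_gene_set(model, net, seeds, threshold=0.80)
        assert expanded.genes == seeds.genes

    def test_probability_at_threshold_added(self):
        net = self._edgeless()
        model = constant_probability_model(net, 0.80)
        seeds = GeneSet("s", genes={"g0"})
        expanded, _ = expand_gene_set(model, net, seeds, threshold=0.80)
        assert expanded.genes == net.nodes

    def test_impossible_threshold_returns_seeds(self):
        net = self._edgeless()
        model = constant_probability_model(net, 0.99)
        seeds = GeneSet("s", genes={"g0"})
        expanded, _ = expand_gene_set(model, net, seeds, threshold=1.01)
        assert expanded.genes == seeds.genes

    def test_expansion_monotone_in_threshold(self, two_cliques):
        net, p_nodes, n_nodes = two_cliques
        model = train_expansion_model(
            net,
            GeneSet("p", genes=frozenset(p_nodes[:6])),
            GeneSet("n", genes=frozenset(n_nodes[:6])),
            seed=0,
        )
        seeds = GeneSet("p", genes=frozenset(p_nodes[:6]))
        previous = None
        for threshold in (0.9, 0.6, 0.3, 0.1):
            expanded, _ = expand_gene_set(model, net, seeds, threshold)
            if previous is not None:
                assert previous.genes <= expanded.genes
            previous = expanded
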