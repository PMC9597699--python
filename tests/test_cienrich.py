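"""Degree-matched nulls, enrichment scores, permutation p-values, CI calls."""

import itertools
import math

import numpy as np
import pytest

from endosig.cienrich import (
    EnrichmentResult,
    build_null_ensemble,
    call_ci_clusters,
    degree_matched_sample,
    enrichment_score,
    permutation_pvalue,
    unannotated_ci_probability_contrast,
)
from endosig.cluster import Cluster
from endosig.netio import GeneSet, build_degree_index

from .conftest import make_net


class TestDegreeMatchedSample:
    def test_unique_degree_maps_to_itself(self, path_net):
        idx = build_degree_index(path_net)
        rng = np.random.default_rng(0)
        assert degree_matched_sample({"b"}, idx, rng, min_candidates=1) == {"b"}

    def test_star_center_forced(self, star5):
        idx = build_degree_index(star5)
        rng = np.random.default_rng(0)
        assert degree_matched_sample({"h"}, idx, rng, min_candidates=1) == {"h"}

    def test_output_size_matches_input(self, small_scenario, small_index):
        rng = np.random.default_rng(5)
        genes = set(list(sorted(small_scenario.network.nodes))[:50])
        out = degree_matched_sample(genes, small_index, rng)
        assert len(out) == 50 and out <= small_scenario.network.nodes

    def test_replacement_degrees_match_source(self):
        # two clear degree classes: isolated edges (degree 1) and a clique (degree 7)
        edges = [(f"u{i}", f"v{i}") for i in range(10)]
        clique = [f"c{i}" for i in range(8)]
        edges += list(itertools.combinations(clique, 2))
        net = make_net(edges)
        idx = build_degree_index(net)
        rng = np.random.default_rng(1)
        source = {"u0", "c0"}
        counts = {1: 0, 7: 0}
        n_draws = 10_000
        for _ in range(n_draws):
            for g in degree_matched_sample(source, idx, rng, min_candidates=1):
                counts[idx.degree_of[g]] += 1
        # each draw must return exactly one gene of each degree class
        assert counts[1] == n_draws and counts[7] == n_draws


class TestEnrichmentScore:
    def test_forced_formula_value(self):
        cg = {f"g{i}" for i in range(10)}
        ci = {f"g{i}" for i in range(4)} | {f"c{i}" for i in range(46)}
        assert enrichment_score(cg, ci, background=1000) == pytest.approx(3.0)

    def test_zero_overlap_is_neg_inf(self):
        assert enrichment_score({"a"}, {"b"}, background=10) == float("-inf")

    def test_cluster_fraction_equals_background_fraction(self):
        genes = {f"g{i}" for i in range(5)}
        ci = genes | {f"c{i}" for i in range(45)}
        assert enrichment_score(genes, ci, background=50) == pytest.approx(0.0)

    def test_monotone_in_overlap(self):
        ci = {f"g{i}" for i in range(50)}
        background = 1000
        scores = []
        for overlap in range(1, 11):
            cg = {f"g{i}" for i in range(overlap)} | {f"x{i}" for i in range(10 - overlap)}
            scores.append(enrichment_score(cg, ci, background))
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            enrichment_score({"a"}, set(), background=10)
        with pytest.raises(ValueError):
            enrichment_score({"a"}, {"a"}, background=0)


class TestPermutationPvalue:
    def test_forced_count(self):
        null = np.concatenate([np.full(10, 5.0), np.full(4990, -1.0)])
        assert permutation_pvalue(4.0, null) == pytest.approx(10 / 5001)

    def test_zero_exceedances_verbatim_gives_zero(self):
        assert permutation_pvalue(10.0, np.zeros(100)) == 0.0
        assert permutation_pvalue(10.0, np.zeros(100), pseudo_count=True) == pytest.approx(1 / 101)

    def test_neg_inf_observed_counts_everything(self):
        null = np.concatenate([np.full(50, float("-inf")), np.full(50, 1.0)])
        assert permutation_pvalue(float("-inf"), null) == pytest.approx(100 / 101)

    def test_non_increasing_in_observed_score(self):
        rng = np.random.default_rng(0)
        null = rng.normal(size=500)
        ps = [permutation_pvalue(e, null) for e in np.linspace(-3, 3, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestNullEnsemble:
    def test_zero_lists_rejected(self, small_scenario, small_index):
        with pytest.raises(ValueError, match="n_lists"):
            build_null_ensemble(
                small_scenario.ci_genes, small_scenario.network, small_index,
                small_scenario.ci_genes, n_lists=0,
            )

    def test_dense_list_yields_clusters_and_is_deterministic(self, small_scenario, small_index):
        sc = small_scenario
        dense = sc.disease_seeds["disease_0"]
        e1 = build_null_ensemble(dense, sc.network, small_index, sc.ci_genes, n_lists=30, seed=9)
        e2 = build_null_ensemble(dense, sc.network, small_index, sc.ci_genes, n_lists=30, seed=9)
        assert e1.n_random_clusters > 0
        assert np.array_equal(e1.null_cluster_scores, e2.null_cluster_scores)
        assert e1.n_lists == 30

    def test_all_scores_from_min_size_clusters(self, small_scenario, small_index):
        sc = small_scenario
        ens = build_null_ensemble(
            sc.disease_seeds["disease_1"], sc.network, small_index, sc.ci_genes,
            n_lists=20, min_size=5, seed=2,
        )
        # every score is an E of a >=5-gene cluster: finite values bounded by
        # the most extreme achievable with >=1 overlap in a 5-gene cluster
        finite = ens.null_cluster_scores[np.isfinite(ens.null_cluster_scores)]
        ci_frac = len(sc.ci_genes) / sc.network.n_nodes
        assert finite.size == 0 or finite.max() <= np.log2(1.0 / ci_frac) + 1e-9


class TestExchangeability:
    def test_sampled_null_matches_full_enumeration(self):
        """On a tiny graph, the sampled E-null matches exhaustive enumeration
        of every degree-valid replacement set."""
        # 12 nodes: triangle chain gives degree classes {1: 4 nodes, 2: 4, 3: 4}
        net = make_net(
            [("a", "b"), ("b", "c"), ("c", "a"),      # triangle: a,b,c
             ("a", "d"), ("b", "e"), ("c", "f"),      # pendants d,e,f (deg 1)
             ("g", "h"), ("h", "i"), ("i", "g"),      # second triangle
             ("g", "j"), ("h", "k"), ("i", "l")]
        )
        idx = build_degree_index(net)
        ci = {"a", "g", "d"}
        background = 12
        genes = {"a", "d"}  # degrees 3 and 1; buckets are disjoint
        deg3 = idx.genes_at[3]
        deg1 = idx.genes_at[1]
        e_obs = enrichment_score(genes, ci, background)
        # exhaustive null over all (deg-3 gene, deg-1 gene) replacements
        exact_scores = [
            enrichment_score({x, y}, ci, background) if ({x, y} & ci) else float("-inf")
            for x in deg3
            for y in deg1
        ]
        p_exact = np.mean([e >= e_obs for e in exact_scores])
        rng = np.random.default_rng(3)
        n = 2000
        hits = 0
        for _ in range(n):
            s = degree_matched_sample(genes, idx, rng, min_candidates=1)
            if enrichment_score(s, ci, background) >= e_obs:
                hits += 1
        p_sampled = hits / n
        se = math.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(p_sampled - p_exact) <= 3 * se


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_end)
        adj[i] = running_min
    return adj


def result(owner, cid, e, p, size=6):
    genes = GeneSet(f"{owner}|{cid}", genes=frozenset(f"{owner}{cid}_{i}" for i in range(size)))
    return EnrichmentResult(Cluster(owner, cid, genes), e, p)


class TestCalls:
    def test_bh_matches_brute_force(self):
        pvals = [0.01, 0.02, 0.03]
        results = [result("d", i, 1.0, p) for i, p in enumerate(pvals)]
        called = call_ci_clusters(results)
        assert [r.fdr for r in called] == pytest.approx(bh_oracle(pvals))
        assert [r.fdr for r in called] == pytest.approx([0.03, 0.03, 0.03])

    @pytest.mark.parametrize("seed", range(5))
    def test_bh_matches_brute_force_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        pvals = rng.uniform(size=rng.integers(2, 100)).tolist()
        results = [result("d", i, 1.0, p) for i, p in enumerate(pvals)]
        called = call_ci_clusters(results)
        assert [r.fdr for r in called] == pytest.approx(bh_oracle(pvals), abs=1e-12)

    def test_single_cluster_fdr_equals_p(self):
        called = call_ci_clusters([result("d", 0, 2.0, 0.04)])
        assert called[0].fdr == pytest.approx(0.04)
        assert called[0].is_ci_enriched

    def test_negative_e_never_called(self):
        called = call_ci_clusters([result("d", 0, float("-inf"), 0.001)])
        assert not called[0].is_ci_enriched

    def test_mixed_owner_rejected(self):
        with pytest.raises(ValueError, match="one owner"):
            call_ci_clusters([result("a", 0, 1.0, 0.1), result("b", 0, 1.0, 0.1)])


class TestContrast:
    def _results(self, enriched_genes, other_genes):
        r1 = result("d", 0, 2.0, 0.001, size=len(enriched_genes))
        r1.cluster.genes = GeneSet("e", genes=frozenset(enriched_genes))
        r1.is_ci_enriched = True
        r2 = result("d", 1, -1.0, 0.9, size=len(other_genes))
        r2.cluster.genes = GeneSet("n", genes=frozenset(other_genes))
        return [r1, r2]

    def test_identical_distributions_show_no_signal(self):
        rng = np.random.default_rng(0)
        e_genes = [f"e{i}" for i in range(40)]
        n_genes = [f"n{i}" for i in range(40)]
        scores = {g: float(rng.uniform()) for g in e_genes + n_genes}
        res = unannotated_ci_probability_contrast(self._results(e_genes, n_genes), set(), scores)
        assert abs(res.mean_enriched - res.mean_non_enriched) < 0.15
        assert res.p_ranksum > 0.05

    def test_separated_groups(self):
        e_genes = [f"e{i}" for i in range(20)]
        n_genes = [f"n{i}" for i in range(20)]
        scores = {g: 0.9 for g in e_genes} | {g: 0.1 for g in n_genes}
        res = unannotated_ci_probability_contrast(self._results(e_genes, n_genes), set(), scores)
        assert res.mean_enriched - res.mean_non_enriched == pytest.approx(0.8)
        assert res.p_ranksum < 1e-6 and res.p_fisher < 1e-6

    def test_ci_genes_excluded_and_empty_group_raises(self):
        e_genes = [f"e{i}" for i in range(5)]
        n_genes = [f"n{i}" for i in range(5)]
        scores = {g: 0.5 for g in e_genes + n_genes}
        with pytest.raises(ValueError, match="enriched"):
            unannotated_ci_probability_contrast(
                self._results(e_genes, n_genes), set(e_genes), scores
            )
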