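"""Description length, exhaustive oracle and the greedy optimizer."""

import numpy as np
import pytest
from scipy.special import gammaln

from topicsbm.bigraph import BipartiteGraph, build_bipartite
from topicsbm.blockmodel import (FitConfig, description_length,
                                 exhaustive_minimize, extract_clusters,
                                 extract_topics, fit)
from topicsbm.matrix import ExpressionMatrix

from conftest import random_tiny_graph


def _toy_graph():
    dense = np.array([[3, 2, 0, 0],
                      [1, 3, 0, 1],
                      [0, 0, 2, 3],
                      [0, 1, 3, 2]], dtype=float)
    return build_bipartite(ExpressionMatrix(dense), discretize="exact")


class TestDescriptionLength:
    def test_single_block_sigma_is_model_cost_only(self):
        """With one block per side the likelihood term vanishes exactly."""
        graph = _toy_graph()
        total = graph.total_edges
        sigma = description_length(graph, (np.zeros(4, int), np.zeros(4, int)))
        # independent evaluation of the counting costs for the 1x1 model
        def lnb(a, b):
            return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        expected = 0.0
        for n in (4, 4):  # partition cost per side, one block of size n
            expected += np.log(n) + lnb(n - 1, 0) + gammaln(n + 1) - gammaln(n + 1)
        expected += lnb(total + 0, 0)          # 1x1 edge-count matrix
        expected += 2 * lnb(total + 3, 3)      # degree sequence per side
        assert sigma == pytest.approx(expected, abs=1e-9)

    def test_block_relabeling_leaves_sigma_unchanged(self):
        graph = _toy_graph()
        a = (np.array([0, 0, 1, 1]), np.array([0, 1, 1, 0]))
        b = (np.array([1, 1, 0, 0]), np.array([2, 0, 0, 2]))
        assert description_length(graph, a) == pytest.approx(
            description_length(graph, b), abs=1e-12)

    def test_toy_assignment_matches_handrolled_summation(self):
        """A from-scratch loop evaluation of the objective agrees exactly."""
        graph = _toy_graph()
        gb = np.array([0, 0, 1, 1])
        sb = np.array([0, 1, 1, 0])

        def lnb(a, b):
            return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

        def oracle(graph, gb, sb):
            n_bg, n_bs = gb.max() + 1, sb.max() + 1
            e = np.zeros((n_bg, n_bs))
            for gi, sj, m in zip(graph.gene_idx, graph.sample_idx, graph.mult):
                e[gb[gi], sb[sj]] += m
            total = e.sum()
            likelihood = 0.0
            for r in range(n_bg):
                for c in range(n_bs):
                    if e[r, c] > 0:
                        likelihood -= e[r, c] * np.log(
                            e[r, c] * total / (e[r].sum() * e[:, c].sum()))
            cost = 0.0
            for labels, n in [(gb, graph.n_genes), (sb, graph.n_samples)]:
                sizes = [int((labels == b).sum()) for b in range(labels.max() + 1)]
                cost += np.log(n) + lnb(n - 1, len(sizes) - 1) + gammaln(n + 1)
                cost -= sum(gammaln(sz + 1) for sz in sizes)
            cost += lnb(total + n_bg * n_bs - 1, n_bg * n_bs - 1)
            for r in range(n_bg):
                n_r = int((gb == r).sum())
                cost += lnb(e[r].sum() + n_r - 1, n_r - 1)
            for c in range(n_bs):
                n_c = int((sb == c).sum())
                cost += lnb(e[:, c].sum() + n_c - 1, n_c - 1)
            return likelihood + cost

        assert description_length(graph, (gb, sb)) == pytest.approx(
            oracle(graph, gb, sb), abs=1e-9)

    def test_mixed_side_block_rejected(self):
        graph = _toy_graph()
        mapping = {g: 0 for g in graph.genes} | {s: 0 for s in graph.samples}
        with pytest.raises(ValueError):
            description_length(graph, mapping)

    def test_sigma_invariant_under_node_reordering(self):
        rng = np.random.default_rng(0)
        graph = random_tiny_graph(rng)
        gb = rng.integers(0, 2, graph.n_genes)
        sb = rng.integers(0, 2, graph.n_samples)
        sigma = description_length(graph, (gb, sb))
        perm_g = rng.permutation(graph.n_genes)
        perm_s = rng.permutation(graph.n_samples)
        inv_g = np.argsort(perm_g)
        inv_s = np.argsort(perm_s)
        permuted = BipartiteGraph(
            [graph.genes[i] for i in perm_g], [graph.samples[j] for j in perm_s],
            inv_g[graph.gene_idx], inv_s[graph.sample_idx], graph.mult)
        assert description_length(permuted, (gb[perm_g], sb[perm_s])) == \
            pytest.approx(sigma, abs=1e-9)


class TestExhaustive:
    def test_single_node_sides_trivial(self):
        graph = BipartiteGraph(["g0"], ["s0"], [0], [0], [2])
        (gb, sb), sigma = exhaustive_minimize(graph)
        assert list(gb) == [0] and list(sb) == [0]
        assert np.isfinite(sigma)

    def test_doubled_multiplicities_keep_argmin(self):
        rng = np.random.default_rng(4)
        graph = random_tiny_graph(rng, max_side=3)
        doubled = BipartiteGraph(graph.genes, graph.samples, graph.gene_idx,
                                 graph.sample_idx, graph.mult * 2)
        (gb1, sb1), _ = exhaustive_minimize(graph)
        (gb2, sb2), _ = exhaustive_minimize(doubled)
        assert np.array_equal(gb1, gb2) and np.array_equal(sb1, sb2)

    def test_planted_two_block_structure_recovered(self):
        dense = np.zeros((3, 3))
        dense[:2, :2] = 40
        dense[2, 2] = 40
        graph = build_bipartite(ExpressionMatrix(dense), discretize="exact")
        (gb, sb), _ = exhaustive_minimize(graph)
        assert list(gb) == [0, 0, 1]
        assert list(sb) == [0, 0, 1]

    def test_large_graphs_refused(self):
        rng = np.random.default_rng(5)
        dense = rng.integers(1, 3, size=(8, 8)).astype(float)
        graph = build_bipartite(ExpressionMatrix(dense), discretize="exact")
        with pytest.raises(ValueError):
            exhaustive_minimize(graph)


class TestFit:
    def test_matches_exhaustive_on_tiny_graphs(self, tiny_graph_suite):
        for idx, graph in enumerate(tiny_graph_suite[:8]):
            _, sigma_opt = exhaustive_minimize(graph)
            h = fit(graph, FitConfig(n_restarts=20, seed=idx))
            assert h.level(0).sigma == pytest.approx(sigma_opt, abs=1e-9)

    def test_seeded_fit_is_deterministic(self):
        graph = _toy_graph()
        cfg = FitConfig(n_restarts=5, seed=3)
        h1, h2 = fit(graph, cfg), fit(graph, cfg)
        assert h1.n_levels == h2.n_levels
        for l1, l2 in zip(h1.levels, h2.levels):
            assert np.array_equal(l1.gene_blocks, l2.gene_blocks)
            assert np.array_equal(l1.sample_blocks, l2.sample_blocks)
            assert l1.sigma == l2.sigma

    def test_never_worse_than_trivial_baselines(self):
        rng = np.random.default_rng(6)
        for idx in range(5):
            graph = random_tiny_graph(rng)
            h = fit(graph, FitConfig(n_restarts=3, seed=idx))
            one = description_length(graph, (np.zeros(graph.n_genes, int),
                                             np.zeros(graph.n_samples, int)))
            singles = description_length(graph, (np.arange(graph.n_genes),
                                                 np.arange(graph.n_samples)))
            assert h.level(0).sigma <= one + 1e-9
            assert h.level(0).sigma <= singles + 1e-9

    def test_disjoint_groups_separated_exactly(self):
        dense = np.zeros((6, 6))
        dense[:3, :3] = 30
        dense[3:, 3:] = 30
        graph = build_bipartite(ExpressionMatrix(dense), discretize="exact")
        h = fit(graph, FitConfig(n_restarts=5, seed=0))
        clusters = extract_clusters(h, 0)
        topics = extract_topics(h, 0)
        assert len({clusters[f"s{j}"] for j in range(3)}) == 1
        assert len({clusters[f"s{j}"] for j in range(3, 6)}) == 1
        assert clusters["s0"] != clusters["s3"]
        assert topics["g0"] != topics["g3"]

    def test_levels_are_coarsenings(self):
        rng = np.random.default_rng(7)
        dense = rng.integers(0, 6, size=(12, 10)).astype(float)
        graph = build_bipartite(ExpressionMatrix(dense), discretize="exact")
        h = fit(graph, FitConfig(n_restarts=3, seed=1))
        for lower, upper in zip(h.levels[:-1], h.levels[1:]):
            # a block at the lower level maps into exactly one upper block
            for blocks in [(lower.gene_blocks, upper.gene_blocks),
                           (lower.sample_blocks, upper.sample_blocks)]:
                low, up = blocks
                for b in np.unique(low):
                    assert np.unique(up[low == b]).size == 1
        last = h.levels[-1]
        assert last.n_topics == 1 and last.n_clusters == 1

    def test_edgeless_graph_rejected(self):
        graph = BipartiteGraph(["g0"], ["s0"], np.array([], int),
                               np.array([], int), np.array([], int))
        with pytest.raises(ValueError):
            fit(graph, FitConfig(n_restarts=1, seed=0))


class TestExtraction:
    def test_block_counts_and_dense_ids(self):
        dense = np.zeros((5, 6))
        dense[:2, :2] = 20
        dense[2:4, 2:4] = 20
        dense[4, 4:] = 20
        graph = build_bipartite(ExpressionMatrix(dense), discretize="exact")
        h = fit(graph, FitConfig(n_restarts=5, seed=2))
        clusters = extract_clusters(h, 0)
        topics = extract_topics(h, 0)
        assert max(clusters.values()) + 1 == len(set(clusters.values()))
        assert max(topics.values()) + 1 == len(set(topics.values()))
        assert h.level(0).n_topics == len(set(topics.values()))
        assert h.level(0).n_clusters == len(set(clusters.values()))

    def test_invalid_level_rejected(self):
        graph = _toy_graph()
        h = fit(graph, FitConfig(n_restarts=2, seed=0))
        with pytest.raises(ValueError):
            extract_clusters(h, 99)

    def test_hierarchy_roundtrip(self, tmp_path):
        graph = _toy_graph()
        h = fit(graph, FitConfig(n_restarts=2, seed=0))
        h.write(tmp_path / "h.tsv", tmp_path / "h.json")
        from topicsbm.blockmodel import BlockHierarchy

        back = BlockHierarchy.read(tmp_path / "h.tsv", meta_path=tmp_path / "h.json")
        assert back.n_levels == h.n_levels
        assert back.level(0).sigma == pytest.approx(h.level(0).sigma)
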