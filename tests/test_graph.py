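"""Hypergraph construction, edge weighting, random walks, sampling."""

import numpy as np
import pytest

import funcsig as fs
from funcsig.graph import stationary_matrix


def make_graph(edge_specs, mode="expression", genes=None):
    if genes is None:
        genes = sorted({g for _, members, *_ in edge_specs for g in members})
    edges = [fs.Hyperedge(eid, set(members),
                          set(rest[0]) if rest else set())
             for eid, members, *rest in edge_specs]
    return genes, edges


class TestEdgeWeights:
    def test_information_content_with_descendants(self):
        # e2 absorbs e1's mass: w(e1) = -log2(3/8), w(e2) = -log2(8/8) = 0
        e1 = fs.Hyperedge("e1", {"a", "b", "c"})
        e2 = fs.Hyperedge("e2", {"a", "b", "c", "d", "e"}, {"e1"})
        w = {e.id: e.weight for e in fs.ic_weight_ontology([e1, e2])}
        assert w["e1"] == pytest.approx(-np.log2(3 / 8), abs=1e-12)
        assert w["e2"] == pytest.approx(0.0, abs=1e-12)

    def test_single_edge_has_zero_weight(self):
        (e,) = fs.ic_weight_ontology([fs.Hyperedge("e", {"a", "b"})])
        assert e.weight == 0.0
        (e,) = fs.size_weight_expression([fs.Hyperedge("e", {"a", "b"})])
        assert e.weight == 0.0

    def test_size_weights_hand_examples(self):
        edges = [fs.Hyperedge("x", {"a", "b"}),
                 fs.Hyperedge("y", {"a", "b", "c", "d", "e", "f"})]
        w = {e.id: e.weight for e in fs.size_weight_expression(edges)}
        assert w["x"] == pytest.approx(2.0)
        assert w["y"] == pytest.approx(-np.log2(6 / 8))
        quarters = fs.size_weight_expression(
            [fs.Hyperedge(f"e{i}", {f"g{i}"}) for i in range(4)])
        assert all(e.weight == pytest.approx(2.0) for e in quarters)

    def test_random_dag_matches_descendant_sum_oracle(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(40)]
        edges = []
        for i in range(20):
            members = set(rng.choice(genes, size=rng.integers(1, 8),
                                     replace=False))
            # children only among earlier edges: acyclic by construction
            n_child = rng.integers(0, min(i, 3) + 1)
            children = {f"e{j}" for j in
                        rng.choice(i, size=n_child, replace=False)} \
                if i and n_child else set()
            edges.append(fs.Hyperedge(f"e{i}", members, children))
        weighted = {e.id: e.weight for e in fs.ic_weight_ontology(edges)}

        # independent oracle: explicit descendant enumeration per edge
        by_id = {e.id: e for e in edges}
        total = sum(len(e) for e in edges)
        for e in edges:
            desc, stack = {e.id}, [e.id]
            while stack:
                for c in by_id[stack.pop()].children:
                    if c in by_id and c not in desc:
                        desc.add(c)
                        stack.append(c)
            expected = max(-np.log2(sum(len(by_id[d]) for d in desc) / total),
                           0.0)
            assert weighted[e.id] == pytest.approx(expected, abs=1e-12)

    def test_cycle_detection_names_cycle(self):
        a = fs.Hyperedge("a", {"x"}, {"b"})
        b = fs.Hyperedge("b", {"y"}, {"a"})
        with pytest.raises(ValueError, match="cycle"):
            fs.ic_weight_ontology([a, b])

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            fs.ic_weight_ontology([])
        with pytest.raises(ValueError):
            fs.size_weight_expression([])


class TestTransitionMatrix:
    def test_hand_computed_entries(self):
        uni = fs.GeneUniverse(["u", "v", "z"])
        graph = fs.FunctionalHypergraph(uni, [
            fs.Hyperedge("e1", {"u", "v"}, weight=1.0),
            fs.Hyperedge("e2", {"u", "v", "z"}, weight=1.0)])
        B = fs.build_transition_matrix(graph).matrix
        assert B[0, 1] == pytest.approx(5 / 12)
        assert B[0, 0] == pytest.approx(5 / 12)
        assert B[0, 2] == pytest.approx(1 / 6)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_single_edge_symmetry(self):
        uni = fs.GeneUniverse(["u", "v"])
        graph = fs.FunctionalHypergraph(
            uni, [fs.Hyperedge("e", {"u", "v"}, weight=3.7)])
        B = fs.build_transition_matrix(graph).matrix
        assert np.allclose(B, 0.5)

    def test_row_stochastic_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            genes = [f"g{i}" for i in range(15)]
            edges = fs.size_weight_expression([
                fs.Hyperedge(f"e{j}", set(rng.choice(genes,
                                                     size=rng.integers(2, 9),
                                                     replace=False)))
                for j in range(8)])
            graph = fs.FunctionalHypergraph(fs.GeneUniverse(genes), edges)
            B = fs.build_transition_matrix(graph).matrix
            active = [i for i, g in enumerate(genes)
                      if g not in graph.isolated]
            assert np.allclose(B[active].sum(axis=1), 1.0, atol=1e-12)

    def test_edge_weight_monotonicity(self):
        # raising w(e1) shifts u's transition mass toward e1's members
        def mass(w1):
            uni = fs.GeneUniverse(["u", "v", "z"])
            graph = fs.FunctionalHypergraph(uni, [
                fs.Hyperedge("e1", {"u", "v"}, weight=w1),
                fs.Hyperedge("e2", {"u", "z"}, weight=1.0)])
            B = fs.build_transition_matrix(graph).matrix
            return B[0, 1]

        masses = [mass(w) for w in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(masses, masses[1:]))

    def test_zero_degree_gene_rejected(self):
        uni = fs.GeneUniverse(["u", "v"])
        graph = fs.FunctionalHypergraph(
            uni, [fs.Hyperedge("e", {"u", "v"}, weight=0.0)])
        with pytest.raises(ValueError, match="zero degree"):
            fs.build_transition_matrix(graph)


class TestRandomWalkRestart:
    def two_gene_model(self, q):
        uni = fs.GeneUniverse(["u", "v"])
        graph = fs.FunctionalHypergraph(
            uni, [fs.Hyperedge("e", {"u", "v"}, weight=1.0)])
        return fs.build_transition_matrix(graph, restart_prob=q)

    def test_restart_only_limit(self):
        prof = fs.random_walk_restart(self.two_gene_model(1.0), "u")
        assert np.allclose(prof.distribution, [1.0, 0.0])

    def test_two_gene_closed_form(self):
        # B = [[1/2,1/2],[1/2,1/2]], q = 1/2 -> s_u = (3/4, 1/4)
        prof = fs.random_walk_restart(self.two_gene_model(0.5), "u")
        assert np.allclose(prof.distribution, [0.75, 0.25], atol=1e-6)

    def test_distribution_is_conserved(self):
        prof = fs.random_walk_restart(self.two_gene_model(0.3), "v")
        assert prof.distribution.sum() == pytest.approx(1.0, abs=1e-8)
        assert (prof.distribution >= 0).all()
        assert prof.converged

    def test_matches_dense_closed_form_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for trial in range(3):
            n = int(rng.integers(10, 50))
            genes = [f"g{i}" for i in range(n)]
            edges = fs.size_weight_expression(
                [fs.Hyperedge(f"e{j}",
                              set(rng.choice(genes, size=rng.integers(2, 10),
                                             replace=False)) | {genes[0]})
                 for j in range(n // 2)])
            graph = fs.FunctionalHypergraph(fs.GeneUniverse(genes), edges)
            model = fs.build_transition_matrix(graph, restart_prob=0.5)
            active = [g for g in genes if g not in graph.isolated]
            q, B = model.restart_prob, model.matrix
            closed = q * np.linalg.inv(np.eye(n) - (1 - q) * B.T)
            for source in active[:5]:
                prof = fs.random_walk_restart(model, source, tol=1e-8)
                i = model.universe.index[source]
                assert np.allclose(prof.distribution, closed[:, i], atol=1e-6)

    def test_stationary_matrix_agrees_with_per_source(self):
        model = self.two_gene_model(0.5)
        S = stationary_matrix(model)
        prof = fs.random_walk_restart(model, "u")
        assert np.allclose(S[:, 0], prof.distribution, atol=1e-5)

    def test_nonconvergence_raises_with_residual(self):
        uni = fs.GeneUniverse(["u", "v", "z"])
        graph = fs.FunctionalHypergraph(uni, [
            fs.Hyperedge("e1", {"u", "v"}, weight=1.0),
            fs.Hyperedge("e2", {"v", "z"}, weight=1.0)])
        model = fs.build_transition_matrix(graph, restart_prob=0.01)
        with pytest.raises(RuntimeError, match="residual"):
            fs.random_walk_restart(model, "u", tol=1e-14, max_iter=2)


class TestNeighborSampling:
    def make_profile(self, dist, genes):
        return fs.StationaryProfile("u", np.asarray(dist, float), 1, True)

    def test_degenerate_profile_hits_single_gene(self):
        uni = fs.GeneUniverse(["u", "v", "w"])
        prof = self.make_profile([0.0, 1.0, 0.0], uni)
        pos, neg = fs.sample_neighbors(prof, uni, n_pos=4, seed=0)
        assert set(pos) == {"v"}

    @pytest.mark.parametrize("n_pos", [1, 3, 20])
    def test_negative_ratio_is_five(self, n_pos):
        uni = fs.GeneUniverse([f"g{i}" for i in range(10)])
        dist = np.arange(10, dtype=float)
        dist /= dist.sum()
        prof = fs.StationaryProfile("g0", dist, 1, True)
        pos, neg = fs.sample_neighbors(prof, uni, n_pos=n_pos, seed=1)
        assert len(neg) == 5 * len(pos) == 5 * n_pos

    def test_source_never_sampled(self):
        uni = fs.GeneUniverse(["a", "b", "c"])
        prof = fs.StationaryProfile("a", np.array([0.9, 0.05, 0.05]), 1, True)
        pos, neg = fs.sample_neighbors(prof, uni, n_pos=50, seed=2)
        assert "a" not in pos and "a" not in neg

    def test_empirical_frequencies_match_multinomial_oracle(self):
        uni = fs.GeneUniverse(["s", "a", "b", "c"])
        dist = np.array([0.0, 0.5, 0.3, 0.2])
        prof = fs.StationaryProfile("s", dist, 1, True)
        n = 100_000
        pos, neg = fs.sample_neighbors(prof, uni, n_pos=n, seed=3)
        # positives ~ proportional to s
        for g, p in zip(["a", "b", "c"], [0.5, 0.3, 0.2]):
            freq = pos.count(g) / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * se
        # negatives ~ proportional to 1/(s + eps)
        inv = 1.0 / (dist[1:] + 1e-12)
        inv /= inv.sum()
        for g, p in zip(["a", "b", "c"], inv):
            freq = neg.count(g) / (5 * n)
            se = np.sqrt(p * (1 - p) / (5 * n))
            assert abs(freq - p) < 3 * se

    def test_reproducible_under_seed(self):
        uni = fs.GeneUniverse([f"g{i}" for i in range(6)])
        dist = np.full(6, 1 / 6)
        prof = fs.StationaryProfile("g0", dist, 1, True)
        draw1 = fs.sample_neighbors(prof, uni, n_pos=10, seed=7)
        draw2 = fs.sample_neighbors(prof, uni, n_pos=10, seed=7)
        assert draw1 == draw2


class TestUniverseAndGraphInvariants:
    def test_universe_rejects_duplicates_and_empties(self):
        with pytest.raises(ValueError):
            fs.GeneUniverse(["a", "a"])
        with pytest.raises(ValueError):
            fs.GeneUniverse(["a", ""])
        with pytest.raises(ValueError):
            fs.GeneUniverse([])

    def test_isolated_genes_flagged(self):
        uni = fs.GeneUniverse(["a", "b", "c"])
        graph = fs.FunctionalHypergraph(
            uni, [fs.Hyperedge("e", {"a", "b"}, weight=1.0)])
        assert graph.isolated == {"c"}

    def test_members_outside_universe_rejected(self):
        uni = fs.GeneUniverse(["a"])
        with pytest.raises(ValueError, match="outside the universe"):
            fs.FunctionalHypergraph(uni, [fs.Hyperedge("e", {"a", "zz"})])
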