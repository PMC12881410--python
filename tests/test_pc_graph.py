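"""Conditional-independence primitives and PC-stable graph learning."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from dagwas.pc_graph import (
    CIContext,
    CPDAG,
    ancestral_subgraph,
    apply_meek_rules,
    cpdag_from_dag,
    d_separated,
    dsep_ci_test,
    enforce_trait_constraints,
    fisher_z_test,
    learn_graph,
    learn_skeleton,
    orient_v_structures,
    partial_correlation,
)


class TestPartialCorrelation:
    def test_empty_conditioning_returns_marginal(self, rng):
        X = rng.normal(size=(200, 3))
        corr = np.corrcoef(X, rowvar=False)
        assert partial_correlation(corr, 0, 2) == pytest.approx(corr[0, 2])

    def test_matches_residual_regression_oracle(self, rng):
        X = rng.normal(size=(300, 5))
        X[:, 1] += 0.8 * X[:, 0]
        X[:, 2] += 0.5 * X[:, 1]
        corr = np.corrcoef(X, rowvar=False)
        for i, j, S in [(0, 2, (1,)), (0, 3, (1, 2)), (1, 4, (0, 2, 3))]:
            idx = list(S)
            Z = np.column_stack([np.ones(len(X)), X[:, idx]])
            ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
            rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
            oracle = np.corrcoef(ri, rj)[0, 1]
            got = partial_correlation(corr, i, j, S)
            assert got == pytest.approx(oracle, abs=1e-10)

    def test_gaussian_chain_partial_vanishes(self, rng):
        n = 2000
        x = rng.normal(size=n)
        z = 0.8 * x + rng.normal(size=n)
        y = 0.7 * z + rng.normal(size=n)
        corr = np.corrcoef(np.column_stack([x, z, y]), rowvar=False)
        assert abs(partial_correlation(corr, 0, 2, (1,))) < 0.05

    def test_conditioning_set_excludes_endpoints(self, rng):
        corr = np.corrcoef(rng.normal(size=(50, 3)), rowvar=False)
        with pytest.raises(ValueError):
            partial_correlation(corr, 0, 1, (0,))


class TestFisherZ:
    def _ctx(self, corr, n):
        return CIContext(corr=corr, n=n, alpha=0.05, max_cond=3)

    def test_zero_correlation_is_independent(self):
        corr = np.eye(3)
        stat, p, indep = fisher_z_test(self._ctx(corr, 100), 0, 1, ())
        assert stat == 0.0 and p == 1.0 and indep

    def test_closed_form_example(self):
        # rho = 0.5, n = 100, |S| = 1: z = atanh(0.5) = 0.5493,
        # statistic = sqrt(96) * 0.5493 = 5.382, p = 7.3e-8
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.5
        stat, p, indep = fisher_z_test(self._ctx(corr, 100), 0, 1, (2,))
        assert stat == pytest.approx(5.382, abs=0.001)
        assert p == pytest.approx(7.3e-8, rel=0.05)
        assert not indep

    def test_p_monotone_in_correlation(self):
        ps = []
        for rho in (0.05, 0.1, 0.2, 0.4, 0.8):
            corr = np.eye(2)
            corr[0, 1] = corr[1, 0] = rho
            ps.append(fisher_z_test(self._ctx(corr, 200), 0, 1, ())[1])
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_small_sample_rejected(self):
        ctx = CIContext(np.eye(5), n=6, max_cond=1)
        with pytest.raises(ValueError):
            fisher_z_test(ctx, 0, 1, (2, 3, 4))  # n - |S| - 3 = 0
        with pytest.raises(ValueError):
            CIContext(np.eye(5), n=6, max_cond=3)


class TestSkeleton:
    def test_collider_structure(self, rng):
        n = 2000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = a + b + 0.5 * rng.normal(size=n)
        data = pd.DataFrame({"A": a, "B": b, "Y": y})
        skel = learn_skeleton(data)
        assert skel.edges() == [("A", "Y"), ("B", "Y")]
        assert skel.sepsets[frozenset(("A", "B"))] == ()

    def test_chain_screens_off_distal_node(self, rng):
        n = 2000
        a = rng.normal(size=n)
        b = 0.9 * a + 0.5 * rng.normal(size=n)
        y = 0.9 * b + 0.5 * rng.normal(size=n)
        data = pd.DataFrame({"A": a, "B": b, "Y": y})
        skel = learn_skeleton(data)
        assert ("A", "Y") not in skel.edges()
        assert skel.sepsets[frozenset(("A", "Y"))] == ("B",)

    def test_independent_columns_usually_empty(self, rng):
        data = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list("ABC"))
        skel = learn_skeleton(data)
        assert len(skel.edges()) <= 1  # each of 3 edges false-positive w.p. alpha


class TestOrientation:
    def test_collider_oriented(self, rng):
        n = 2000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = a + b + 0.5 * rng.normal(size=n)
        skel = learn_skeleton(pd.DataFrame({"A": a, "B": b, "Y": y}))
        g = orient_v_structures(skel)
        assert g.has_directed("A", "Y") and g.has_directed("B", "Y")

    def test_chain_left_undirected(self, rng):
        n = 2000
        a = rng.normal(size=n)
        b = 0.9 * a + 0.5 * rng.normal(size=n)
        y = 0.9 * b + 0.5 * rng.normal(size=n)
        skel = learn_skeleton(pd.DataFrame({"A": a, "B": b, "Y": y}))
        g = orient_v_structures(skel)
        assert not g.directed_edges
        assert g.has_undirected("A", "B") and g.has_undirected("B", "Y")

    def test_empty_skeleton_empty_cpdag(self):
        skel = learn_skeleton(pd.DataFrame(
            np.random.default_rng(0).normal(size=(500, 2)), columns=["A", "B"]),
            alpha=1e-12)
        g = orient_v_structures(skel)
        assert not g.directed_edges and not g.undirected_edges


class TestMeekRules:
    def test_r1_propagates_into_undirected(self):
        g = CPDAG(["A", "B", "C"])
        g.add_directed("A", "B")
        g.add_undirected("B", "C")
        out = apply_meek_rules(g)
        assert out.has_directed("B", "C")

    def test_r2_closes_directed_chain(self):
        g = CPDAG(["A", "B", "C"])
        g.add_directed("A", "B")
        g.add_directed("B", "C")
        g.add_undirected("A", "C")
        out = apply_meek_rules(g)
        assert out.has_directed("A", "C")

    def test_idempotent_on_closed_graph(self):
        g = CPDAG(["A", "B", "C"])
        g.add_directed("A", "C")
        g.add_directed("B", "C")
        once = apply_meek_rules(g)
        twice = apply_meek_rules(once)
        assert once == twice

    def test_never_creates_cycles(self, rng):
        for seed in range(20):
            dag, nodes = _random_dag(5, 0.5, np.random.default_rng(seed))
            g = cpdag_from_dag(dag, nodes)
            assert not g.has_directed_cycle()


class TestTraitConstraints:
    def test_reverse_edge_deleted(self):
        g = CPDAG(["S", "trait"])
        g.add_directed("trait", "S")
        out = enforce_trait_constraints(g, "trait")
        assert not out.adjacent("S", "trait")

    def test_undirected_trait_edge_oriented_inward(self):
        g = CPDAG(["S", "trait"])
        g.add_undirected("S", "trait")
        out = enforce_trait_constraints(g, "trait")
        assert out.has_directed("S", "trait")

    def test_graph_without_trait_edges_unchanged(self):
        g = CPDAG(["A", "B", "trait"])
        g.add_directed("A", "B")
        out = enforce_trait_constraints(g, "trait")
        assert out == g

    def test_trait_out_degree_zero(self):
        g = CPDAG(["A", "B", "trait"])
        g.add_directed("trait", "A")
        g.add_undirected("trait", "B")
        out = enforce_trait_constraints(g, "trait")
        assert out.out_degree("trait") == 0


class TestAncestralSubgraph:
    def _graph(self):
        g = CPDAG(["A", "B", "C", "D", "trait"])
        g.add_directed("A", "B")
        g.add_directed("B", "trait")
        g.add_directed("C", "D")
        return g

    def test_directed_reachability(self):
        sub = ancestral_subgraph(self._graph(), "trait")
        assert sub.nodes == ["A", "B", "trait"]

    def test_parent_star_fully_retained(self):
        g = CPDAG(["P1", "P2", "P3", "trait"])
        for p in ("P1", "P2", "P3"):
            g.add_directed(p, "trait")
        sub = ancestral_subgraph(g, "trait")
        assert sub.nodes == ["P1", "P2", "P3", "trait"]

    def test_undirected_chain_pruned_by_default(self):
        g = CPDAG(["U", "B", "trait"])
        g.add_undirected("U", "B")
        g.add_directed("B", "trait")
        assert "U" not in ancestral_subgraph(g, "trait").nodes
        assert "U" in ancestral_subgraph(g, "trait",
                                         include_undirected=True).nodes


def _random_dag(n_nodes, p_edge, rng):
    nodes = [f"V{k}" for k in range(n_nodes)]
    order = rng.permutation(n_nodes)
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((nodes[order[i]], nodes[order[j]]))
    return edges, nodes


class TestDSeparation:
    def test_matches_networkx_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            edges, nodes = _random_dag(6, 0.4, rng)
            parents = {v: set() for v in nodes}
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            for u, v in edges:
                parents[v].add(u)
                g.add_edge(u, v)
            for _ in range(10):
                x, y = rng.choice(nodes, size=2, replace=False)
                rest = [v for v in nodes if v not in (x, y)]
                S = list(rng.choice(rest, size=rng.integers(0, 3),
                                    replace=False))
                assert d_separated(parents, x, y, S) == nx.is_d_separator(
                    g, {x}, {y}, set(S))

    def test_basic_patterns(self):
        parents = {"A": set(), "B": {"A"}, "C": {"B"}}
        assert d_separated(parents, "A", "C", {"B"})
        assert not d_separated(parents, "A", "C", set())
        collider = {"A": set(), "B": set(), "C": {"A", "B"}}
        assert d_separated(collider, "A", "B", set())
        assert not d_separated(collider, "A", "B", {"C"})


class TestLearnGraphEndToEnd:
    def test_oracle_recovery_of_known_cpdag(self):
        # hub pair -> shared mediators -> trait, plus two direct parents
        edges = [("H1", "M1"), ("H2", "M1"), ("H1", "M2"), ("H2", "M2"),
                 ("M1", "trait"), ("M2", "trait"), ("P1", "trait"),
                 ("P2", "trait")]
        nodes = sorted({u for e in edges for u in e})
        ci = dsep_ci_test(edges, nodes)
        g = learn_graph(None, "trait", ci_test=ci, nodes=nodes,
                        max_cond=len(nodes) - 2)
        assert g == cpdag_from_dag(edges, nodes)
        assert set(g.parents("trait")) == {"M1", "M2", "P1", "P2"}
        assert g.children("H1") == ["M1", "M2"]

    def test_ld_proxy_screened_off(self, rng):
        n = 2000
        causal = rng.normal(size=n)
        proxy = 0.8 * causal + 0.6 * rng.normal(size=n)  # r ~ 0.8
        trait = 0.8 * causal + rng.normal(size=n)
        data = pd.DataFrame({"causal": causal, "proxy": proxy, "trait": trait})
        g = learn_graph(data, "trait")
        assert not g.adjacent("proxy", "trait")
        assert g.has_directed("causal", "trait") or g.adjacent("causal", "trait")

    def test_pure_noise_leaves_trait_isolated(self, rng):
        data = pd.DataFrame(rng.normal(size=(800, 6)),
                            columns=[f"S{k}" for k in range(5)] + ["trait"])
        g = learn_graph(data, "trait")
        assert len(g.nodes) <= 2  # at most one false parent at alpha=0.05

    def test_column_order_invariance(self, rng):
        n = 1500
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = a + b + rng.normal(size=n)
        data = pd.DataFrame({"A": a, "B": b, "trait": y})
        g1 = learn_graph(data, "trait")
        g2 = learn_graph(data[["B", "trait", "A"]], "trait")
        assert g1 == g2


def test_cpdag_from_dag_matches_manual_cases():
    # chain: fully undirected CPDAG
    g = cpdag_from_dag([("A", "B"), ("B", "C")], ["A", "B", "C"])
    assert not g.directed_edges and len(g.undirected_edges) == 2
    # collider: fully directed
    g = cpdag_from_dag([("A", "C"), ("B", "C")], ["A", "B", "C"])
    assert g.directed_edges == {("A", "C"), ("B", "C")}
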