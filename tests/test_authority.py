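"""Authority flow: transfer matrix, power iteration, CO ranking variants.

The independent oracle for the fixed point is a dense linear solve of
(I − d·A)·r = (1 − d)/|S| · s, which the iterative solver must match.
"""

import numpy as np
import pytest

from clinrank.authority import (AuthorityConfig, CO_VARIANTS,
                                build_transition_matrix, objectrank_solve,
                                objectrank_step, pagerank_global, rank_co)
from clinrank.graph import DataGraph, Edge, Node
from clinrank.text import EmptyBaseSetError, Query, base_set, build_stats

from conftest import random_graph


def dense_fixed_point(graph, s, d):
    """Oracle: solve the stationary equation directly."""
    A = build_transition_matrix(graph).matrix.toarray()
    n = len(graph)
    return np.linalg.solve(np.eye(n) - d * A, (1 - d) / s.sum() * s)


class TestTransitionMatrix:
    def test_single_edge_full_transfer(self):
        g = DataGraph([Node("a", "L"), Node("b", "L")], [Edge("a", "b", "r")])
        A = build_transition_matrix(g)
        expected = np.zeros((2, 2))
        expected[1, 0] = 1.0
        np.testing.assert_array_equal(A.matrix.toarray(), expected)

    def test_two_out_edges_split_evenly(self):
        g = DataGraph(
            [Node(x, "L") for x in "abc"],
            [Edge("a", "b", "r"), Edge("a", "c", "r")],
        )
        col = build_transition_matrix(g).matrix.toarray()[:, 0]
        np.testing.assert_array_equal(col, [0, 0.5, 0.5])

    def test_worked_example_matrix(self, fixture_graph):
        """The 7x7 matrix printed in the documentation's example: nonzero
        rows 2, 6, 7 with entries 0.5 and 1.0 set by source out-degrees."""
        A = build_transition_matrix(fixture_graph).matrix.toarray()
        expected = np.zeros((7, 7))
        expected[1, 2] = 0.5   # v3 -> v2
        expected[5, 2] = 0.5   # v3 -> v6
        expected[5, 3] = 0.5   # v4 -> v6
        expected[5, 4] = 1.0   # v5 -> v6
        expected[6, 0] = 1.0   # v1 -> v7
        expected[6, 3] = 0.5   # v4 -> v7
        expected[6, 5] = 1.0   # v6 -> v7
        np.testing.assert_array_equal(A, expected)

    def test_column_sums_at_most_one(self):
        for seed in range(5):
            g = random_graph(seed, n=20, p=0.2)
            A = build_transition_matrix(g).matrix
            sums = np.asarray(A.sum(axis=0)).ravel()
            assert np.all(sums <= 1 + 1e-12)

    def test_role_rates_scale_entries(self):
        g = DataGraph(
            [Node("a", "L"), Node("b", "L"), Node("c", "L")],
            [Edge("a", "b", "weak"), Edge("a", "c", "strong")],
        )
        cfg = AuthorityConfig(rates={"weak": 0.2})
        A = build_transition_matrix(g, cfg).matrix.toarray()
        assert A[1, 0] == pytest.approx(0.1)   # 0.2 / OutDeg 2
        assert A[2, 0] == pytest.approx(0.5)   # default rate 1

    def test_reverse_edges_add_backward_flow(self):
        g = DataGraph([Node("a", "L"), Node("b", "L")], [Edge("a", "b", "r")])
        A = build_transition_matrix(
            g, AuthorityConfig(reverse_edges=True)
        ).matrix.toarray()
        assert A[1, 0] == 1.0 and A[0, 1] == 1.0

    def test_config_validation(self):
        for bad in (dict(d=0), dict(d=1), dict(epsilon=0), dict(max_iters=0),
                    dict(rates={"r": 2.0})):
            with pytest.raises(ValueError):
                AuthorityConfig(**bad)


class TestStep:
    def test_source_only_component_is_0_05(self, fixture_graph, fixture_stats,
                                           pe_query):
        """v1 has no incoming edges, so after one step at d = 0.85 its
        score is exactly the teleport share (1 − d)/|S| = 0.05,
        independent of the initialization."""
        A = build_transition_matrix(fixture_graph)
        _, s = base_set(pe_query, fixture_graph, fixture_stats)
        for r0 in (s / 3, np.zeros(7), np.full(7, 1 / 7)):
            r1 = objectrank_step(A, s, 0.85, r0)
            assert r1[0] == pytest.approx(0.05, abs=1e-12)

    def test_no_edges_reaches_fixed_point_in_one_step(self):
        g = DataGraph([Node("a", "L", (("t", "x"),)), Node("b", "L")])
        A = build_transition_matrix(g)
        s = np.array([1.0, 0.0])
        for r0 in (np.zeros(2), np.array([0.3, 0.7])):
            np.testing.assert_allclose(
                objectrank_step(A, s, 0.85, r0), [0.15, 0.0]
            )

    def test_empty_base_set_rejected(self, fixture_graph):
        A = build_transition_matrix(fixture_graph)
        with pytest.raises(ValueError, match="base set"):
            objectrank_step(A, np.zeros(7), 0.85, np.zeros(7))


class TestSolve:
    def test_worked_example_converged_scores(self, fixture_graph,
                                             fixture_stats, pe_query):
        """The example's converged authority vector: base-set sources at
        0.05, downstream entities at 0.063 and 0.117 (printed truncated
        to three decimals)."""
        sv = objectrank_solve(fixture_graph, pe_query, stats=fixture_stats)
        assert sv.converged
        expected = [0.05, 0.0, 0.0, 0.05, 0.05, 0.063, 0.117]
        np.testing.assert_allclose(sv.r, expected, atol=1e-3)

    @pytest.mark.parametrize("d", [0.30, 0.85])
    def test_matches_dense_linear_solve(self, d):
        for seed in range(20):
            g = random_graph(seed)
            q = Query(("record",))  # every node matches: S = V
            _, s = base_set(q, g)
            cfg = AuthorityConfig(d=d)
            sv = objectrank_solve(g, q, cfg)
            oracle = dense_fixed_point(g, s, d)
            np.testing.assert_allclose(sv.r, oracle, atol=10 * cfg.epsilon)

    def test_small_d_converges_faster(self):
        g = random_graph(11, n=40, p=0.2)
        q = Query(("alpha",))
        fast = objectrank_solve(g, q, AuthorityConfig(d=0.30))
        slow = objectrank_solve(g, q, AuthorityConfig(d=0.85))
        assert fast.converged and slow.converged
        assert fast.iterations_used < slow.iterations_used

    def test_dangling_base_node_scores_one_minus_d(self):
        g = DataGraph([
            Node("a", "L", (("t", "alpha"),)),
            Node("b", "L", (("t", "beta"),)),
        ], [Edge("b", "a", "r")])
        sv = objectrank_solve(g, Query(("alpha",)), AuthorityConfig(d=0.85))
        assert sv.score("a") == pytest.approx(0.15)

    def test_empty_base_set_signalled(self, fixture_graph):
        with pytest.raises(EmptyBaseSetError):
            objectrank_solve(fixture_graph, Query(("aspirin",)))

    def test_conservation_bound(self):
        for seed in range(5):
            g = random_graph(seed, n=25, p=0.15)
            sv = objectrank_solve(g, Query(("record",)))
            assert np.all(sv.r >= 0)
            assert sv.r.sum() <= 1 + 1e-9

    def test_contraction_of_l1_residuals(self):
        for seed in range(5):
            g = random_graph(seed, n=30, p=0.2)
            sv = objectrank_solve(g, Query(("record",)))
            res = sv.residuals
            for prev, cur in zip(res, res[1:]):
                assert cur <= 0.85 * prev * (1 + 1e-9) + 1e-15

    def test_edge_into_node_never_lowers_its_score(self):
        for seed in range(10):
            g = random_graph(seed, n=15, p=0.15)
            q = Query(("record",))
            before = objectrank_solve(g, q)
            donors = [nid for nid in g.node_ids if before.score(nid) > 0]
            rng = np.random.default_rng(seed)
            target = str(rng.choice(g.node_ids))
            donor = str(rng.choice(donors))
            if donor == target or any(
                e.source == donor and e.target == target for e in g.edges
            ):
                continue
            g2 = DataGraph(g.nodes, list(g.edges) + [Edge(donor, target, "r")])
            after = objectrank_solve(g2, q)
            assert after.score(target) >= before.score(target) - 1e-12


class TestPageRank:
    def test_equals_objectrank_with_full_base_set(self):
        for seed in range(5):
            g = random_graph(seed, n=20, p=0.2)
            pr = pagerank_global(g)
            orank = objectrank_solve(g, Query(("record",)))  # S = V
            np.testing.assert_allclose(pr.r, orank.r, atol=1e-10)

    def test_mutual_pair_symmetric(self):
        g = DataGraph(
            [Node("a", "L", (("t", "x"),)), Node("b", "L", (("t", "x"),))],
            [Edge("a", "b", "r"), Edge("b", "a", "r")],
        )
        pr = pagerank_global(g)
        assert pr.score("a") == pytest.approx(pr.score("b"))

    def test_star_hub_dominates_and_matches_oracle(self):
        leaves = [Node(f"l{i}", "L", (("t", "record"),)) for i in range(6)]
        hub = Node("hub", "L", (("t", "record"),))
        g = DataGraph(leaves + [hub],
                      [Edge(l.id, "hub", "r") for l in leaves])
        pr = pagerank_global(g)
        assert pr.score("hub") > max(pr.score(l.id) for l in leaves)
        oracle = dense_fixed_point(g, np.ones(7), 0.85)
        np.testing.assert_allclose(pr.r, oracle, atol=1e-8)


class TestRankCO:
    def test_flow_reaches_entities_without_keywords(self, fixture_graph,
                                                    pe_query):
        rl = rank_co(pe_query, fixture_graph, "CO085")
        assert {"v6", "v7"} <= set(rl.node_ids)

    def test_co085bm25_excludes_zero_bm25_entities(self, fixture_graph,
                                                   pe_query):
        rl = rank_co(pe_query, fixture_graph, "CO085BM25")
        # v6/v7 have positive authority but no query terms -> product 0
        assert set(rl.node_ids) == {"v1", "v4", "v5"}

    def test_smaller_d_concentrates_on_base_set(self):
        """On a chain base -> a -> b the downstream/midstream score ratio
        shrinks with d (closed form: r(b)/r(a) = d on the chain)."""
        g = DataGraph(
            [Node("base", "L", (("t", "alpha"),)),
             Node("a", "L", (("t", "mid"),)),
             Node("b", "L", (("t", "far"),))],
            [Edge("base", "a", "r"), Edge("a", "b", "r")],
        )
        q = Query(("alpha",))
        ratios = {}
        for variant in ("CO030", "CO085"):
            sv = objectrank_solve(
                g, q, AuthorityConfig(d=CO_VARIANTS[variant])
            )
            ratios[variant] = sv.score("b") / sv.score("a")
            assert ratios[variant] == pytest.approx(CO_VARIANTS[variant],
                                                    abs=1e-9)
        assert ratios["CO030"] < ratios["CO085"]

    def test_unknown_variant_rejected(self, fixture_graph, pe_query):
        with pytest.raises(ValueError):
            rank_co(pe_query, fixture_graph, "CO050")
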