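import itertools
import math

import numpy as np
import pytest

from mcpopgen import (ModelParams, TransitionMatrix, betweenness,
                      bottleneck_threshold, build_transition_matrix,
                      dominant_eigenvector, make_fixture,
                      most_probable_neighbors, most_probable_path,
                      node_probability_summary, percolation)


def brute_force_best_path(a, source, target):
    """Exhaustive search over all simple paths, pruning provably worse
    prefixes; returns (best probability, lexicographically smallest best
    path).  Independent of the Dijkstra implementation."""
    n = a.shape[0]
    best = [0.0, None]

    def rec(node, prob, path, visited):
        if node == target:
            cand = (prob, path)
            if prob > best[0] or (prob == best[0] and
                                  (best[1] is None or path < best[1])):
                best[0], best[1] = prob, list(path)
            return
        order = sorted(range(n), key=lambda i: -a[i, node])
        for nxt in order:
            p = a[nxt, node]
            if p <= 0 or nxt in visited or nxt == node:
                continue
            if prob * p < best[0]:
                continue
            visited.add(nxt)
            path.append(nxt)
            rec(nxt, prob * p, path, visited)
            path.pop()
            visited.remove(nxt)

    rec(source, 1.0, [source], {source})
    return best[0], best[1]


class TestMostProbableNeighbors:
    def test_argmax_column(self):
        m = TransitionMatrix(np.array([[0.1, 0.2, 0.3],
                                       [0.6, 0.5, 0.3],
                                       [0.3, 0.3, 0.4]]))
        sel = most_probable_neighbors(m)
        nb = sel.edges.set_index("from_state")["to_state"]
        assert nb[0] == 1 and nb[1] == 1 and nb[2] == 2

    def test_ties_all_reported(self):
        a = np.array([[0.45, 0.2, 0.3],
                      [0.45, 0.5, 0.3],
                      [0.10, 0.3, 0.4]])
        sel = most_probable_neighbors(TransitionMatrix(a))
        from0 = sel.edges[sel.edges.from_state == 0]
        assert set(from0.to_state) == {0, 1}

    def test_exclude_self_loop(self, model_n5):
        sel = most_probable_neighbors(model_n5, include_self=False)
        assert (sel.edges.from_state != sel.edges.to_state).all()

    def test_model_neighbors_near_hardy_weinberg(self, model_n20):
        """For c=0 the expected next state is the Hardy–Weinberg state at
        the parental allele frequency, i.e. the per-column argmax."""
        a = model_n20.toarray()
        sel = most_probable_neighbors(model_n20)
        for _, row in sel.edges.iterrows():
            col = a[:, int(row.from_state)]
            assert col[int(row.to_state)] == col.max()

    def test_in_degree_counts(self, model_n5):
        sel = most_probable_neighbors(model_n5)
        assert sel.in_degree.sum() == len(sel.edges)


class TestMostProbablePath:
    def test_source_equals_target(self, toy3):
        mpp = most_probable_path(toy3, 1, 1)
        assert mpp.path == [1] and mpp.probability == 1.0

    def test_three_state_toy(self):
        a = np.array([[0.5, 0.5, 0.0],
                      [0.5, 0.0, 0.5],
                      [0.0, 0.5, 0.5]])
        a[:, 0] = [0.3, 0.5, 0.2]
        a[:, 1] = [0.25, 0.25, 0.5]
        a[:, 2] = [0.1, 0.2, 0.7]
        m = TransitionMatrix(a)
        mpp = most_probable_path(m, 0, 2)
        # direct 0->2 has 0.2; 0->1->2 has 0.5*0.5=0.25
        assert mpp.path == [0, 1, 2]
        assert mpp.probability == pytest.approx(0.25)

    def test_cost_consistency(self, toy5):
        mpp = most_probable_path(toy5, 0, 3)
        cost = -sum(math.log(toy5.column(u)[v])
                    for u, v in zip(mpp.path[:-1], mpp.path[1:]))
        assert cost == pytest.approx(-math.log(mpp.probability), abs=1e-10)

    def test_matches_brute_force_on_random_5x5(self):
        for seed in range(30):
            m = make_fixture("random", seed=seed, n=5)
            a = m.toarray()
            for source, target in itertools.permutations(range(5), 2):
                mpp = most_probable_path(m, source, target)
                best_p, best_path = brute_force_best_path(a, source, target)
                assert mpp.probability == pytest.approx(best_p, rel=1e-10)
                assert mpp.path == best_path

    def test_matches_brute_force_on_model_n5(self, model_n5):
        src = model_n5.space.index((5, 0, 0))
        dst = model_n5.space.index((0, 0, 5))
        mpp = most_probable_path(model_n5, src, dst)
        best_p, _ = brute_force_best_path(model_n5.toarray(), src, dst)
        assert mpp.probability == pytest.approx(best_p, rel=1e-10)

    def test_unreachable_error(self):
        a = np.eye(3)
        m = TransitionMatrix(a)
        with pytest.raises(RuntimeError, match="unreachable"):
            most_probable_path(m, 0, 2)


class TestBottleneckAndPercolation:
    def test_min_edge_of_path(self):
        a = np.array([[0.3, 0.25, 0.1],
                      [0.5, 0.25, 0.2],
                      [0.2, 0.5, 0.7]])
        m = TransitionMatrix(a)
        assert bottleneck_threshold(m, 0, 2) == pytest.approx(0.5)

    def test_filter_contains_path_edges(self, toy5):
        mpp = most_probable_path(toy5, 0, 3)
        thr = bottleneck_threshold(toy5, 0, 3)
        sel = percolation(toy5, thr)
        kept = set(zip(sel.edges.from_state, sel.edges.to_state))
        for u, v in zip(mpp.path[:-1], mpp.path[1:]):
            assert (u, v) in kept


class TestBetweenness:
    def test_two_state_chain_has_no_interior(self):
        m = TransitionMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert betweenness(m).tolist() == [0, 0]

    def test_hub_routing(self):
        # all cross traffic between 0 and 2 routes via 1
        a = np.array([[0.58, 0.3, 0.01],
                      [0.40, 0.4, 0.40],
                      [0.02, 0.3, 0.59]])
        m = TransitionMatrix(a)
        counts = betweenness(m)
        assert counts[1] == 2  # paths 0->1->2 and 2->1->0
        assert counts[0] == counts[2] == 0

    def test_matches_brute_force_on_random_matrices(self):
        for seed in range(100):
            m = make_fixture("random", seed=seed, n=5)
            a = m.toarray()
            expected = np.zeros(5, dtype=int)
            for s, t in itertools.permutations(range(5), 2):
                _, path = brute_force_best_path(a, s, t)
                for node in path[1:-1]:
                    expected[node] += 1
            assert betweenness(m).tolist() == expected.tolist()

    def test_disconnected_graph_error(self):
        m = TransitionMatrix(np.eye(4))
        with pytest.raises(RuntimeError, match="not strongly connected"):
            betweenness(m)


class TestNodeSummary:
    def test_stay_plus_out_is_one(self, toy5):
        df = node_probability_summary(toy5)
        assert (df.p_stay + df.p_out).to_numpy() == pytest.approx(np.ones(5))
        assert df.p_stay.to_numpy() == pytest.approx(np.diag(toy5.toarray()))

    def test_uniform_matrix_p_in(self):
        n = 4
        m = TransitionMatrix(np.full((n, n), 1 / n))
        df = node_probability_summary(m, include_in_degree=False)
        assert df.p_in.to_numpy() == pytest.approx(np.full(n, 1 / n))

    def test_p_in_inf_degenerate_weighting(self, toy3):
        v = np.array([0.0, 1.0, 0.0])  # all long-run mass on state 1
        df = node_probability_summary(toy3, v, include_in_degree=False)
        a = toy3.toarray()
        assert df.p_in_inf[0] == pytest.approx(a[0, 1])
        assert df.p_in_inf[2] == pytest.approx(a[2, 1])

    def test_limit_column_matches_eigenvector(self, model_n5):
        v = dominant_eigenvector(model_n5)
        df = node_probability_summary(model_n5, v)
        assert df.p_limit.to_numpy() == pytest.approx(v.v)
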