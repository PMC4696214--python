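"""Network-analytic summaries of a transition matrix.

The duality between a column-stochastic matrix M and a weighted directed
graph (edge j -> i with weight M[i, j]) turns Markov chain questions into
graph questions: the *most probable neighbor* of a state is the nearest
neighbor, the *most probable path* between two states is a shortest path
under the -log transform of the probabilities, and counting most probable
paths through each node gives a betweenness centrality whose high scorers
are the frequent transient states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse import csgraph

from .matrix import TransitionMatrix

__all__ = [
    "EdgeSelection",
    "MostProbablePath",
    "most_probable_neighbors",
    "most_probable_path",
    "bottleneck_threshold",
    "percolation",
    "betweenness",
    "node_probability_summary",
    "arrival_distribution",
]


@dataclass
class EdgeSelection:
    """A selected subset of directed edges (from, to, probability)."""

    edges: pd.DataFrame  # columns: from_state, to_state, probability
    rule: str
    in_degree: np.ndarray | None = None

    def to_tsv(self, path) -> None:
        df = self.edges.copy()
        df["rule"] = self.rule
        df.to_csv(path, sep="\t", index=False)


@dataclass
class MostProbablePath:
    path: list[int]
    probability: float


def _cost_graph(m: TransitionMatrix) -> sp.csr_matrix:
    """Directed graph with edge u -> v of cost -log M[v, u]; self-loops and
    zero probabilities (absent transitions) are excluded.  Probability-one
    edges yield explicit zero-cost entries, which scipy.sparse.csgraph
    treats as real edges."""
    coo = sp.coo_matrix(m.data) if not m.is_sparse else m.data.tocoo()
    keep = (coo.data > 0) & (coo.row != coo.col)
    # matrix entry (i, j) is the edge j -> i
    return sp.csr_matrix(
        (-np.log(coo.data[keep]), (coo.col[keep], coo.row[keep])),
        shape=(m.n, m.n),
    )


def most_probable_neighbors(m: TransitionMatrix,
                            include_self: bool = True) -> EdgeSelection:
    """For every source state, its most likely destination(s) next step.

    All exactly tied maxima are reported.  ``include_self=False`` ignores the
    self-loop (useful around near-absorbing states whose most likely "move"
    is to stay).  The in-degree of each node in the resulting graph counts
    how many states it is the most probable neighbor of.
    """
    n = m.n
    src, dst, prob = [], [], []
    in_degree = np.zeros(n, dtype=np.int64)
    for j in range(n):
        col = m.column(j)
        if not include_self:
            col = col.copy()
            col[j] = -np.inf
        best = col.max()
        for i in np.flatnonzero(col == best):
            src.append(j)
            dst.append(int(i))
            prob.append(m.column(j)[i])
            in_degree[i] += 1
    edges = pd.DataFrame(
        {"from_state": src, "to_state": dst, "probability": prob}
    )
    rule = "most_probable_neighbor" + ("" if include_self else "_no_self")
    return EdgeSelection(edges=edges, rule=rule, in_degree=in_degree)


def _lex_greedy_path(graph: sp.csr_matrix, dist_to_target: np.ndarray,
                     source: int, target: int, total: float) -> list[int]:
    """Walk the shortest-path DAG from source, choosing the smallest-index
    next node at every step: the lexicographically smallest optimal path."""
    tol = 1e-9 * (1.0 + abs(total))
    path = [source]
    visited = {source}
    cur = source
    cost = 0.0
    indptr, indices, data = graph.indptr, graph.indices, graph.data
    while cur != target:
        lo, hi = indptr[cur], indptr[cur + 1]
        best_w, best_c = -1, 0.0
        for w, c in zip(indices[lo:hi], data[lo:hi]):
            if w in visited:
                continue
            if cost + c + dist_to_target[w] <= total + tol:
                if best_w == -1 or w < best_w:
                    best_w, best_c = int(w), float(c)
        if best_w == -1:
            raise RuntimeError(
                f"path reconstruction stalled at state {cur} (numerical ties?)"
            )
        path.append(best_w)
        visited.add(best_w)
        cost += best_c
        cur = best_w
    return path


def _path_probability(m: TransitionMatrix, path: list[int]) -> float:
    p = 1.0
    for u, v in zip(path[:-1], path[1:]):
        p *= m.column(u)[v]
    return p


def most_probable_path(m: TransitionMatrix, source: int,
                       target: int) -> MostProbablePath:
    """State sequence maximizing the product of transition probabilities.

    Found by Dijkstra's algorithm on edge costs -log M[i, j] (all
    non-negative); among tied optima the lexicographically smallest state
    sequence is returned.  Self-loops never appear as interior steps.
    """
    if source == target:
        return MostProbablePath(path=[int(source)], probability=1.0)
    graph = _cost_graph(m)
    dist_t = csgraph.dijkstra(graph.T, directed=True, indices=target)
    total = dist_t[source]
    if not np.isfinite(total):
        raise RuntimeError(
            f"state {target} is unreachable from state {source} "
            "(no positive-probability path)"
        )
    path = _lex_greedy_path(graph, dist_t, int(source), int(target), float(total))
    return MostProbablePath(path=path, probability=_path_probability(m, path))


def bottleneck_threshold(m: TransitionMatrix, source: int, target: int) -> float:
    """Smallest transition probability along the most probable path."""
    mpp = most_probable_path(m, source, target)
    return min(m.column(u)[v] for u, v in zip(mpp.path[:-1], mpp.path[1:]))


def percolation(m: TransitionMatrix, threshold: float) -> EdgeSelection:
    """All directed edges with probability >= threshold (flow filter)."""
    coo = sp.coo_matrix(m.data) if not m.is_sparse else m.data.tocoo()
    keep = coo.data >= threshold
    edges = pd.DataFrame(
        {
            "from_state": coo.col[keep],
            "to_state": coo.row[keep],
            "probability": coo.data[keep],
        }
    ).sort_values(["from_state", "to_state"], ignore_index=True)
    return EdgeSelection(edges=edges, rule=f"percolation>={threshold:g}")


def betweenness(m: TransitionMatrix) -> np.ndarray:
    """Number of most probable paths passing through each node.

    All ordered pairs (i, j), i != j, are considered; each contributes its
    single tie-broken most probable path, and every interior node of that
    path is credited once.  Endpoints are never counted for their own pair.
    """
    n = m.n
    graph = _cost_graph(m)
    dist = csgraph.dijkstra(graph, directed=True)
    bad = ~np.isfinite(dist)
    np.fill_diagonal(bad, False)
    if bad.any():
        pairs = np.argwhere(bad)[:10]
        raise RuntimeError(
            f"graph is not strongly connected; unreachable pairs include "
            f"{[tuple(p) for p in pairs]}"
        )
    counts = np.zeros(n, dtype=np.int64)
    for t in range(n):
        dist_t = dist[:, t]
        for s in range(n):
            if s == t:
                continue
            path = _lex_greedy_path(graph, dist_t, s, t, float(dist_t[s]))
            for node in path[1:-1]:
                counts[node] += 1
    return counts


def arrival_distribution(m: TransitionMatrix, j: int) -> np.ndarray:
    """p(i|j): the probability distribution of destinations from state j
    (column j of the matrix)."""
    return m.column(j)


def node_probability_summary(m: TransitionMatrix, v=None,
                             include_in_degree: bool = True) -> pd.DataFrame:
    """Per-state probability summaries of transient and limiting behavior.

    Columns: ``p_stay`` (diagonal, probability to remain), ``p_out``
    (1 - p_stay), ``p_in`` (mean inbound probability over the other states),
    and, when a limiting distribution ``v`` is supplied, ``p_in_inf``
    (inbound probability under the limiting distribution of sources) and
    ``p_limit`` (the limiting distribution itself).  ``mpn_in_degree`` is
    the in-degree in the most-probable-neighbor graph.
    """
    n = m.n
    diag = m.diagonal()
    row_sums = np.asarray(m.data.sum(axis=1)).ravel()
    out = {
        "p_stay": diag,
        "p_out": 1.0 - diag,
        "p_in": (row_sums - diag) / (n - 1),
    }
    if v is not None:
        vec = np.asarray(getattr(v, "v", v), dtype=float)
        out["p_in_inf"] = m.matvec(vec) - diag * vec
        out["p_limit"] = vec
    if include_in_degree:
        out["mpn_in_degree"] = most_probable_neighbors(m).in_degree
    return pd.DataFrame(out)
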