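"""Structure-preserving sparse approximation of a dense stochastic matrix.

Each column of a left-stochastic matrix is a probability distribution; the
approximation keeps, per column, the smallest set of largest entries whose
mass reaches a threshold s and rounds the rest to zero — except that the
main diagonal entry (aperiodicity) and the wrap-around sub- and
super-diagonal entries (a Hamiltonian cycle through all states, hence
irreducibility) are always retained when present in the original.  Kept
entries are rescaled so the column sums to one again.

The per-column procedure:

1. rank entries by decreasing value, ties by ascending row index;
2. r = minimal rank whose cumulative sum reaches s;
3. keep at least the two biggest values (r = max(2, r));
4. extend r while the next-ranked value ties the r-th;
5. zero all entries ranked beyond r except rows {(i-1, i, i+1) mod n};
6. rescale the column to sum to one.

The total absolute perturbation before rescaling is bounded by (1-s)*|S|;
after rescaling each column moves by at most 2*(1-s) in L1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import TransitionMatrix

__all__ = ["SparseColumn", "ApproxReport", "approximate_column",
           "approximate_matrix", "density"]


@dataclass
class SparseColumn:
    """Kept entries of one approximated column, rescaled to sum to one."""

    index: int
    rows: np.ndarray
    values: np.ndarray
    discarded: float  # probability mass zeroed before rescaling


@dataclass
class ApproxReport:
    """Per-column accounting of a matrix approximation run."""

    s: float
    n: int
    discarded: np.ndarray = field(default_factory=lambda: np.empty(0))
    density: float = float("nan")

    @property
    def max_discarded(self) -> float:
        return float(self.discarded.max()) if self.discarded.size else 0.0

    @property
    def total_discarded(self) -> float:
        """Total pre-rescale perturbation; bounded by (1-s)*n."""
        return float(self.discarded.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": np.arange(self.n), "discarded_mass": self.discarded}
        )


def approximate_column(column: np.ndarray, i: int, s: float,
                       n: int | None = None) -> SparseColumn:
    """Apply the six-step thresholding procedure to one column.

    ``i`` is the column's index in the matrix (needed for the protected
    diagonal rows), ``n`` the matrix dimension (defaults to the column
    length).  Protected rows are only retained if nonzero in the original:
    the procedure never creates entries.
    """
    col = np.asarray(column, dtype=float)
    if n is None:
        n = col.size
    if col.size != n:
        raise ValueError(f"column length {col.size} != matrix dimension {n}")
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"threshold s must be in [0, 1], got {s}")
    if abs(col.sum() - 1.0) > 1e-9:
        raise ValueError(f"column {i} is not normalized (sum {col.sum()!r})")

    # step 1: stable ranking by decreasing value, ties by ascending row index
    order = np.argsort(-col, kind="stable")
    ranked = col[order]

    # step 2: minimal rank whose cumulative sum reaches s (all if never reached)
    csum = np.cumsum(ranked)
    hit = np.searchsorted(csum, s, side="left")
    r = min(int(hit) + 1, n)  # number of kept ranks, 1-based

    # step 3: keep at least the two biggest values
    r = min(max(2, r), n)

    # step 4: keep all values of equal rank
    while r < n and ranked[r] == ranked[r - 1]:
        r += 1

    if r == n:  # nothing dropped; column unchanged
        rows = np.flatnonzero(col)
        return SparseColumn(i, rows, col[rows], 0.0)

    # step 5: zero beyond rank r, protecting existing tri-diagonal (mod n) rows
    keep = np.zeros(n, dtype=bool)
    keep[order[:r]] = True
    for prot in ((i - 1) % n, i % n, (i + 1) % n):
        if col[prot] > 0.0:
            keep[prot] = True

    kept_mass = col[keep].sum()
    discarded = float(col.sum() - kept_mass)

    # step 6: rescale kept entries to sum to one
    rows = np.flatnonzero(keep & (col > 0.0))
    values = col[rows] / kept_mass
    return SparseColumn(i, rows, values, discarded)


def approximate_matrix(source, s: float,
                       space=None) -> tuple[TransitionMatrix, ApproxReport]:
    """Approximate every column of a matrix; return (sparse matrix, report).

    ``source`` may be a :class:`TransitionMatrix` or any iterable of dense
    probability columns (e.g. :func:`mcpopgen.model.column_generator`), in
    which case the full dense matrix is never held in memory.  Column errors
    are re-raised with the offending column index attached.
    """
    if isinstance(source, TransitionMatrix):
        if space is None:
            space = source.space
        cols = source.columns()
    else:
        cols = iter(source)

    rows_acc: list[np.ndarray] = []
    data_acc: list[np.ndarray] = []
    indptr = [0]
    discarded: list[float] = []
    n = None
    for i, col in enumerate(cols):
        col = np.asarray(col, dtype=float)
        if n is None:
            n = col.size
        try:
            sc = approximate_column(col, i, s, n)
        except ValueError as exc:
            raise ValueError(f"column {i}: {exc}") from exc
        rows_acc.append(sc.rows)
        data_acc.append(sc.values)
        indptr.append(indptr[-1] + sc.rows.size)
        discarded.append(sc.discarded)
    if n is None:
        raise ValueError("source yielded no columns")
    if len(discarded) != n:
        raise ValueError(f"source yielded {len(discarded)} columns for dimension {n}")

    mat = sp.csc_matrix(
        (np.concatenate(data_acc), np.concatenate(rows_acc), np.array(indptr)),
        shape=(n, n),
    )
    tm = TransitionMatrix(mat, space=space, validate=False)
    report = ApproxReport(s=s, n=n, discarded=np.array(discarded), density=tm.density)
    return tm, report


def density(m: TransitionMatrix) -> float:
    """Fraction of stored nonzero entries (nnz / |S|^2)."""
    return m.density
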