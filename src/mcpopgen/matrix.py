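"""Column-stochastic transition matrix container.

The convention throughout the package is *left-stochastic* (column)
storage: entry ``(i, j)`` is the probability of a one-step transition FROM
state ``j`` TO state ``i``, so every column sums to one.  The container
wraps either a dense ndarray or a scipy CSC matrix and optionally carries
the :class:`~mcpopgen.statespace.StateSpace` its rows/columns are indexed
by.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .statespace import StateSpace

__all__ = ["TransitionMatrix"]


class TransitionMatrix:
    """Square column-stochastic matrix, dense or sparse."""

    def __init__(self, data, space: StateSpace | None = None, validate: bool = True):
        if sp.issparse(data):
            data = data.tocsc()
        else:
            data = np.asarray(data, dtype=float)
            if data.ndim != 2:
                raise ValueError(f"matrix must be 2-D, got shape {data.shape}")
        if data.shape[0] != data.shape[1]:
            raise ValueError(f"matrix must be square, got shape {data.shape}")
        if space is not None and len(space) != data.shape[0]:
            raise ValueError(
                f"state space has {len(space)} states but matrix is {data.shape[0]}x{data.shape[1]}"
            )
        self.data = data
        self.space = space
        if validate:
            self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.data)

    @property
    def density(self) -> float:
        """Fraction of stored nonzero entries, nnz / n^2."""
        if self.is_sparse:
            nnz = self.data.count_nonzero()
        else:
            nnz = int(np.count_nonzero(self.data))
        return nnz / float(self.n) ** 2

    # -- access ---------------------------------------------------------
    def column(self, j: int) -> np.ndarray:
        """Dense copy of column j (out-transition distribution of state j)."""
        if self.is_sparse:
            return np.asarray(self.data[:, [j]].todense()).ravel()
        return self.data[:, j].copy()

    def columns(self):
        """Iterate dense columns in order (streaming-friendly)."""
        for j in range(self.n):
            yield self.column(j)

    def diagonal(self) -> np.ndarray:
        if self.is_sparse:
            return self.data.diagonal()
        return np.diag(self.data).copy()

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.data.sum(axis=0)).ravel()

    def toarray(self) -> np.ndarray:
        if self.is_sparse:
            return self.data.toarray()
        return self.data

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(self.data @ v).ravel()

    # -- validation -----------------------------------------------------
    def validate(self, warn_tol: float = 1e-6, fail_tol: float = 1e-3) -> None:
        """Check entry range and column sums.

        Deviations of a column sum from 1 beyond ``fail_tol`` raise; beyond
        ``warn_tol`` they warn (useful when reading matrices written with
        limited precision).
        """
        if self.is_sparse:
            vals = self.data.data
        else:
            vals = self.data
        if vals.size and (np.min(vals) < -1e-12 or np.max(vals) > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        dev = np.abs(self.column_sums() - 1.0)
        worst = float(dev.max()) if dev.size else 0.0
        if worst > fail_tol:
            raise ValueError(
                f"column sums deviate from 1 by up to {worst:.3g} (> {fail_tol:g})"
            )
        if worst > warn_tol:
            warnings.warn(
                f"column sums deviate from 1 by up to {worst:.3g}", stacklevel=2
            )

    def __repr__(self) -> str:
        kind = "sparse" if self.is_sparse else "dense"
        return f"TransitionMatrix(n={self.n}, {kind}, density={self.density:.4g})"
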