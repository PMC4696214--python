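"""Limiting distribution and expected first-passage times.

For an irreducible, aperiodic, column-stochastic matrix M the limiting
distribution is the unique normalized right eigenvector v of eigenvalue 1
(M v = v); it gives the long-run occupancy probability of every state.
Expected first-passage times to a target set follow from the fundamental
matrix of the chain with the targets made absorbing: t (I - M') = 1 where
M' is the sub-matrix over non-target states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .matrix import TransitionMatrix

__all__ = ["LimitingDistribution", "PassageTimes", "dominant_eigenvector",
           "first_passage_times"]

#: default residual tolerance ||Mv - v||_1 accepted for a returned eigenvector
RESIDUAL_TOL = 1e-8


@dataclass
class LimitingDistribution:
    """Normalized dominant right eigenvector of a transition matrix."""

    v: np.ndarray
    residual: float
    space: object | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": np.arange(self.v.size), "value": self.v})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PassageTimes:
    """Expected steps (generations) to first reach the target set."""

    times: np.ndarray
    targets: np.ndarray
    space: object | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": np.arange(self.times.size), "time": self.times})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _power_iteration(m: TransitionMatrix, tol_change: float = 1e-13,
                     tol_residual: float = 1e-10, maxiter: int = 10**6) -> np.ndarray:
    v = np.full(m.n, 1.0 / m.n)
    for _ in range(maxiter):
        w = m.matvec(v)
        w /= w.sum()
        change = np.abs(w - v).sum()
        v = w
        if change < tol_change:
            return v
        if change < 1e-6:  # residual check is O(n^2); only try when close
            if np.abs(m.matvec(v) - v).sum() < tol_residual:
                return v
    residual = float(np.abs(m.matvec(v) - v).sum())
    raise RuntimeError(
        f"power iteration did not converge in {maxiter} steps (residual {residual:.3g})"
    )


def dominant_eigenvector(m: TransitionMatrix, method: str = "auto",
                         residual_tol: float = RESIDUAL_TOL,
                         maxiter: int = 10**6) -> LimitingDistribution:
    """Normalized right eigenvector of eigenvalue 1 (limiting distribution).

    methods: "arpack" (implicitly restarted Arnoldi, the default for n >= 3),
    "dense" (full eigendecomposition, small matrices), "power" (plain power
    iteration).  The same code path serves dense and sparse storage.  The
    result is validated: eigenvalue within 1e-6 of 1, entries non-negative,
    residual ||Mv - v||_1 below ``residual_tol``; a reducible chain (e.g.
    mu = 0 with absorbing fixation states, where the eigenvalue is not
    simple) typically fails these checks and is refused.
    """
    n = m.n
    if method == "auto":
        method = "arpack" if n >= 3 else "dense"

    if method == "power":
        v = _power_iteration(m, maxiter=maxiter)
    elif method == "dense":
        w, vecs = scipy.linalg.eig(m.toarray())
        k = int(np.argmin(np.abs(w - 1.0)))
        if abs(w[k] - 1.0) > 1e-6:
            raise RuntimeError(f"no eigenvalue near 1 (closest {w[k]!r})")
        v = vecs[:, k]
    elif method == "arpack":
        op = m.data if m.is_sparse else np.asarray(m.data)
        try:
            w, vecs = spla.eigs(op, k=1, which="LM", v0=np.full(n, 1.0 / n),
                                maxiter=maxiter, tol=0)
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(f"Arnoldi iteration did not converge: {exc}") from exc
        if abs(w[0] - 1.0) > 1e-6:
            raise RuntimeError(f"dominant eigenvalue {w[0]!r} is not 1; "
                               "matrix may not be column-stochastic")
        v = vecs[:, 0]
    else:
        raise ValueError(f"unknown method {method!r}")

    if np.abs(v.imag).max() > 1e-10 * np.abs(v.real).max():
        raise RuntimeError("dominant eigenvector is not real; eigenvalue 1 "
                           "may not be simple (reducible chain?)")
    v = v.real
    if v.sum() < 0:
        v = -v
    if v.min() < -1e-8 * v.max():
        raise RuntimeError(
            "dominant eigenvector has negative entries; eigenvalue 1 is "
            "likely not simple (chain reducible, e.g. mu = 0)"
        )
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    residual = float(np.abs(m.matvec(v) - v).sum())
    if residual > residual_tol:
        raise RuntimeError(
            f"eigenvector residual ||Mv - v||_1 = {residual:.3g} exceeds "
            f"{residual_tol:g}; chain may be reducible or ill-conditioned"
        )
    return LimitingDistribution(v=v, residual=residual, space=m.space)


def first_passage_times(m: TransitionMatrix, targets) -> PassageTimes:
    """Expected first-passage times to the target state set, per start state.

    Solves t (I - M') = 1 over the non-target states (column convention);
    target states get time 0.
    """
    targets = np.atleast_1d(np.asarray(targets, dtype=np.intp))
    if targets.size == 0:
        raise ValueError("target set must be non-empty")
    n = m.n
    mask = np.ones(n, dtype=bool)
    mask[targets] = False
    non = np.flatnonzero(mask)
    times = np.zeros(n)
    if non.size:
        if m.is_sparse:
            sub = m.data[non][:, non]
            a = (sp.identity(non.size, format="csc") - sub).T.tocsc()
            try:
                t = spla.spsolve(a, np.ones(non.size))
            except RuntimeError as exc:  # singular factorization
                raise RuntimeError(f"I - M' is singular; targets unreachable? {exc}")
        else:
            sub = m.data[np.ix_(non, non)]
            a = (np.eye(non.size) - sub).T
            try:
                t = scipy.linalg.solve(a, np.ones(non.size))
            except scipy.linalg.LinAlgError as exc:
                raise RuntimeError(f"I - M' is singular; targets unreachable? {exc}")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise RuntimeError(
                "first-passage solve produced non-positive or non-finite times; "
                "targets may be unreachable from some states"
            )
        times[non] = t
    return PassageTimes(times=times, targets=targets, space=m.space)
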