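"""Matrix/vector I/O and deterministic test fixtures.

Interchange formats: Matrix Market (array format for dense, coordinate
format with the standard 1-based on-disk indices for sparse) and plain TSV
for small dense matrices, vectors and tables.  Column sums are validated on
read: deviations beyond 1e-6 warn, beyond 1e-3 fail.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import TransitionMatrix
from .model import ModelParams, build_transition_matrix
from .statespace import StateSpace

__all__ = ["read_matrix", "write_matrix", "read_vector", "write_vector",
           "make_fixture"]


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".mtx", ".mm"):
        return "matrix-market"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer matrix format from {path!r}; pass fmt=")


def read_matrix(path, fmt: str | None = None,
                space: StateSpace | None = None) -> TransitionMatrix:
    """Read a column-stochastic matrix from Matrix Market or dense TSV."""
    fmt = _infer_format(path, fmt)
    if fmt == "matrix-market":
        try:
            data = scipy.io.mmread(path)
        except ValueError as exc:
            raise ValueError(f"malformed Matrix Market file {path!r}: {exc}") from exc
    elif fmt == "tsv":
        try:
            data = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"malformed TSV matrix file {path!r}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return TransitionMatrix(data, space=space)


def write_matrix(m: TransitionMatrix, path, fmt: str | None = None) -> None:
    """Write Matrix Market (coordinate if sparse, array if dense) or TSV."""
    fmt = _infer_format(path, fmt)
    if fmt == "matrix-market":
        scipy.io.mmwrite(path, m.data)
    elif fmt == "tsv":
        np.savetxt(path, m.toarray(), delimiter="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_vector(path) -> np.ndarray:
    """Read a vector TSV with columns (index, value), ordered by index."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.sort_values(df.columns[0])[df.columns[1]].to_numpy(dtype=float)


def write_vector(v, path, value_name: str = "value") -> None:
    vec = np.asarray(getattr(v, "v", v), dtype=float)
    pd.DataFrame({"index": np.arange(vec.size), value_name: vec}).to_csv(
        path, sep="\t", index=False
    )


# fixed toy chains reused across the test suite and documentation
_TOY3 = np.array(
    [
        [0.5, 0.3, 0.2],
        [0.3, 0.5, 0.3],
        [0.2, 0.2, 0.5],
    ]
)

_TOY5 = np.array(
    [
        [0.60, 0.10, 0.05, 0.05, 0.10],
        [0.20, 0.50, 0.15, 0.05, 0.10],
        [0.10, 0.20, 0.50, 0.10, 0.10],
        [0.05, 0.10, 0.20, 0.60, 0.20],
        [0.05, 0.10, 0.10, 0.20, 0.50],
    ]
)


def make_fixture(kind: str, seed: int = 0, n: int = 5, N: int = 5,
                 mu: float = 1e-6, c: float = 0.0) -> TransitionMatrix:
    """Deterministic small column-stochastic matrices for tests and demos.

    kinds: ``toy3``/``toy5`` fixed matrices; ``random`` seeded strictly
    positive column-normalized matrix of size ``n``; ``model`` the
    genotype-frequency model matrix for (N, mu, c).
    """
    if kind == "toy3":
        return TransitionMatrix(_TOY3.copy())
    if kind == "toy5":
        return TransitionMatrix(_TOY5.copy())
    if kind == "random":
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.05, 1.0, size=(n, n))
        return TransitionMatrix(m / m.sum(axis=0))
    if kind == "model":
        return build_transition_matrix(ModelParams(N=N, mu=mu, c=c))
    raise ValueError(f"unknown fixture kind {kind!r}")
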