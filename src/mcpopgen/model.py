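"""Wright–Fisher genotype-frequency model with partial clonality.

One locus, two alleles (a, A), constant population size N of diploid
individuals.  Each offspring is produced clonally with probability c (a
uniformly chosen parent is copied, each of its two alleles mutating
independently with probability mu) and sexually with probability 1 - c
(random union of two gametes drawn from the parental allele pool, each
gamete mutating with probability mu).  The N offspring are drawn
independently, so one column of the transition matrix is a multinomial
distribution over genotype-count states.

The resulting column-stochastic matrix is dense (density one for mu > 0),
irreducible and aperiodic, and partially symmetric under the allele-swap
permutation because mutation is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .matrix import TransitionMatrix
from .statespace import GenotypeState, StateSpace, state_count

__all__ = [
    "ModelParams",
    "mutation_kernel",
    "offspring_distribution",
    "transition_column",
    "column_generator",
    "build_transition_matrix",
]

#: refuse dense materialization beyond this state count (memory grows as |S|^2)
DEFAULT_MAX_DENSE_STATES = 8000


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the partially clonal Wright–Fisher genotype model.

    N
        population size (individuals), N >= 1.
    mu
        symmetric per-allele mutation probability per generation, in [0, 0.5].
    c
        probability that an offspring is produced clonally, in [0, 1].
    clonal_mutation
        whether mutation also acts on clonally produced offspring (default
        True; required for the matrix to have density one for every c).
    """

    N: int
    mu: float
    c: float = 0.0
    clonal_mutation: bool = True

    def __post_init__(self):
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not 0.0 <= self.mu <= 0.5:
            raise ValueError(f"mu must be in [0, 0.5], got {self.mu}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must be in [0, 1], got {self.c}")


def mutation_kernel(mu: float) -> np.ndarray:
    """Per-genotype two-allele mutation kernel Q (column-stochastic, 3x3).

    Column j holds the genotype distribution of a copy of parent genotype j
    after each allele mutated independently with probability mu; genotype
    order (aa, aA, AA).
    """
    m, w = mu, 1.0 - mu
    return np.array(
        [
            [w * w, m * w, m * m],
            [2 * m * w, w * w + m * m, 2 * m * w],
            [m * m, m * w, w * w],
        ]
    )


def offspring_distribution(parent, params: ModelParams) -> np.ndarray:
    """Genotype distribution pi of a single offspring of the given parent state.

    pi = c * pi_clonal + (1 - c) * pi_sexual where pi_sexual is the
    Hardy–Weinberg distribution at the mutated parental allele frequency and
    pi_clonal copies a uniformly chosen parent through the mutation kernel.
    """
    s = GenotypeState(*parent)
    N = params.N
    if s.N != N:
        raise ValueError(f"parent counts {tuple(s)} do not sum to N={N}")
    geno_freq = np.array([s.n_aa, s.n_aA, s.n_AA], dtype=float) / N

    nu_a = geno_freq[0] + 0.5 * geno_freq[1]
    nu_m = nu_a * (1.0 - params.mu) + (1.0 - nu_a) * params.mu
    pi_sex = np.array([nu_m**2, 2.0 * nu_m * (1.0 - nu_m), (1.0 - nu_m) ** 2])

    if params.clonal_mutation:
        pi_clo = mutation_kernel(params.mu) @ geno_freq
    else:
        pi_clo = geno_freq
    return params.c * pi_clo + (1.0 - params.c) * pi_sex


class _ColumnKernel:
    """Precomputed multinomial log-pmf machinery for one state space."""

    def __init__(self, space: StateSpace):
        self.space = space
        self.counts = space.counts.astype(float)
        # log N! - sum_k log n_k!  per state, exact up to gammaln accuracy
        self.log_coeff = gammaln(space.N + 1) - gammaln(self.counts + 1).sum(axis=1)

    def column(self, pi: np.ndarray) -> np.ndarray:
        """Multinomial pmf over all states for offspring distribution pi."""
        pos = pi > 0.0
        logp = self.log_coeff + self.counts[:, pos] @ np.log(pi[pos])
        col = np.exp(logp)
        if not pos.all():
            # states requiring a zero-probability genotype are unreachable
            col[(self.space.counts[:, ~pos] > 0).any(axis=1)] = 0.0
        return col


def transition_column(params: ModelParams, space: StateSpace, j: int,
                      _kernel: _ColumnKernel | None = None) -> np.ndarray:
    """Column j of the transition matrix (probabilities of all destinations)."""
    kern = _kernel if _kernel is not None else _ColumnKernel(space)
    return kern.column(offspring_distribution(space[j], params))


def column_generator(params: ModelParams, space: StateSpace | None = None):
    """Yield the transition-matrix columns one at a time.

    Deterministic and stateless per column; lets downstream consumers (e.g.
    the sparse approximation) process the matrix without ever storing it
    densely.
    """
    if space is None:
        space = StateSpace(params.N)
    kern = _ColumnKernel(space)
    for state in space:
        yield kern.column(offspring_distribution(state, params))


def build_transition_matrix(params: ModelParams, space: StateSpace | None = None,
                            max_states: int = DEFAULT_MAX_DENSE_STATES) -> TransitionMatrix:
    """Materialize the dense column-stochastic transition matrix.

    Raises a capacity error (reporting the computed |S|) when the state
    space exceeds ``max_states``; use :func:`column_generator` together with
    the streaming sparse approximation for larger systems.
    """
    n_states = state_count(params.N, 3)
    if n_states > max_states:
        raise MemoryError(
            f"dense materialization refused: |S| = {n_states} states for N={params.N} "
            f"exceeds max_states={max_states}; use column_generator() instead"
        )
    if space is None:
        space = StateSpace(params.N)
    m = np.empty((n_states, n_states))
    for j, col in enumerate(column_generator(params, space)):
        m[:, j] = col
    return TransitionMatrix(m, space=space, validate=False)
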