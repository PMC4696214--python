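"""Genotype-count state spaces for finite-population Markov chain models.

A population of ``N`` diploid individuals at one biallelic locus is described
by the counts of the three genotypes ``(n_aa, n_aA, n_AA)``.  Every
assignment of the ``N`` individuals to the three genotypes is one state of
the Markov chain; the state space is the set of all weak compositions of
``N`` into three parts.  This module enumerates and indexes that state
space, computes its cardinality for general genomic systems (ploidy, loci,
alleles per locus), exposes the allele-swap symmetry of the model, and maps
states into de Finetti (ternary) coordinates for plotting.
"""

from __future__ import annotations

import math
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeState",
    "GenomeConfig",
    "StateSpace",
    "genotype_count",
    "state_count",
    "enumerate_states",
    "allele_swap_permutation",
    "allele_swap_paired_order",
    "definetti_coords",
]

_SQRT3_2 = math.sqrt(3.0) / 2.0


class GenotypeState(NamedTuple):
    """Counts of the three genotypes at a biallelic diploid locus."""

    n_aa: int
    n_aA: int
    n_AA: int

    @property
    def N(self) -> int:
        return self.n_aa + self.n_aA + self.n_AA

    def swapped(self) -> "GenotypeState":
        """The state obtained by renaming allele a <-> A."""
        return GenotypeState(self.n_AA, self.n_aA, self.n_aa)


class GenomeConfig(NamedTuple):
    """Genomic system: ploidy level and number of alleles per locus."""

    ploidy: int
    alleles: tuple[int, ...]


def genotype_count(config: GenomeConfig | None = None, *, ploidy: int | None = None,
                   alleles=None) -> int:
    """Number of distinct genotypes g for a given genomic system.

    Each locus with A alleles at ploidy P contributes the multiset
    coefficient C(A + P - 1, P); loci multiply.  Exact integer arithmetic.
    """
    if config is not None:
        ploidy, alleles = config.ploidy, config.alleles
    if ploidy is None or alleles is None:
        raise TypeError("genotype_count needs a GenomeConfig or ploidy= and alleles=")
    if ploidy < 1:
        raise ValueError(f"ploidy must be >= 1, got {ploidy}")
    g = 1
    for a in alleles:
        if a < 1:
            raise ValueError(f"allele counts must be >= 1, got {a}")
        g *= math.comb(a + ploidy - 1, ploidy)
    return g


def state_count(N: int, g: int) -> int:
    """Cardinality of the state space: weak compositions of N into g parts.

    |S| = C(N + g - 1, N).  Exact integers; values beyond 10^20 occur for
    realistic multi-locus systems and must not be rounded.
    """
    if N < 0:
        raise ValueError(f"population size must be >= 0, got {N}")
    if g < 1:
        raise ValueError(f"genotype count must be >= 1, got {g}")
    return math.comb(N + g - 1, N)


class StateSpace:
    """Ordered enumeration of all genotype-count states for fixed N.

    Canonical order is lexicographically descending in (n_aa, n_aA):
    (N,0,0) first, (0,0,N) last.
    """

    def __init__(self, N: int):
        if N < 1:
            raise ValueError(f"population size must be >= 1, got {N}")
        self.N = int(N)
        states = []
        for n_aa in range(N, -1, -1):
            for n_aA in range(N - n_aa, -1, -1):
                states.append(GenotypeState(n_aa, n_aA, N - n_aa - n_aA))
        self.states: tuple[GenotypeState, ...] = tuple(states)
        self._index = {s: i for i, s in enumerate(states)}
        # counts as an int array, one row per state
        self.counts = np.array(states, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[GenotypeState]:
        return iter(self.states)

    def __getitem__(self, i: int) -> GenotypeState:
        return self.states[i]

    def index(self, state) -> int:
        s = GenotypeState(*state)
        if s.N != self.N:
            raise ValueError(f"state {tuple(s)} does not sum to N={self.N}")
        return self._index[s]

    @property
    def frequencies(self) -> np.ndarray:
        """Genotype frequencies, one row (nu_aa, nu_aA, nu_AA) per state."""
        return self.counts / self.N

    def definetti(self) -> np.ndarray:
        """(x, y) de Finetti coordinates for every state, shape (|S|, 2)."""
        nu = self.frequencies
        x = nu[:, 2] + 0.5 * nu[:, 1]
        y = _SQRT3_2 * nu[:, 1]
        return np.column_stack([x, y])

    @property
    def fixation_indices(self) -> tuple[int, int]:
        """Indices of the two monomorphic (fixation) states."""
        N = self.N
        return (self.index((N, 0, 0)), self.index((0, 0, N)))

    def to_frame(self) -> pd.DataFrame:
        xy = self.definetti()
        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "n_aa": self.counts[:, 0],
                "n_aA": self.counts[:, 1],
                "n_AA": self.counts[:, 2],
                "x": xy[:, 0],
                "y": xy[:, 1],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:
        return f"StateSpace(N={self.N}, |S|={len(self)})"


def enumerate_states(N: int) -> StateSpace:
    """Build the canonical StateSpace for population size N."""
    return StateSpace(N)


def allele_swap_permutation(space: StateSpace) -> np.ndarray:
    """Permutation sigma with sigma[i] = index of the allele-swapped state i.

    Swapping allele names maps (n_aa, n_aA, n_AA) to (n_AA, n_aA, n_aa);
    the permutation is an involution.
    """
    return np.array([space.index(s.swapped()) for s in space], dtype=np.intp)


def allele_swap_paired_order(space: StateSpace) -> np.ndarray:
    """Secondary state order placing allele-swap partners adjacently.

    Useful to display the partial symmetry of the transition matrix; states
    on the symmetry axis (n_aa = n_AA) have no distinct partner and appear
    singly.  Returns a permutation ``order`` such that
    ``space.states[order[k]]`` lists the states in the paired order.
    """
    sigma = allele_swap_permutation(space)
    seen = np.zeros(len(space), dtype=bool)
    order = []
    for i in range(len(space)):
        if seen[i]:
            continue
        order.append(i)
        seen[i] = True
        j = int(sigma[i])
        if not seen[j]:
            order.append(j)
            seen[j] = True
    return np.array(order, dtype=np.intp)


def definetti_coords(state, N: int) -> tuple[float, float]:
    """De Finetti (ternary) coordinates of one state.

    With genotype frequencies nu = counts / N, x = nu_AA + nu_aA / 2 and
    y = (sqrt(3)/2) * nu_aA.  Corners: all-aa -> (0, 0), all-AA -> (1, 0),
    all-heterozygote -> (1/2, sqrt(3)/2).
    """
    s = GenotypeState(*state)
    if s.N != N:
        raise ValueError(f"state {tuple(s)} does not sum to N={N}")
    nu_aA = s.n_aA / N
    nu_AA = s.n_AA / N
    return (nu_AA + 0.5 * nu_aA, _SQRT3_2 * nu_aA)
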