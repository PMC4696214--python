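"""F_IS statistics, limiting F_IS distributions, and divergence measures.

The inbreeding coefficient F_IS = 1 - nu_aA / (2 nu_a nu_A) measures the
deficit (positive) or excess (negative) of heterozygotes relative to the
Hardy–Weinberg expectation at the current allele frequencies.  It is
undefined in monomorphic populations (nu_a * nu_A = 0); that probability
mass is tracked separately and omitted from all comparisons, mirroring the
omission of infinite terms from the divergence statistics.

F_IS values are kept as exact rationals per state, so states sharing a
value aggregate exactly; any binning is a display concern only.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .statespace import GenotypeState, StateSpace

__all__ = ["fis", "FisDistribution", "fis_distribution", "divergence", "g_test",
           "GTestResult"]

DIVERGENCE_METHODS = ("total_distance", "kl", "power_divergence", "ks")


def fis(state, N: int) -> Fraction | None:
    """Exact F_IS of one genotype-count state; None where undefined.

    With counts (n_aa, n_aA, n_AA) summing to N,
    F_IS = 1 - 2N n_aA / ((2 n_aa + n_aA)(2 n_AA + n_aA)); the denominator
    vanishes exactly for the monomorphic states.
    """
    s = GenotypeState(*state)
    if s.N != N:
        raise ValueError(f"state {tuple(s)} does not sum to N={N}")
    den = (2 * s.n_aa + s.n_aA) * (2 * s.n_AA + s.n_aA)
    if den == 0:
        return None
    return 1 - Fraction(2 * N * s.n_aA, den)


@dataclass
class FisDistribution:
    """Probability mass per exact F_IS class, plus undefined-state mass."""

    classes: tuple[Fraction, ...]  # sorted ascending
    mass: np.ndarray
    undefined_mass: float

    def __post_init__(self):
        total = float(self.mass.sum()) + self.undefined_mass
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"masses sum to {total!r}, expected 1")

    @property
    def defined_mass(self) -> float:
        return float(self.mass.sum())

    def conditional(self) -> dict[Fraction, float]:
        """Class -> mass, renormalized over the defined (polymorphic) classes."""
        z = self.defined_mass
        if z <= 0:
            raise ValueError("no probability mass on states with defined F_IS")
        return {c: float(m) / z for c, m in zip(self.classes, self.mass)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fis_value": [float(c) for c in self.classes], "mass": self.mass}
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# undefined_mass\t{float(self.undefined_mass)!r}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def fis_distribution(v, space: StateSpace | None = None) -> FisDistribution:
    """Aggregate a limiting distribution by the exact F_IS of each state.

    ``v`` may be a :class:`~mcpopgen.spectral.LimitingDistribution` (its
    state space is used) or a bare probability vector with ``space`` given.
    """
    if space is None:
        space = getattr(v, "space", None)
    vec = np.asarray(getattr(v, "v", v), dtype=float)
    if space is None or len(space) != vec.size:
        raise ValueError("a StateSpace matching the vector length is required")
    acc: dict[Fraction, float] = {}
    undefined = 0.0
    for p, state in zip(vec, space):
        f = fis(state, space.N)
        if f is None:
            undefined += p
        elif p != 0.0:  # zero-mass states do not create classes
            acc[f] = acc.get(f, 0.0) + p
    classes = tuple(sorted(acc))
    mass = np.array([acc[c] for c in classes])
    return FisDistribution(classes=classes, mass=mass, undefined_mass=undefined)


def _aligned(f, g, conditional: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Align two distributions on the union of their classes.

    FisDistribution inputs contribute their per-class masses with the
    undefined (monomorphic) mass omitted — raw by default, renormalized over
    the defined classes with ``conditional=True``.  Mappings
    (class -> mass) and pre-aligned equal-length arrays are also accepted;
    bare arrays must be normalized, mappings may be sub-normalized (a
    distribution with omitted classes).
    """
    def as_map(d):
        if isinstance(d, FisDistribution):
            return d.conditional() if conditional else dict(zip(d.classes, d.mass))
        if isinstance(d, dict):
            return d
        return None

    fm, gm = as_map(f), as_map(g)
    if fm is not None and gm is not None:
        keys = sorted(set(fm) | set(gm))
        fv = np.array([fm.get(k, 0.0) for k in keys], dtype=float)
        gv = np.array([gm.get(k, 0.0) for k in keys], dtype=float)
        strict = False
    else:
        fv = np.asarray(f, dtype=float)
        gv = np.asarray(g, dtype=float)
        if fv.shape != gv.shape:
            raise ValueError("bare vectors must have equal length (pre-aligned)")
        strict = True
    for name, vec in (("first", fv), ("second", gv)):
        total = vec.sum()
        if (vec < -1e-12).any() or total <= 0 or total > 1 + 1e-6:
            raise ValueError(f"{name} input is not a (sub-)distribution")
        if strict and abs(total - 1.0) > 1e-6:
            raise ValueError(f"{name} distribution is not normalized")
    return fv, gv


def divergence(f, g, method: str = "total_distance", lam: float = 2.0 / 3.0,
               conditional: bool = False) -> float:
    """Divergence between two aligned discrete distributions.

    methods: ``total_distance`` sum |f - g| (in [0, 2]); ``kl``
    Kullback–Leibler sum f log(f/g) with 0 log 0 = 0 and infinite terms
    (g = 0 < f) omitted; ``power_divergence`` the Cressie–Read family
    2/(lam (lam+1)) sum f [(f/g)^lam - 1], default lam = 2/3, infinite terms
    omitted; ``ks`` the maximal cumulative difference over the sorted
    classes (two-sample Kolmogorov–Smirnov statistic, in [0, 1]).

    For :class:`FisDistribution` inputs the comparison is over the defined
    (polymorphic) classes with the undefined mass omitted; pass
    ``conditional=True`` to renormalize over those classes first.
    """
    fv, gv = _aligned(f, g, conditional)
    if method == "total_distance":
        return float(np.abs(fv - gv).sum())
    if method == "ks":
        return float(np.abs(np.cumsum(fv) - np.cumsum(gv)).max())
    both = (fv > 0) & (gv > 0)
    if method == "kl":
        return float(np.sum(fv[both] * np.log(fv[both] / gv[both])))
    if method == "power_divergence":
        if lam == 0:
            raise ValueError("lam must be nonzero (use kl for the lam -> 0 limit)")
        ratio = (fv[both] / gv[both]) ** lam - 1.0
        return float(2.0 / (lam * (lam + 1.0)) * np.sum(fv[both] * ratio))
    raise ValueError(f"unknown method {method!r}; choose from {DIVERGENCE_METHODS}")


class GTestResult(NamedTuple):
    statistic: float
    pvalue: float
    df: int
    omitted: int  # classes dropped because g = 0 < f (infinite terms)


def g_test(f, g, n_eff: float = 1000.0, conditional: bool = False) -> GTestResult:
    """Log-likelihood-ratio (G) comparison of two probability vectors.

    G = 2 n_eff sum f_k ln(f_k / g_k) over classes with f_k > 0 and
    g_k > 0; classes that would contribute infinite terms are omitted and
    counted.  ``n_eff`` is the pseudo-count scale turning probabilities
    into counts; the p-value comes from a chi-square with
    (retained classes - 1) degrees of freedom.
    """
    fv, gv = _aligned(f, g, conditional)
    retained = (fv > 0) & (gv > 0)
    omitted = int(((fv > 0) & (gv <= 0)).sum())
    k = int(retained.sum())
    if k < 2:
        raise ValueError(f"only {k} retained classes; need at least 2")
    stat = 2.0 * n_eff * float(np.sum(fv[retained] * np.log(fv[retained] / gv[retained])))
    df = k - 1
    pvalue = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return GTestResult(statistic=stat, pvalue=pvalue, df=df, omitted=omitted)
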