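import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcpopgen import (FisDistribution, ModelParams, StateSpace,
                      allele_swap_permutation, build_transition_matrix,
                      divergence, dominant_eigenvector, fis, fis_distribution,
                      g_test)


class TestFis:
    @pytest.mark.parametrize(
        "state, N, expected",
        [
            ((1, 2, 1), 4, Fraction(0)),       # Hardy–Weinberg
            ((0, 4, 0), 4, Fraction(-1)),      # all heterozygotes
            ((2, 0, 2), 4, Fraction(1)),       # no heterozygotes, even freqs
            ((3, 2, 5), 10, 1 - Fraction(2 * 10 * 2, 8 * 12)),
        ],
    )
    def test_values(self, state, N, expected):
        assert fis(state, N) == expected

    def test_monomorphic_undefined(self):
        assert fis((7, 0, 0), 7) is None
        assert fis((0, 0, 7), 7) is None

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=2, max_value=60), st.data())
    def test_matches_float_formula_and_swap_symmetry(self, N, data):
        n_aa = data.draw(st.integers(0, N))
        n_aA = data.draw(st.integers(0, N - n_aa))
        state = (n_aa, n_aA, N - n_aa - n_aA)
        f = fis(state, N)
        nu_aa, nu_aA, nu_AA = (c / N for c in state)
        nu_a, nu_A = nu_aa + nu_aA / 2, nu_AA + nu_aA / 2
        if nu_a * nu_A == 0:
            assert f is None
        else:
            assert float(f) == pytest.approx(1 - nu_aA / (2 * nu_a * nu_A))
            assert fis(state[::-1], N) == f  # allele swap invariance


class TestFisDistribution:
    def test_point_mass(self):
        space = StateSpace(4)
        v = np.zeros(len(space))
        v[space.index((1, 2, 1))] = 1.0
        d = fis_distribution(v, space)
        assert d.classes == (Fraction(0),)
        assert d.mass == pytest.approx([1.0])
        assert d.undefined_mass == 0.0

    def test_model_limit_dominated_by_fixation(self, model_n5):
        d = fis_distribution(dominant_eigenvector(model_n5))
        assert d.undefined_mass > 0.5
        assert d.defined_mass + d.undefined_mass == pytest.approx(1.0, abs=1e-10)

    def test_allele_swap_invariance(self, model_n5):
        v = dominant_eigenvector(model_n5)
        sigma = allele_swap_permutation(model_n5.space)
        d1 = fis_distribution(v)
        d2 = fis_distribution(v.v[np.argsort(sigma)], model_n5.space)
        assert d1.classes == d2.classes
        assert d2.mass == pytest.approx(d1.mass, abs=1e-12)

    def test_tsv_roundtrip(self, tmp_path, model_n5):
        d = fis_distribution(dominant_eigenvector(model_n5))
        path = tmp_path / "fis.tsv"
        d.to_tsv(path)
        from mcpopgen.cli import _read_fis_tsv

        back = _read_fis_tsv(path)
        assert back.undefined_mass == d.undefined_mass
        assert back.mass == pytest.approx(d.mass)


class TestDivergence:
    def make_dist(self, masses, undefined=0.0):
        classes = tuple(Fraction(k, 10) for k in range(len(masses)))
        return FisDistribution(classes=classes, mass=np.asarray(masses, float),
                               undefined_mass=undefined)

    def test_identical_distributions_are_zero(self):
        f = self.make_dist([0.3, 0.3, 0.2], undefined=0.2)
        for meth in ("total_distance", "kl", "power_divergence", "ks"):
            assert divergence(f, f, method=meth) == 0.0

    def test_disjoint_supports(self):
        assert divergence(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 2.0
        assert divergence(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                          method="ks") == 1.0

    def test_kl_direct_value(self):
        got = divergence(np.array([0.8, 0.2]), np.array([0.5, 0.5]), method="kl")
        assert got == pytest.approx(0.8 * math.log(1.6) + 0.2 * math.log(0.4))
        assert got == pytest.approx(0.19274475)

    def test_power_divergence_value(self):
        f, g = np.array([0.8, 0.2]), np.array([0.5, 0.5])
        lam = 2 / 3
        expected = 2 / (lam * (lam + 1)) * (
            0.8 * ((0.8 / 0.5) ** lam - 1) + 0.2 * ((0.2 / 0.5) ** lam - 1)
        )
        assert divergence(f, g, method="power_divergence") == pytest.approx(expected)

    def test_class_alignment_union(self):
        f = self.make_dist([0.6, 0.4])
        g = FisDistribution(classes=(Fraction(1, 10), Fraction(2, 10)),
                            mass=np.array([0.5, 0.5]), undefined_mass=0.0)
        # union classes {0, 0.1, 0.2}: |0.6-0| + |0.4-0.5| + |0-0.5|
        assert divergence(f, g) == pytest.approx(1.2)

    def test_unnormalized_vectors_error(self):
        with pytest.raises(ValueError):
            divergence(np.array([0.9, 0.3]), np.array([0.5, 0.5]))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_nonnegativity_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        f, g = rng.dirichlet(np.ones(n)), rng.dirichlet(np.ones(n))
        td = divergence(f, g)
        assert 0 <= td <= 2
        assert 0 <= divergence(f, g, method="ks") <= 1
        assert divergence(f, g, method="kl") >= -1e-12
        assert divergence(f, g, method="power_divergence") >= -1e-12


class TestGTest:
    def test_identical_gives_zero_and_p_one(self):
        f = np.array([0.5, 0.3, 0.2])
        res = g_test(f, f)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_direct_value(self):
        res = g_test(np.array([0.6, 0.4]), np.array([0.5, 0.5]), n_eff=100)
        expected = 200 * (0.6 * math.log(1.2) + 0.4 * math.log(0.8))
        assert res.statistic == pytest.approx(expected)
        assert res.statistic == pytest.approx(4.027103, rel=1e-5)
        assert res.df == 1

    def test_infinite_classes_omitted_and_counted(self):
        f = np.array([0.5, 0.3, 0.2])
        g = np.array([0.6, 0.4, 0.0])
        res = g_test(f, g)
        assert res.omitted == 1
        assert res.df == 1

    def test_too_few_classes_error(self):
        with pytest.raises(ValueError):
            g_test(np.array([1.0, 0.0]), np.array([0.0, 1.0]))


def test_approximation_preserves_fis_distribution_closely(model_n20):
    """The s=0.99 approximate limiting F_IS distribution stays close to the
    original on the same N=20 chain."""
    from mcpopgen import approximate_matrix

    sparse, _ = approximate_matrix(model_n20, 0.99)
    f_orig = fis_distribution(dominant_eigenvector(model_n20))
    f_appr = fis_distribution(dominant_eigenvector(sparse))
    assert divergence(f_orig, f_appr) < 0.05
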