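"""Poisson mixture EM: pmf, E/M steps, convergence, oracle equivalence."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from kmerbin import FrequencyHistogram, MixtureModel, poisson_pmf, run_em
from kmerbin.em import default_init, e_step, log_likelihood, m_step


def brute_force_em_iteration(xs, model):
    """Independent per-data-point EM iteration (textbook formulas), used
    as the oracle for the histogram-form implementation."""
    xs = np.asarray(xs, dtype=float)
    n = xs.size
    m = model.m
    p = np.empty((n, m))
    for i, x in enumerate(xs):
        for j in range(m):
            lam = model.lambdas[j]
            p[i, j] = model.alphas[j] * (
                lam ** float(x) * math.exp(-lam) / math.factorial(int(x))
            )
    Z = p / p.sum(axis=1, keepdims=True)
    alphas = Z.sum(axis=0) / n
    lambdas = (Z * xs[:, None]).sum(axis=0) / Z.sum(axis=0)
    return MixtureModel(alphas=alphas / alphas.sum(), lambdas=lambdas)


class TestPmf:
    def test_closed_forms(self):
        assert poisson_pmf(2.0, 0) == pytest.approx(math.exp(-2), rel=1e-12)
        assert poisson_pmf(3.0, 3) == pytest.approx(27 * math.exp(-3) / 6, rel=1e-12)

    def test_log_space_no_overflow(self):
        # arbitrary-precision oracle: 5^120 e^-5 / 120!
        exact = float(sympy.N(sympy.Integer(5) ** 120 * sympy.exp(-5) / sympy.factorial(120), 30))
        got = poisson_pmf(5.0, 120)
        assert np.isfinite(got)
        assert got == pytest.approx(exact, rel=1e-10)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            poisson_pmf(0.0, 1)


class TestESteps:
    def test_symmetry(self):
        hist = FrequencyHistogram.from_entries({3: 2.0, 7: 1.0})
        model = MixtureModel(alphas=[0.5, 0.5], lambdas=[4.0, 4.0])
        Z = e_step(hist, model)
        assert np.allclose(Z, 0.5)

    def test_single_component(self):
        hist = FrequencyHistogram.from_entries({1: 1.0, 9: 2.0})
        Z = e_step(hist, MixtureModel(alphas=[1.0], lambdas=[3.0]))
        assert np.allclose(Z, 1.0)

    def test_derived_value(self):
        # Z_1 = e^-1 / (e^-1 + 10 e^-10) at x=1, alpha=(.5,.5), lambda=(1,10)
        hist = FrequencyHistogram.from_entries({1: 1.0})
        model = MixtureModel(alphas=[0.5, 0.5], lambdas=[1.0, 10.0])
        Z = e_step(hist, model)
        expected = math.exp(-1) / (math.exp(-1) + 10 * math.exp(-10))
        assert Z[0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.99877, abs=5e-6)

    def test_rows_normalised(self):
        hist = FrequencyHistogram.from_entries({0: 1.0, 2: 3.0, 50: 2.0})
        model = MixtureModel(alphas=[0.2, 0.8], lambdas=[1.0, 30.0])
        Z = e_step(hist, model)
        assert np.allclose(Z.sum(axis=1), 1.0, atol=1e-9)

    def test_extreme_counts_stay_finite(self):
        # log-space evaluation: a count deep in both tails still yields a
        # normalised, NaN-free responsibility row
        hist = FrequencyHistogram.from_entries({100000: 1.0})
        model = MixtureModel(alphas=[0.5, 0.5], lambdas=[1.0, 2.0])
        Z = e_step(hist, model)
        assert np.all(np.isfinite(Z))
        assert Z.sum() == pytest.approx(1.0, abs=1e-9)
        assert Z[0, 1] > Z[0, 0]  # the larger lambda is less implausible


class TestMStep:
    def test_single_component_mean(self):
        hist = FrequencyHistogram.from_entries({2: 1.0, 4: 2.0, 10: 1.0})
        Z = np.ones((3, 1))
        model = m_step(hist, Z)
        assert model.alphas[0] == pytest.approx(1.0)
        assert model.lambdas[0] == pytest.approx((2 + 8 + 10) / 4)

    def test_all_mass_one_component(self):
        hist = FrequencyHistogram.from_entries({2: 1.0, 4: 1.0, 6: 1.0})
        Z = np.column_stack([np.ones(3), np.zeros(3)])
        with pytest.warns(RuntimeWarning):
            model = m_step(hist, Z, prev=MixtureModel(alphas=[0.5, 0.5], lambdas=[1.0, 9.0]))
        assert np.allclose(model.alphas, [1.0, 0.0])
        assert model.lambdas[0] == pytest.approx(4.0)
        assert model.lambdas[1] == pytest.approx(9.0)  # kept from prev

    def test_hard_split(self):
        hist = FrequencyHistogram.from_entries({1: 10.0, 20: 10.0})
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = m_step(hist, Z)
        assert np.allclose(model.alphas, [0.5, 0.5])
        assert np.allclose(model.lambdas, [1.0, 20.0])


class TestRunEM:
    def test_m1_closed_form(self):
        hist = FrequencyHistogram.from_entries({3: 5.0, 8: 2.0, 12: 1.0})
        res = run_em(hist, m=1)
        wmean = (3 * 5 + 8 * 2 + 12) / 8
        assert res.model.lambdas[0] == pytest.approx(wmean, rel=1e-12)
        assert res.converged

    def test_loglik_nondecreasing(self, rng):
        xs = np.concatenate([rng.poisson(4, 400), rng.poisson(15, 600)])
        v, c = np.unique(xs, return_counts=True)
        hist = FrequencyHistogram(xs=v, weights=c.astype(float))
        res = run_em(hist, m=2)
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-9)

    def test_parameter_recovery_small(self, rng):
        xs = np.concatenate([rng.poisson(5, 6000), rng.poisson(25, 14000)])
        v, c = np.unique(xs, return_counts=True)
        hist = FrequencyHistogram(xs=v, weights=c.astype(float))
        model = run_em(hist, m=2).model.sorted_by_lambda()
        assert np.allclose(model.lambdas, [5, 25], rtol=0.06)
        assert np.allclose(model.alphas, [0.3, 0.7], atol=0.05)

    def test_label_permutation_equivariance(self):
        hist = FrequencyHistogram.from_entries({2: 30.0, 9: 20.0, 15: 10.0})
        init = MixtureModel(alphas=[0.4, 0.6], lambdas=[3.0, 12.0])
        perm = MixtureModel(alphas=[0.6, 0.4], lambdas=[12.0, 3.0])
        a = run_em(hist, init=init).model
        b = run_em(hist, init=perm).model
        assert np.allclose(a.alphas, b.alphas[::-1], atol=1e-9)
        assert np.allclose(a.lambdas, b.lambdas[::-1], atol=1e-7)

    def test_weight_scaling_invariance(self):
        ent = {1: 5.0, 4: 9.0, 11: 3.0}
        h1 = FrequencyHistogram.from_entries(ent)
        h2 = FrequencyHistogram.from_entries({x: 7.0 * w for x, w in ent.items()})
        a = run_em(h1, m=2).model
        b = run_em(h2, m=2).model
        assert np.allclose(a.alphas, b.alphas, atol=1e-9)
        assert np.allclose(a.lambdas, b.lambdas, atol=1e-9)


@settings(deadline=None, max_examples=25)
@given(
    st.lists(st.integers(0, 40), min_size=5, max_size=60).filter(lambda d: sum(d) > 0),
    st.integers(1, 3),
)
def test_histogram_em_matches_brute_force(data, m):
    """Histogram-form EM is numerically identical to the per-data-point fit."""
    xs = np.asarray(data, dtype=np.int64)
    v, c = np.unique(xs, return_counts=True)
    hist = FrequencyHistogram(xs=v, weights=c.astype(float))
    model = default_init(m)
    for _ in range(3):
        oracle = brute_force_em_iteration(xs, model)
        Z = e_step(hist, model)
        ours = m_step(hist, Z, prev=model)
        assert np.allclose(ours.alphas, oracle.alphas, atol=1e-12)
        assert np.allclose(ours.lambdas, oracle.lambdas, atol=1e-12)
        model = ours


def test_loglik_value_matches_direct_sum():
    hist = FrequencyHistogram.from_entries({0: 2.0, 3: 4.0, 7: 1.0})
    model = MixtureModel(alphas=[0.3, 0.7], lambdas=[2.0, 6.0])
    direct = sum(
        w * math.log(sum(a * poisson_pmf(l, int(x)) for a, l in zip(model.alphas, model.lambdas)))
        for x, w in hist.entries.items()
    )
    assert log_likelihood(hist, model) == pytest.approx(direct, rel=1e-12)
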