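"""Complete-data statistic: kernel, estimator, projection, null variance."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import nbu2test as nt
from nbu2test.core import delta_hat_rows


def _kernel_sympy(xi, xj, s):
    """Independent 50-digit term-by-term evaluation of the kernel."""
    xi, xj, s = (sympy.Rational(str(v)) for v in (xi, xj, s))
    expr = s * xi * sympy.exp(-s * xi) + sympy.exp(-s * xi) * sympy.exp(-s * xj) - sympy.exp(
        -s * xi
    )
    return float(sympy.N(expr, 50))


class TestKernel:
    def test_zero_at_origin(self):
        assert nt.kernel(0.0, 0.0, 0.4) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("x,s", [(0.5, 0.4), (2.0, 0.6), (7.0, 1.0)])
    def test_first_argument_zero_is_nonpositive(self, x, s):
        # kernel(0, x) = e^{-s x} - 1 <= 0
        assert nt.kernel(0.0, x, s) == pytest.approx(np.exp(-s * x) - 1, rel=1e-14)
        assert nt.kernel(0.0, x, s) <= 0

    @pytest.mark.parametrize(
        "xi,xj,s",
        [(1.0, 2.0, 0.4), (0.3, 5.0, 0.6), (4.0, 0.1, 1.5), (2.5, 2.5, 0.4)],
    )
    def test_matches_high_precision_oracle(self, xi, xj, s):
        assert nt.kernel(xi, xj, s) == pytest.approx(_kernel_sympy(xi, xj, s), rel=1e-13)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nt.kernel(-1.0, 1.0, 0.4)
        with pytest.raises(ValueError):
            nt.kernel(np.inf, 1.0, 0.4)
        with pytest.raises(ValueError):
            nt.kernel(1.0, 1.0, -0.4)


def _delta_hat_brute(times, s):
    """Explicit double loop over all ordered pairs (i, j), including i = j.

    Compensated summation so the oracle itself carries no accumulation error.
    """
    n = len(times)
    total = math.fsum(float(nt.kernel(xi, xj, s)) for xi in times for xj in times)
    return total / (s**3 * n * (n - 1))


class TestDeltaHat:
    def test_small_sample_against_double_loop(self):
        times = [1.0, 2.0, 3.0]
        assert nt.delta_hat(times, 0.4) == pytest.approx(
            _delta_hat_brute(times, 0.4), rel=1e-12
        )

    def test_reduced_formula_equals_double_loop_on_random_samples(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 31))
            s = float(rng.uniform(0.1, 2.0))
            x = rng.exponential(size=n) * rng.uniform(0.2, 5.0)
            fast = nt.delta_hat(x, s)
            slow = _delta_hat_brute(x, s)
            assert fast == pytest.approx(slow, rel=1e-12, abs=1e-14)

    @pytest.mark.parametrize(
        "dataset,s,printed,tol",
        [
            ("leukemia", 0.4, 1.5, 0.08),
            ("leukemia", 0.6, 0.43, 0.04),
            ("liver_complete", 0.4, 0.07, 0.01),
            ("liver_complete", 0.6, 0.003, 0.001),
        ],
    )
    def test_published_worked_examples(self, dataset, s, printed, tol, request):
        sample = request.getfixturevalue(dataset)
        assert nt.delta_hat(sample, s) == pytest.approx(printed, abs=tol)

    def test_degenerate_all_zero_times(self):
        # limiting input: every kernel term vanishes at the origin
        assert delta_hat_rows(np.zeros((1, 2)), 0.4)[0] == pytest.approx(0.0, abs=1e-15)

    def test_rejects_singleton_and_bad_s(self):
        with pytest.raises(ValueError):
            nt.delta_hat([1.0], 0.4)
        with pytest.raises(ValueError):
            nt.delta_hat([1.0, 2.0], -1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        c=st.sampled_from([0.5, 2.0, 10.0]),
        s=st.floats(0.1, 2.0),
        seed=st.integers(0, 10_000),
    )
    def test_scale_equivariance(self, c, s, seed):
        # delta_hat(c X, s / c) = c^3 delta_hat(X, s)
        x = np.random.default_rng(seed).exponential(size=20)
        lhs = nt.delta_hat(c * x, s / c)
        rhs = c**3 * nt.delta_hat(x, s)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_pairwise_kernel_mean_zero_under_any_exponential_rate(self, rng):
        # E[kernel(X1, X2)] = 0 for i.i.d. Exp(beta), any beta: the
        # off-diagonal part of the statistic is exactly centred.
        for beta in (0.3, 1.0, 4.0):
            x1 = rng.exponential(scale=1 / beta, size=200_000)
            x2 = rng.exponential(scale=1 / beta, size=200_000)
            vals = nt.kernel(x1, x2, 0.4)
            se = vals.std() / np.sqrt(vals.size)
            assert abs(vals.mean()) < 3 * se

    def test_exact_null_mean_including_diagonal(self, rng):
        # the diagonal terms shift the null mean to a known O(1/n) constant
        n, s, reps = 50, 0.4, 5_000
        stats = delta_hat_rows(rng.exponential(size=(reps, n)), s)
        se = stats.std() / np.sqrt(reps)
        assert stats.mean() == pytest.approx(nt.null_delta_mean(n, s), abs=4 * se)

    def test_positive_drift_under_lfr_alternative(self, rng):
        # LFR theta = 1 is a proper NBU(2) alternative: mean statistic > 0
        fam = nt.lfr(1.0)
        stats = delta_hat_rows(fam.draw((3_000, 50), rng), 0.4)
        se = stats.std() / np.sqrt(stats.size)
        assert stats.mean() > 3 * se


def _xi_sympy(x, s):
    x, s = sympy.Rational(str(x)), sympy.Rational(str(s))
    expr = (
        s * x * sympy.exp(-s * x)
        + (1 - s) / (1 + s) * sympy.exp(-s * x)
        - 1 / (1 + s) ** 2
    )
    return float(sympy.N(expr, 50))


class TestProjection:
    def test_value_at_origin_s1(self):
        assert nt.xi_projection(0.0, 1.0) == pytest.approx(-0.25, abs=1e-15)

    @pytest.mark.parametrize("x,s", [(2.0, 0.4), (0.5, 0.6), (10.0, 1.0)])
    def test_matches_high_precision_oracle(self, x, s):
        assert nt.xi_projection(x, s) == pytest.approx(_xi_sympy(x, s), rel=1e-13)

    @pytest.mark.parametrize("s", [0.1, 0.4, 0.6, 1.0, 2.0])
    def test_zero_mean_under_unit_exponential(self, s):
        mean, _ = quad(lambda x: nt.xi_projection(x, s) * np.exp(-x), 0, np.inf)
        assert mean == pytest.approx(0.0, abs=1e-10)


class TestNullVariance:
    @pytest.mark.parametrize("s", [0.1, 0.4, 0.6, 1.0, 2.0])
    def test_matches_quadrature_of_squared_projection(self, s):
        # sigma0^2 = E[xi(X)^2] since E[xi(X)] = 0 under Exp(1)
        val, _ = quad(lambda x: nt.xi_projection(x, s) ** 2 * np.exp(-x), 0, np.inf)
        assert nt.sigma0_sq(s) == pytest.approx(val, abs=1e-8)

    def test_monte_carlo_variance_agrees(self, rng):
        x = rng.exponential(size=1_000_000)
        assert nt.sigma0_sq(0.4) == pytest.approx(np.var(nt.xi_projection(x, 0.4)), rel=0.02)

    def test_reference_magnitudes(self):
        assert nt.sigma0_sq(0.4) == pytest.approx(0.00242, abs=5e-5)
        assert nt.sigma0_sq(0.6) == pytest.approx(0.00542, abs=5e-5)

    def test_positive_and_validated(self):
        assert nt.sigma0_sq(3.7) > 0
        with pytest.raises(ValueError):
            nt.sigma0_sq(0.0)


class TestRunTest:
    def test_leukemia_rejects_h0(self, leukemia):
        res = nt.run_test(leukemia, nt.TestConfig(s=0.4, alpha=0.05, seed=0))
        assert res.reject_h0
        assert res.n == 40 and res.calibration_used == "simulated"

    def test_liver_does_not_reject(self, liver_complete):
        res = nt.run_test(liver_complete, nt.TestConfig(s=0.4, alpha=0.05, seed=0))
        assert not res.reject_h0

    def test_asymptotic_mode_runs_and_agrees_in_decision_on_clear_data(self, leukemia):
        res = nt.run_test(leukemia, nt.TestConfig(s=0.4, calibration="asymptotic"))
        assert res.reject_h0
        assert res.critical_value > 0

    def test_unknown_calibration_rejected(self):
        with pytest.raises(ValueError):
            nt.TestConfig(s=0.4, calibration="bootstrap")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            nt.TestConfig(s=-1.0)
        with pytest.raises(ValueError):
            nt.TestConfig(s=0.4, alpha=1.5)
        with pytest.raises(ValueError):
            nt.TestConfig(s=0.4, n_reps=10)


class TestSurvivalSample:
    def test_sorts_and_validates(self):
        s = nt.SurvivalSample([3.0, 1.0, 2.0])
        assert list(s.times) == [1.0, 2.0, 3.0] and s.n == 3

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -2.0], [1.0, np.nan], []])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            nt.SurvivalSample(bad)
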