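"""Core LBA densities and simulator against independent oracles:
Monte Carlo, finite differences, adaptive quadrature, and an ML refit.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize
from scipy.stats import norm

from lbacomp import (
    LBAParams,
    defective_density,
    lba_cdf,
    lba_pdf,
    log_likelihood,
    simulate_trial,
    simulate_trials,
)
from lbacomp.lba import response_probability, rt_window_mass


class TestCdf:
    def test_zero_time_has_zero_mass(self):
        assert lba_cdf(0.0, 1.0, 0.5, 1.5, 1.0) == 0.0

    def test_degenerate_start_point_closed_form(self):
        # A -> 0: passage iff drift exceeds b/t
        assert lba_cdf(1.0, 1.0, 0.0, 2.0, 1.0) == pytest.approx(norm.cdf(1.0))

    def test_matches_monte_carlo(self, rng):
        n = 10**6
        k = rng.uniform(0, 0.5, n)
        d = rng.normal(1.5, 1.0, n)
        with np.errstate(divide="ignore"):
            hit = (d > 0) & ((1.0 - k) / np.where(d > 0, d, np.nan) <= 0.8)
        mc = np.nanmean(hit)
        se = np.sqrt(mc * (1 - mc) / n)
        assert lba_cdf(0.8, 1.0, 0.5, 1.5, 1.0) == pytest.approx(mc, abs=3 * se)

    def test_limit_is_positive_drift_probability(self):
        assert lba_cdf(1e6, 1.0, 0.5, 1.5, 1.0) == pytest.approx(norm.cdf(1.5), abs=1e-6)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            lba_cdf(1.0, 1.0, 1.5, 1.0, 1.0)  # A > b
        with pytest.raises(ValueError):
            lba_cdf(1.0, 1.0, 0.5, 1.0, -1.0)  # s_v <= 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        b=st.floats(0.5, 2.0),
        a_frac=st.floats(0.0, 1.0),
        v=st.floats(0.2, 3.0),
    )
    def test_monotone_nondecreasing(self, b, a_frac, v):
        grid = np.linspace(0.0, 10.0, 1000)
        F = lba_cdf(grid, b, a_frac * b, v, 1.0)
        assert np.all(np.diff(F) >= -1e-12)


class TestPdf:
    def test_vanishes_at_origin(self):
        assert lba_pdf(1e-12, 1.0, 0.5, 1.5, 1.0) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("t", [0.3, 0.8, 1.5])
    def test_is_derivative_of_cdf(self, t):
        h = 1e-4
        fd = (lba_cdf(t + h, 1, 0.5, 1.5, 1) - lba_cdf(t - h, 1, 0.5, 1.5, 1)) / (2 * h)
        assert abs(fd - lba_pdf(t, 1, 0.5, 1.5, 1)) < 1e-6

    def test_integrates_to_positive_drift_mass(self):
        val, _ = quad(lambda t: lba_pdf(t, 1, 0.5, 1.0, 1.0), 0, np.inf, limit=200)
        assert val == pytest.approx(norm.cdf(1.0), abs=1e-6)


PARAM_GRID = [
    LBAParams(b=b, A=A, v_correct=vc, v_error=ve, s_v=1.0)
    for b in (0.5, 1.0, 1.5)
    for A in (0.0, 0.25, None)
    for vc in (1.0, 2.0)
    for ve in (0.0, 0.5)
    for A in ([b / 2 if A is None else A])
]


class TestDefectiveDensity:
    def test_zero_before_nondecision_time(self):
        p = LBAParams(b=1, A=0.5, v_correct=1.5, v_error=0.5, t0=0.2)
        assert defective_density(0.2, "correct", p) == 0.0
        assert defective_density(0.1, "error", p) == 0.0

    def test_unknown_choice_label(self):
        p = LBAParams(b=1, A=0.5, v_correct=1.5, v_error=0.5)
        with pytest.raises(ValueError):
            defective_density(1.0, "left", p)

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_normalized_masses_sum_to_one(self, params):
        total = response_probability(params, "correct") + response_probability(
            params, "error"
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_choice_probability_matches_simulation(self, rng):
        p = LBAParams(b=1, A=0.5, v_correct=1.5, v_error=0.5, t0=0.2)
        p_correct = response_probability(p, "correct")
        n = 10**5
        correct, _ = simulate_trials(p, n, rng)
        se = np.sqrt(p_correct * (1 - p_correct) / n)
        assert correct.mean() == pytest.approx(p_correct, abs=3 * se)

    def test_window_mass_matches_quadrature(self):
        p = LBAParams(b=0.95, A=0.3, v_correct=1.35, v_error=0.25, t0=0.45)
        num = sum(
            quad(lambda t: defective_density(t, ch, p), p.t0, 5.0, limit=400)[0]
            for ch in ("correct", "error")
        ) - sum(
            quad(lambda t: defective_density(t, ch, p), p.t0, 0.25, limit=400)[0]
            for ch in ("correct", "error")
        )
        assert rt_window_mass(p, 0.25, 5.0) == pytest.approx(num, abs=1e-8)


class TestSimulator:
    def test_deterministic_limit(self, rng):
        p = LBAParams(b=1, A=0.0, v_correct=2.0, v_error=1.0, s_v=1e-9, t0=0.2)
        choice, rt = simulate_trial(p, rng)
        assert choice == "correct"
        assert rt == pytest.approx(0.7, abs=1e-6)

    def test_identical_seeds_identical_streams(self):
        p = LBAParams(b=1, A=0.5, v_correct=1.5, v_error=0.5, t0=0.2)
        a = simulate_trials(p, 500, np.random.default_rng(9))
        b = simulate_trials(p, 500, np.random.default_rng(9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_simulated_rts_match_conditional_cdf(self, rng):
        """KS distance between simulated correct RTs and quadrature CDF < 0.01."""
        p = LBAParams(b=1, A=0.5, v_correct=1.5, v_error=0.5, t0=0.2)
        n = 10**5
        correct, rt = simulate_trials(p, n, rng)
        sample = np.sort(rt[correct])
        grid = np.linspace(p.t0, 30.0, 4000)
        dens = defective_density(grid, "correct", p)
        cdf = np.concatenate([[0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        cdf /= response_probability(p, "correct")
        F = np.interp(sample, grid, np.clip(cdf, 0, 1))
        ks = np.max(np.abs(F - np.arange(1, len(sample) + 1) / len(sample)))
        assert ks < 0.01

    def test_raising_threshold_trades_speed_for_accuracy(self):
        low = LBAParams(b=0.6, A=0.3, v_correct=2.0, v_error=0.5)
        high = LBAParams(b=1.4, A=0.3, v_correct=2.0, v_error=0.5)
        c_lo, rt_lo = simulate_trials(low, 10**5, np.random.default_rng(3))
        c_hi, rt_hi = simulate_trials(high, 10**5, np.random.default_rng(3))
        assert (1 - c_hi.mean()) < (1 - c_lo.mean())
        assert rt_hi.mean() > rt_lo.mean()


class TestLogLikelihood:
    def test_empty_trials(self):
        p = LBAParams(b=1, A=0.5, v_correct=1.5, v_error=0.5)
        assert log_likelihood([], p) == 0.0

    def test_singleton_equals_log_density(self):
        p = LBAParams(b=1, A=0.5, v_correct=1.5, v_error=0.5, t0=0.2)
        ll = log_likelihood([("correct", 0.9)], p)
        assert ll == pytest.approx(np.log(defective_density(0.9, "correct", p)))

    def test_rt_before_t0_gives_minus_inf(self):
        p = LBAParams(b=1, A=0.5, v_correct=1.5, v_error=0.5, t0=0.5)
        assert log_likelihood([("correct", 0.4)], p) == -np.inf

    def test_ml_refit_recovers_generating_parameters(self, rng):
        """Refitting 10^4 simulated trials recovers (b, v_c, v_e, t0) within 5%."""
        true = LBAParams(b=1.0, A=0.3, v_correct=1.5, v_error=0.6, t0=0.3)
        correct, rt = simulate_trials(true, 10**4, rng)

        def nll(x):
            b, vc, ve, t0 = x
            if b < true.A or t0 < 0 or t0 >= rt.min():
                return 1e9
            p = LBAParams(b=b, A=true.A, v_correct=vc, v_error=ve, t0=t0)
            ll = log_likelihood((correct, rt), p)
            return -ll if np.isfinite(ll) else 1e9

        res = minimize(nll, [1.2, 1.0, 0.5, 0.3], method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-6})
        truth = np.array([true.b, true.v_correct, true.v_error, true.t0])
        assert np.all(np.abs(res.x - truth) / truth < 0.05)
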