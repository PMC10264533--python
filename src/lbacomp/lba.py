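"""Linear Ballistic Accumulator: closed-form densities, simulation, likelihood.

The LBA (Brown & Heathcote, 2008) models a speeded binary choice as a race
between two independent accumulators. On each trial, accumulator ``i`` starts
at a point drawn uniformly from ``[0, A]`` and gains evidence linearly at a
rate drawn from ``Normal(v_i, s_v)``; the first accumulator to reach the
threshold ``b`` determines the choice, and the response time is the winning
passage time plus a nondecision offset ``t0``.

All times are in seconds. Functions are vectorised over ``t``/``rt`` and,
where noted, over parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import log_ndtr, ndtr

__all__ = [
    "LBAParams",
    "lba_cdf",
    "lba_pdf",
    "defective_density",
    "prob_positive_drift",
    "response_probability",
    "simulate_trial",
    "simulate_trials",
    "log_likelihood",
    "rt_window_mass",
]

# Below this start-point range the uniform start is treated as degenerate at 0
# to avoid 0/0 in the closed forms.
_A_EPS = 1e-10


@dataclass(frozen=True)
class LBAParams:
    """Parameters of a two-accumulator LBA.

    Attributes
    ----------
    b:
        Response threshold (evidence units). Higher values mean a more
        cautious strategy: more accuracy, slower responses.
    A:
        Upper bound of the uniform start-point distribution. ``0 <= A <= b``.
    v_correct, v_error:
        Mean drift rates (evidence/s) of the accumulator matching and
        mismatching the stimulus.
    s_v:
        Between-trial drift-rate standard deviation, shared by both
        accumulators.
    t0:
        Nondecision time (s): encoding and motor latency added to the
        winning passage time.
    """

    b: float
    A: float
    v_correct: float
    v_error: float
    s_v: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.b >= self.A >= 0.0):
            raise ValueError(f"require b >= A >= 0, got b={self.b}, A={self.A}")
        if self.s_v <= 0.0:
            raise ValueError(f"require s_v > 0, got {self.s_v}")
        if self.t0 < 0.0:
            raise ValueError(f"require t0 >= 0, got {self.t0}")
        # At least one accumulator must have a chance of a positive drift,
        # otherwise no trial ever terminates.
        p_none = ndtr(-self.v_correct / self.s_v) * ndtr(-self.v_error / self.s_v)
        if p_none >= 1.0:
            raise ValueError("P(all drifts <= 0) = 1: no response can terminate")

    def drifts(self) -> tuple[float, float]:
        return (self.v_correct, self.v_error)

    def with_(self, **kw) -> "LBAParams":
        return replace(self, **kw)


def _check_scalar_params(b: float, A: float, s_v: float) -> None:
    if A < 0 or A > b:
        raise ValueError(f"require 0 <= A <= b, got A={A}, b={b}")
    if s_v <= 0:
        raise ValueError(f"require s_v > 0, got s_v={s_v}")


def prob_positive_drift(v, s_v):
    """P(sampled drift > 0) = Phi(v / s_v); the total mass of one accumulator."""
    return ndtr(np.asarray(v, dtype=float) / s_v)


def lba_cdf(t, b, A, v, s_v):
    """CDF of a single accumulator's first-passage time through ``b``.

    The distribution is defective: as ``t -> inf`` the CDF tends to
    ``Phi(v / s_v)``, the probability that the sampled drift is positive.
    Negative-drift trials never cross the threshold.
    """
    _check_scalar_params(b, A, s_v)
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(t.shape), dtype=float)
    pos = t > 0
    if np.any(pos):
        tp = t[pos] if t.ndim else t
        if A < _A_EPS:
            val = ndtr((tp * v - b) / (tp * s_v))
        else:
            ts = tp * s_v
            z1 = (b - A - tp * v) / ts
            z2 = (b - tp * v) / ts
            val = (
                1.0
                + (b - A - tp * v) / A * ndtr(z1)
                - (b - tp * v) / A * ndtr(z2)
                + ts / A * (_npdf(z1) - _npdf(z2))
            )
        val = np.clip(val, 0.0, 1.0)
        if t.ndim:
            out[pos] = val
        else:
            out = val
    return out if t.ndim else float(out)


def lba_pdf(t, b, A, v, s_v):
    """Density of a single accumulator's first-passage time through ``b``."""
    _check_scalar_params(b, A, s_v)
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(t.shape), dtype=float)
    pos = t > 0
    if np.any(pos):
        tp = t[pos] if t.ndim else t
        ts = tp * s_v
        if A < _A_EPS:
            # Degenerate start point: inverse-Gaussian-like closed form.
            val = b / (tp**2 * s_v) * _npdf((tp * v - b) / ts)
        else:
            z1 = (b - A - tp * v) / ts
            z2 = (b - tp * v) / ts
            val = (
                -v * ndtr(z1) + s_v * _npdf(z1) + v * ndtr(z2) - s_v * _npdf(z2)
            ) / A
        val = np.maximum(val, 0.0)
        if t.ndim:
            out[pos] = val
        else:
            out = val
    return out if t.ndim else float(out)


def _npdf(z):
    return np.exp(-0.5 * np.square(z)) / np.sqrt(2.0 * np.pi)


def _norm_constant(params: LBAParams) -> float:
    """P(at least one accumulator samples a positive drift)."""
    return float(
        1.0
        - ndtr(-params.v_correct / params.s_v) * ndtr(-params.v_error / params.s_v)
    )


def defective_density(rt, choice, params: LBAParams, normalize: bool = True):
    """Joint density of responding ``choice`` at time ``rt``.

    ``f_choice(rt - t0) * (1 - F_other(rt - t0))``: the chosen accumulator
    finishes at the decision time while the other has not yet finished.
    Integrated over ``rt`` this gives the probability of that choice, so the
    two defective densities together integrate to the probability that any
    response occurs. With ``normalize`` the density is conditioned on a
    response occurring (divides by ``1 - P(both drifts <= 0)``), matching a
    simulator that redraws both-negative-drift trials.

    ``choice`` is ``"correct"`` or ``"error"``. Returns 0 for ``rt <= t0``.
    """
    if choice == "correct":
        v_win, v_lose = params.v_correct, params.v_error
    elif choice == "error":
        v_win, v_lose = params.v_error, params.v_correct
    else:
        raise ValueError(f"unknown choice label {choice!r}")
    rt = np.asarray(rt, dtype=float)
    t = rt - params.t0
    f = lba_pdf(t, params.b, params.A, v_win, params.s_v)
    surv = 1.0 - lba_cdf(t, params.b, params.A, v_lose, params.s_v)
    dens = f * surv
    if normalize:
        dens = dens / _norm_constant(params)
    return dens if rt.ndim else float(dens)


def response_probability(params: LBAParams, choice: str = "correct",
                         normalize: bool = True) -> float:
    """Probability of the given response, by adaptive quadrature."""
    from scipy.integrate import quad

    val, _ = quad(
        lambda u: defective_density(params.t0 + u, choice, params, normalize),
        0.0,
        np.inf,
        limit=200,
    )
    return float(val)


def simulate_trials(params: LBAParams, n: int, rng: np.random.Generator,
                    max_rt: float | None = None, min_rt: float | None = None):
    """Simulate ``n`` LBA trials; returns ``(correct: bool array, rt: array)``.

    Per trial, start points ``k_i ~ U[0, A]`` and drifts ``d_i ~ N(v_i, s_v)``
    are drawn for both accumulators; trials where both drifts are nonpositive
    are redrawn (matching the normalised likelihood). The winner is the
    accumulator with the smallest passage time ``(b - k_i) / d_i`` among those
    with positive drift. With ``max_rt`` set, trials slower than the cap are
    redrawn as well (the raw passage time has a ``t**-2`` density tail and
    hence no finite mean; capped agents model responders whose over-long
    trials would count as lapses).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    correct = np.empty(n, dtype=bool)
    rt = np.empty(n, dtype=float)
    pending = np.arange(n)
    v = np.array([params.v_correct, params.v_error])
    while pending.size:
        m = pending.size
        k = rng.uniform(0.0, params.A, size=(m, 2)) if params.A > 0 else np.zeros((m, 2))
        d = rng.normal(v, params.s_v, size=(m, 2))
        ok = (d > 0).any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            times = np.where(d > 0, (params.b - k) / d, np.inf)
        winner = np.argmin(times, axis=1)
        this_rt = params.t0 + times[np.arange(m), winner]
        if max_rt is not None:
            ok &= this_rt <= max_rt
        if min_rt is not None:
            ok &= this_rt >= min_rt
        idx = pending[ok]
        correct[idx] = winner[ok] == 0
        rt[idx] = this_rt[ok]
        pending = pending[~ok]
    return correct, rt


def simulate_trial(params: LBAParams, rng: np.random.Generator):
    """Simulate one trial; returns ``(choice, rt)`` with choice a label."""
    correct, rt = simulate_trials(params, 1, rng)
    return ("correct" if correct[0] else "error"), float(rt[0])


def _cdf_raw(t, b, A, v, s_v):
    """Single-accumulator passage-time CDF, array args, 0 where t <= 0.

    ``t = inf`` maps to the limiting mass ``Phi(v / s_v)``.
    """
    t = np.asarray(t, dtype=float)
    pos = t > 0
    inf_t = np.isinf(t)
    t_safe = np.where(pos & ~inf_t, t, 1.0)
    ts = t_safe * s_v
    z1 = (b - A - t_safe * v) / ts
    z2 = (b - t_safe * v) / ts
    F = (
        1.0
        + (b - A - t_safe * v) / A * ndtr(z1)
        - (b - t_safe * v) / A * ndtr(z2)
        + ts / A * (_npdf(z1) - _npdf(z2))
    )
    F = np.where(inf_t, ndtr(np.asarray(v / s_v, dtype=float)), F)
    return np.where(pos, np.clip(F, 0.0, 1.0), 0.0)


def rt_window_mass(params: LBAParams, lo: float, hi: float,
                   normalize: bool = True) -> float:
    """P(lo < RT < hi) under the LBA, in closed form.

    The response time of the race is the minimum of the two accumulators'
    passage times, so ``P(RT > t) = (1 - F_c(t)) (1 - F_e(t))`` (minus the
    never-terminating mass), and the window mass is a difference of two
    survivor evaluations — no quadrature. Used to condition the likelihood
    on the RT analysis window when trials outside it were excluded.
    """
    m = _window_mass_arrays(params.b, params.A, params.v_correct, params.v_error,
                            params.s_v, params.t0, lo, hi, normalize)
    return float(m)


def _window_mass_arrays(b, A, v_correct, v_error, s_v, t0, lo, hi,
                        normalize: bool = True):
    lo_t = np.maximum(np.asarray(lo, dtype=float) - t0, 0.0)
    hi_t = np.asarray(hi, dtype=float) - t0
    s_lo = (1.0 - _cdf_raw(lo_t, b, A, v_correct, s_v)) * (
        1.0 - _cdf_raw(lo_t, b, A, v_error, s_v)
    )
    s_hi = np.where(
        hi_t > 0,
        (1.0 - _cdf_raw(hi_t, b, A, v_correct, s_v))
        * (1.0 - _cdf_raw(hi_t, b, A, v_error, s_v)),
        1.0,  # window entirely below t0: zero mass via s_lo == s_hi
    )
    s_lo = np.where(hi_t > 0, s_lo, 1.0)
    mass = s_lo - s_hi
    if normalize:
        mass = mass / (1.0 - ndtr(-v_correct / s_v) * ndtr(-v_error / s_v))
    return np.clip(mass, 0.0, 1.0)


def defective_logpdf_arrays(rt, correct, b, A, v_correct, v_error, s_v, t0,
                            normalize: bool = True, window=None):
    """Elementwise log defective density with broadcast parameters.

    All arguments broadcast against each other; this is the hot path of the
    hierarchical sampler, where ``b``, ``A`` etc. differ per trial and per
    chain. Start-point ranges below ``1e-10`` are not special-cased here
    (the sampler keeps ``A`` away from 0), and invalid points map to
    ``-inf`` rather than raising. With ``window=(lo, hi)`` the density is
    conditioned on ``lo < rt < hi``, for data whose RT outliers were
    excluded by that rule; fitting the unconditioned density to
    window-truncated data biases rates upward.
    """
    rt = np.asarray(rt, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    b = np.asarray(b, dtype=float)
    A = np.asarray(A, dtype=float)
    t = rt - np.asarray(t0, dtype=float)
    v_win = np.where(correct, v_correct, v_error)
    v_lose = np.where(correct, v_error, v_correct)
    valid = (t > 0) & (A > _A_EPS) & (b >= A) & (s_v > 0)
    t_safe = np.where(valid, t, 1.0)
    ts = t_safe * s_v
    z1w = (b - A - t_safe * v_win) / ts
    z2w = (b - t_safe * v_win) / ts
    f = (-v_win * ndtr(z1w) + s_v * _npdf(z1w)
         + v_win * ndtr(z2w) - s_v * _npdf(z2w)) / A
    z1l = (b - A - t_safe * v_lose) / ts
    z2l = (b - t_safe * v_lose) / ts
    F = (1.0 + (b - A - t_safe * v_lose) / A * ndtr(z1l)
         - (b - t_safe * v_lose) / A * ndtr(z2l)
         + ts / A * (_npdf(z1l) - _npdf(z2l)))
    surv = 1.0 - np.clip(F, 0.0, 1.0)
    dens = np.maximum(f, 0.0) * surv
    if normalize:
        dens = dens / (1.0 - ndtr(-v_correct / s_v) * ndtr(-v_error / s_v))
    if window is not None:
        lo, hi = window
        valid = valid & (rt > lo) & (rt < hi)
        mass = _window_mass_arrays(b, A, v_correct, v_error, s_v, t0, lo, hi,
                                   normalize)
        dens = dens / np.maximum(mass, 1e-300)
        valid = valid & (mass > 0.0)
    with np.errstate(divide="ignore"):
        out = np.where(valid & (dens > 0.0), np.log(np.maximum(dens, 1e-300)), -np.inf)
    return out


def log_likelihood(trials, params: LBAParams, normalize: bool = True,
                   window=None) -> float:
    """Sum of log defective densities over ``trials``.

    ``trials`` is an iterable of ``(choice, rt)`` pairs or a pair of arrays
    ``(correct: bool array, rt: array)``. Any trial with ``rt <= t0`` (or a
    zero density) yields ``-inf`` rather than an exception, so samplers can
    reject the parameter point. ``window=(lo, hi)`` conditions each trial's
    density on the RT analysis window (see :func:`rt_window_mass`).
    """
    if isinstance(trials, tuple) and len(trials) == 2 and not isinstance(trials[0], str):
        correct = np.asarray(trials[0], dtype=bool)
        rt = np.asarray(trials[1], dtype=float)
    else:
        trials = list(trials)
        if not trials:
            return 0.0
        correct = np.array([c == "correct" for c, _ in trials])
        rt = np.array([r for _, r in trials], dtype=float)
    if rt.size == 0:
        return 0.0
    dens = np.where(
        correct,
        defective_density(rt, "correct", params, normalize),
        defective_density(rt, "error", params, normalize),
    )
    if window is not None:
        lo, hi = window
        if np.any(rt <= lo) or np.any(rt >= hi):
            return -np.inf
        dens = dens / rt_window_mass(params, lo, hi, normalize)
    if np.any(dens <= 0.0) or not np.all(np.isfinite(dens)):
        return -np.inf
    return float(np.sum(np.log(dens)))
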