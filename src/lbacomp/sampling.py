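"""Posterior sampling and convergence assessment.

The sampler is differential-evolution MCMC (DE-MCMC): a population of
chains in which each chain proposes a jump along the difference of two
other randomly chosen chains, scaled by ``gamma = 2.38 / sqrt(2 k)`` for a
``k``-dimensional update, plus a small uniform jitter. This family of
samplers is the standard workhorse for hierarchical evidence-accumulation
models, whose participant blocks are strongly correlated internally but
conditionally independent of each other given the group-level block.

Two entry points share the machinery:

* a generic population sampler over any object exposing ``param_names``
  and a vectorised ``log_density(points)``;
* a blocked Gibbs-style scheme for :class:`~lbacomp.model.HierarchicalLBAModel`,
  alternating participant-block updates (one vectorised likelihood pass for
  all chains and participants) with group-block updates (no likelihood).

Convergence is summarised per parameter with rank-normalised split R-hat
and bulk effective sample size via :mod:`arviz`; warnings fire at
R-hat > 1.01 or ESS < 400.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from lbacomp.model import (
    PARTICIPANT_PARAMS,
    PARTICIPANT_POSITIVE,
    GroupModelSpec,
    HierarchicalLBAModel,
)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "DensityModel",
    "sample_posterior",
    "prior_samples",
]


@dataclass(frozen=True)
class SamplerConfig:
    """DE-MCMC settings.

    ``n_chains`` is the population size (at least ~2x the largest block
    dimension, and at least 2 for diagnostics); ``n_warmup`` iterations are
    discarded; ``n_draws`` are kept per chain. ``prob_gamma1`` is the
    probability of a mode-jumping move with ``gamma = 1``; ``jitter`` is
    the half-width of the uniform proposal noise.
    """

    n_chains: int = 32
    n_warmup: int = 500
    n_draws: int = 500
    seed: int = 0
    prob_gamma1: float = 0.1
    jitter: float = 1e-4
    group_sweeps: int = 3
    thin: int = 1
    rhat_warn: float = 1.01
    ess_warn: float = 400.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need n_chains >= 2 for convergence diagnostics")
        if self.n_draws < 1 or self.n_warmup < 0 or self.thin < 1:
            raise ValueError("invalid chain length settings")


class PosteriorSamples:
    """Labelled posterior draws with convergence diagnostics.

    ``draws`` maps parameter name -> array of shape ``(chains, draws)``.
    Extra unlabelled state (participant-block arrays used by posterior
    prediction) rides along in ``extra``.
    """

    def __init__(self, draws: dict[str, np.ndarray], seed: int,
                 config: SamplerConfig | None = None, extra: dict | None = None):
        names = list(draws)
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        for k, v in draws.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite draws for parameter {k!r}")
        self.draws = {k: np.asarray(v) for k, v in draws.items()}
        self.seed = seed
        self.config = config
        self.extra = extra or {}
        self._diag: pd.DataFrame | None = None

    def __contains__(self, name: str) -> bool:
        return name in self.draws

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    @property
    def param_names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All draws of one parameter, chains concatenated."""
        return self.draws[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws: chain, draw, one column per parameter."""
        c, t = self.n_chains, self.n_draws
        data = {"chain": np.repeat(np.arange(c), t), "draw": np.tile(np.arange(t), c)}
        for k, v in self.draws.items():
            data[k] = v.reshape(-1)
        return pd.DataFrame(data)

    def diagnostics(self, warn: bool = True) -> pd.DataFrame:
        """Per-parameter mean, SD, split R-hat and bulk ESS."""
        if self._diag is None:
            idata = az.from_dict(posterior={k: v for k, v in self.draws.items()})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = az.rhat(idata)
                ess = az.ess(idata)
            rows = []
            for k, v in self.draws.items():
                rows.append(
                    {
                        "parameter": k,
                        "mean": float(v.mean()),
                        "sd": float(v.std()),
                        "rhat": float(rhat[k].values),
                        "ess_bulk": float(ess[k].values),
                    }
                )
            self._diag = pd.DataFrame(rows).set_index("parameter")
        if warn and self.config is not None:
            bad_r = self._diag[self._diag["rhat"] > self.config.rhat_warn]
            if len(bad_r):
                warnings.warn(
                    f"{len(bad_r)} parameter(s) with R-hat > {self.config.rhat_warn}: "
                    f"worst {bad_r['rhat'].max():.3f}"
                )
            bad_e = self._diag[self._diag["ess_bulk"] < self.config.ess_warn]
            if len(bad_e):
                warnings.warn(
                    f"{len(bad_e)} parameter(s) with bulk ESS < {self.config.ess_warn:.0f}: "
                    f"worst {bad_e['ess_bulk'].min():.0f}"
                )
        return self._diag

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class DensityModel:
    """Adapter giving any vectorised log density the model protocol.

    ``log_density`` takes an array of points ``(n, k)`` and returns ``(n,)``
    log densities; ``init`` draws ``(n, k)`` starting points.
    """

    def __init__(self, param_names, log_density, init):
        self.param_names = list(param_names)
        self._logd = log_density
        self._init = init

    def log_density(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(self._logd(np.atleast_2d(points)), dtype=float)

    def initial_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.asarray(self._init(n, rng), dtype=float)

    def log_joint(self, vec) -> float:
        if isinstance(vec, dict):
            vec = np.array([vec[k] for k in self.param_names], dtype=float)
        return float(self.log_density(np.atleast_2d(vec))[0])


def _de_proposal(state: np.ndarray, rng: np.random.Generator,
                 prob_gamma1: float, jitter: float) -> np.ndarray:
    """One DE proposal per row of ``state`` (chains on the leading axis)."""
    n, k = state.shape
    r1 = rng.integers(0, n - 1, size=n)
    r1 = r1 + (r1 >= np.arange(n))
    r2 = rng.integers(0, n - 2, size=n)
    lo, hi = np.minimum(np.arange(n), r1), np.maximum(np.arange(n), r1)
    r2 = r2 + (r2 >= lo)
    r2 = r2 + (r2 >= hi)
    gamma = np.where(rng.random(n) < prob_gamma1, 1.0, 2.38 / np.sqrt(2.0 * k))
    eps = rng.uniform(-jitter, jitter, size=(n, k))
    return state + gamma[:, None] * (state[r1] - state[r2]) + eps


def _sample_generic(model, config: SamplerConfig, rng: np.random.Generator):
    state = model.initial_points(config.n_chains, rng)
    logp = model.log_density(state)
    for attempt in range(10):
        bad = ~np.isfinite(logp)
        if not bad.any():
            break
        state[bad] = model.initial_points(int(bad.sum()), rng)
        logp[bad] = model.log_density(state[bad])
    else:
        if not np.all(np.isfinite(logp)):
            j = int(np.nonzero(~np.isfinite(logp))[0][0])
            raise RuntimeError(
                "non-finite log density at initialisation after 10 retries; "
                f"first offending point: {dict(zip(model.param_names, state[j]))}"
            )
    total = config.n_warmup + config.n_draws * config.thin
    kept = np.empty((config.n_chains, config.n_draws, state.shape[1]))
    j = 0
    for it in range(total):
        prop = _de_proposal(state, rng, config.prob_gamma1, config.jitter)
        lp = model.log_density(prop)
        accept = np.log(rng.random(config.n_chains)) < lp - logp
        state[accept] = prop[accept]
        logp[accept] = lp[accept]
        if it >= config.n_warmup and (it - config.n_warmup) % config.thin == 0:
            kept[:, j] = state
            j += 1
    return kept[:, :j]


def _blocked_de(idx_n: int, rng: np.random.Generator):
    """Random distinct (r1, r2) chain indices per row, both != row index."""
    r1 = rng.integers(0, idx_n - 1, size=idx_n)
    r1 = r1 + (r1 >= np.arange(idx_n))
    r2 = rng.integers(0, idx_n - 2, size=idx_n)
    lo, hi = np.minimum(np.arange(idx_n), r1), np.maximum(np.arange(idx_n), r1)
    r2 = r2 + (r2 >= lo)
    r2 = r2 + (r2 >= hi)
    return r1, r2


def _sample_hierarchical(model: HierarchicalLBAModel, config: SamplerConfig,
                         rng: np.random.Generator):
    C, P, K = config.n_chains, model.n_participants, model.k_part
    G = model.n_group

    # Initialise every chain from a tight jitter around one plausible point
    # (the DE population then expands to posterior scale during warmup);
    # overdispersed prior starts leave the population too spread for DE
    # proposals to be accepted. The start respects each participant's
    # fastest RT, which upper-bounds their nondecision time.
    min_rt = np.minimum.reduceat(model.rt, model.offsets)
    start = np.empty((P, K))
    start[:, 0] = 0.3                        # A
    start[:, 1] = np.minimum(0.8 * min_rt, 0.5)  # t0
    start[:, 2] = 2.0                        # rate sum
    start[:, 3:7] = 0.6                      # B_c
    start[:, 7:11] = 1.0                     # d_c
    part = start[None] * (1.0 + 0.05 * rng.standard_normal((C, P, K)))
    part[..., 1] = np.minimum(part[..., 1], 0.9 * min_rt)
    group = np.empty((C, G))
    group[:, :K] = part.mean(axis=1)
    group[:, K:2 * K] = 0.15 * (1.0 + 0.1 * rng.standard_normal((C, K)))
    if G > 2 * K:
        group[:, 2 * K:] = 0.01 * rng.standard_normal((C, G - 2 * K))

    loglik = model.log_likelihood_participants(part)
    for _ in range(10):
        bad = ~np.isfinite(loglik)
        if not bad.any():
            break
        resampled = start[None] * (1.0 + 0.05 * rng.standard_normal((C, P, K)))
        resampled[..., 1] = np.minimum(resampled[..., 1], 0.9 * min_rt)
        part = np.where(bad[:, :, None], resampled, part)
        loglik = model.log_likelihood_participants(part)
    if not np.all(np.isfinite(loglik)):
        ci, pi = np.argwhere(~np.isfinite(loglik))[0]
        raise RuntimeError(
            "non-finite likelihood at initialisation after 10 retries "
            f"(participant {model.participant_ids[pi]!r}); check RTs against t0"
        )
    logprior_part = model.log_prior_participants(part, group)
    logprior_group = model.log_prior_group(group)

    total = config.n_warmup + config.n_draws * config.thin
    kept_group = np.empty((C, config.n_draws, G))
    kept_part = np.empty((C, config.n_draws, P, K))
    # step-size multipliers, adapted toward ~25% acceptance during warmup
    scale_p = 1.0
    scale_g = np.ones(K)
    scale_nc = 1.0
    acc_accum_p = 0.0
    acc_accum_g = np.zeros(K)
    acc_accum_nc = 0.0
    adapt_every = 25
    j = 0
    for it in range(total):
        # --- participant blocks: DREAM-style move per (chain, participant):
        # a DE jump restricted to a random subspace of the 11 parameters
        # (crossover), which keeps acceptance healthy on the correlated
        # threshold/rate/nondecision ridge.
        r1, r2 = _blocked_de(C, rng)
        cr = rng.choice([0.4, 0.7, 1.0], size=(C, P, 1))
        mask = rng.random((C, P, K)) < cr
        none_sel = ~mask.any(axis=-1)
        mask[none_sel] = True
        d_sel = mask.sum(axis=-1)
        g = np.where(
            rng.random((C, P)) < config.prob_gamma1,
            1.0,
            scale_p * 2.38 / np.sqrt(2.0 * d_sel),
        )
        eps = rng.uniform(-config.jitter, config.jitter, size=(C, P, K))
        step = g[:, :, None] * (part[r1] - part[r2]) + eps
        prop = part + np.where(mask, step, 0.0)
        lp_prior = model.log_prior_participants(prop, group)
        ok = np.isfinite(lp_prior)
        ll_prop = np.full((C, P), -np.inf)
        if ok.any():
            ll_all = model.log_likelihood_participants(prop)
            ll_prop = np.where(ok, ll_all, -np.inf)
        accept = np.log(rng.random((C, P))) < (lp_prior + ll_prop) - (
            logprior_part + loglik
        )
        part = np.where(accept[:, :, None], prop, part)
        loglik = np.where(accept, ll_prop, loglik)
        logprior_part = np.where(accept, lp_prior, logprior_part)
        acc_accum_p += accept.mean()

        # --- group block: conditional on participants the group posterior
        # factorises over parameter types, so update each (mu_k, sigma_k
        # [, beta_k]) sub-block independently; no likelihood re-evaluation.
        for _ in range(config.group_sweeps):
            for k in range(K):
                idx = model.group_block_indices(k)
                cur_lp = model.group_column_logpdf(part, group, k)
                r1, r2 = _blocked_de(C, rng)
                sub = group[:, idx]
                g = np.where(
                    rng.random(C) < config.prob_gamma1,
                    1.0,
                    scale_g[k] * 2.38 / np.sqrt(2.0 * len(idx)),
                )
                prop_sub = (
                    sub
                    + g[:, None] * (sub[r1] - sub[r2])
                    + rng.uniform(-config.jitter, config.jitter, size=sub.shape)
                )
                gprop = group.copy()
                gprop[:, idx] = prop_sub
                new_lp = model.group_column_logpdf(part, gprop, k)
                acc = np.log(rng.random(C)) < new_lp - cur_lp
                group[np.ix_(acc, idx)] = prop_sub[acc]
                acc_accum_g[k] += acc.mean() / config.group_sweeps
        logprior_group = model.log_prior_group(group)
        logprior_part = model.log_prior_participants(part, group)

        # --- non-centered group move: propose a new group block and carry
        # every participant block along through theta' = loc' + (sigma' /
        # sigma) (theta - loc). This moves the whole population across the
        # group-mean ridge and through the sigma funnel, where the centered
        # updates above stall. Deterministic-map MH with Jacobian
        # P * sum_k log(sigma'_k / sigma_k); costs one likelihood pass.
        r1, r2 = _blocked_de(C, rng)
        cr_nc = rng.choice([0.3, 0.6, 1.0], size=(C, 1))
        mask_nc = rng.random((C, G)) < cr_nc
        none_nc = ~mask_nc.any(axis=-1)
        mask_nc[none_nc] = True
        d_nc = mask_nc.sum(axis=-1)
        gnc = np.where(
            rng.random(C) < config.prob_gamma1,
            1.0,
            scale_nc * 2.38 / np.sqrt(2.0 * d_nc),
        )
        step_nc = gnc[:, None] * (group[r1] - group[r2]) + rng.uniform(
            -config.jitter, config.jitter, size=(C, G)
        )
        gprop = group + np.where(mask_nc, step_nc, 0.0)
        sig_old = group[:, K:2 * K]
        sig_new = gprop[:, K:2 * K]
        valid = (sig_new > 0).all(axis=1)
        sig_new_safe = np.where(sig_new > 0, sig_new, 1.0)
        ratio = sig_new_safe / sig_old
        loc_old = model.participant_means(group)
        loc_new = model.participant_means(gprop)
        part_prop = loc_new + ratio[:, None, :] * (part - loc_old)
        hyper_new = np.where(valid, model.log_prior_group(gprop), -np.inf)
        hier_new = model.log_prior_participants(part_prop, gprop)
        ll_new = np.where(
            np.isfinite(hier_new), model.log_likelihood_participants(part_prop), -np.inf
        )
        jac = P * np.log(ratio).sum(axis=1)
        log_alpha = (
            ll_new.sum(axis=1) + hier_new.sum(axis=1) + hyper_new + jac
        ) - (loglik.sum(axis=1) + logprior_part.sum(axis=1) + logprior_group)
        acc_nc = np.log(rng.random(C)) < log_alpha
        part = np.where(acc_nc[:, None, None], part_prop, part)
        group = np.where(acc_nc[:, None], gprop, group)
        loglik = np.where(acc_nc[:, None], ll_new, loglik)
        logprior_part = np.where(acc_nc[:, None], hier_new, logprior_part)
        logprior_group = np.where(acc_nc, hyper_new, logprior_group)
        acc_accum_nc += acc_nc.mean()

        # Robbins-Monro step-size adaptation, frozen after warmup
        if it < config.n_warmup and (it + 1) % adapt_every == 0:
            rate_p = acc_accum_p / adapt_every
            scale_p = float(np.clip(scale_p * np.exp(rate_p - 0.25), 0.1, 3.0))
            rate_g = acc_accum_g / adapt_every
            scale_g = np.clip(scale_g * np.exp(rate_g - 0.3), 0.1, 3.0)
            rate_nc = acc_accum_nc / adapt_every
            scale_nc = float(np.clip(scale_nc * np.exp(rate_nc - 0.25), 0.05, 3.0))
            acc_accum_p = 0.0
            acc_accum_g[:] = 0.0
            acc_accum_nc = 0.0

        if it >= config.n_warmup and (it - config.n_warmup) % config.thin == 0:
            kept_group[:, j] = group
            kept_part[:, j] = part
            j += 1

    draws: dict[str, np.ndarray] = {}
    for gi, name in enumerate(model.spec.group_param_names):
        draws[name] = kept_group[:, :j, gi]
    # group-level derived thresholds b_c = mu_A + mu_B[c] are left to callers;
    # participant blocks are exported under indexed names
    for pi, pid in enumerate(model.participant_ids):
        for ki, pname in enumerate(PARTICIPANT_PARAMS):
            draws[f"{pname}[{pid}]"] = kept_part[:, :j, pi, ki]
    extra = {
        "participant_ids": list(model.participant_ids),
        "participant_param_names": list(PARTICIPANT_PARAMS),
        "participant_draws": kept_part[:, :j],
        "conditions": list(model.conditions),
    }
    return draws, extra


def sample_posterior(model, config: SamplerConfig | None = None) -> PosteriorSamples:
    """Draw posterior samples from a model's log joint density.

    Hierarchical LBA models use the blocked participant/group scheme; any
    other object with ``param_names``, ``log_density`` and
    ``initial_points`` is sampled with plain population DE-MCMC.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    if isinstance(model, HierarchicalLBAModel):
        draws, extra = _sample_hierarchical(model, config, rng)
        return PosteriorSamples(draws, seed=config.seed, config=config, extra=extra)
    kept = _sample_generic(model, config, rng)
    draws = {n: kept[:, :, i] for i, n in enumerate(model.param_names)}
    return PosteriorSamples(draws, seed=config.seed, config=config)


def prior_samples(spec: GroupModelSpec, n: int = 10000,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
    """Independent draws from the priors over group means (and betas).

    Used to form Savage-Dickey prior densities of derived effects (condition
    differences are obtained by differencing the relevant columns).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in PARTICIPANT_PARAMS:
        out[f"mu_{name}"] = spec.mean_prior(name).rvs(n, rng)
    for name in spec.beta_names:
        out[name] = spec.prior_beta.rvs(n, rng)
    return out
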