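"""Hierarchical Bayesian LBA with condition-specific threshold and effort.

Model structure
---------------
For participant ``p`` in condition ``c`` the decision model is a
two-accumulator LBA with

* threshold ``b_{p,c} = A_p + B_{p,c}`` (``B > 0`` keeps ``b >= A``),
* drift rates from the participant's shared rate sum ``s_p`` and the
  condition-specific rate difference ``d_{p,c}``:
  ``v_correct = (s + d)/2``, ``v_error = (s - d)/2``,
* shared start-point range ``A_p`` and nondecision time ``t0_p``,
* drift SD fixed to 1 for identifiability.

Threshold offsets and rate differences vary over the four competition
conditions; ``A``, ``t0`` and the rate sum are constrained equal across
conditions within a participant. Participant parameters are drawn from
normal group distributions (truncated to positive support for ``A``,
``t0``, ``s`` and ``B``), optionally shifted by a linear effect of the
standardised trait-competitiveness score ``z_p``:
``B_{p,c} ~ N+(mu_B[c] + beta_B[c] * z_p, sigma_B[c])`` and likewise for
``d``. Group means and SDs carry weakly-informative truncated-normal and
half-normal priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import truncnorm

from lbacomp.lba import _window_mass_arrays, defective_logpdf_arrays
from lbacomp._kernels import loglik_reduce
from lbacomp.schemes import CONDITIONS

__all__ = [
    "PriorSpec",
    "GroupModelSpec",
    "HierarchicalLBAModel",
    "rates_from_sum_diff",
    "rates_to_sum_diff",
    "build_model",
    "condition_effects",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: Participant-level parameter layout: shared block then per-condition blocks.
PARTICIPANT_PARAMS = (
    ["A", "t0", "s"]
    + [f"B[{c}]" for c in CONDITIONS]
    + [f"d[{c}]" for c in CONDITIONS]
)
#: Which entries of the participant block are constrained positive.
PARTICIPANT_POSITIVE = np.array(
    [True, True, True] + [True] * 4 + [False] * 4
)


def rates_from_sum_diff(s, d):
    """Map (rate sum, rate difference) to (v_correct, v_error)."""
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    v_c = (s + d) / 2.0
    v_e = (s - d) / 2.0
    if v_c.ndim == 0:
        return float(v_c), float(v_e)
    return v_c, v_e


def rates_to_sum_diff(v_correct, v_error):
    """Inverse of :func:`rates_from_sum_diff`."""
    v_c = np.asarray(v_correct, dtype=float)
    v_e = np.asarray(v_error, dtype=float)
    s = v_c + v_e
    d = v_c - v_e
    if s.ndim == 0:
        return float(s), float(d)
    return s, d


@dataclass(frozen=True)
class PriorSpec:
    """A (possibly truncated) normal prior."""

    mean: float
    sd: float
    lower: float | None = None  # truncation bound; None = unconstrained

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.mean) / self.sd
        lp = -0.5 * z * z - np.log(self.sd) - _LOG_SQRT_2PI
        if self.lower is not None:
            lp = np.where(x > self.lower, lp - log_ndtr((self.mean - self.lower) / self.sd), -np.inf)
        return lp

    def rvs(self, size, rng: np.random.Generator):
        if self.sd == 0:
            return np.full(size, self.mean)
        if self.lower is None:
            return rng.normal(self.mean, self.sd, size=size)
        a = (self.lower - self.mean) / self.sd
        return truncnorm.rvs(a, np.inf, loc=self.mean, scale=self.sd, size=size,
                             random_state=rng)

    def analytic_mean(self) -> float:
        if self.lower is None:
            return self.mean
        a = (self.lower - self.mean) / self.sd
        return float(truncnorm.mean(a, np.inf, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class GroupModelSpec:
    """Priors and structure of the hierarchical model.

    Defaults are weakly informative on the scale of typical LBA fits;
    every prior is configurable. ``covariate=True`` adds a slope ``beta``
    for standardised trait competitiveness on each condition's threshold
    offset and rate difference. ``rt_window`` conditions every trial
    density on the RT analysis window, so that excluding outlier RTs in
    preprocessing does not bias the fitted rates.
    """

    conditions: tuple = CONDITIONS
    prior_mean_A: PriorSpec = PriorSpec(0.5, 0.3, lower=0.0)
    prior_mean_t0: PriorSpec = PriorSpec(0.3, 0.15, lower=0.0)
    prior_mean_s: PriorSpec = PriorSpec(2.0, 1.0, lower=0.0)
    prior_mean_B: PriorSpec = PriorSpec(0.5, 0.5, lower=0.0)
    prior_mean_d: PriorSpec = PriorSpec(1.0, 1.0)
    prior_group_sd: PriorSpec = PriorSpec(0.0, 0.3, lower=0.0)  # half-normal
    prior_beta: PriorSpec = PriorSpec(0.0, 0.5)
    covariate: bool = False
    s_v: float = 1.0
    #: RT analysis window (s): the likelihood is conditioned on trials
    #: falling inside it, matching the preprocessing exclusions. None
    #: disables the truncation correction.
    rt_window: tuple | None = (0.25, 5.0)

    def mean_prior(self, name: str) -> PriorSpec:
        if name == "A":
            return self.prior_mean_A
        if name == "t0":
            return self.prior_mean_t0
        if name == "s":
            return self.prior_mean_s
        if name.startswith("B["):
            return self.prior_mean_B
        if name.startswith("d["):
            return self.prior_mean_d
        raise KeyError(name)

    @property
    def group_mean_names(self) -> list[str]:
        return [f"mu_{n}" for n in PARTICIPANT_PARAMS]

    @property
    def group_sd_names(self) -> list[str]:
        return [f"sigma_{n}" for n in PARTICIPANT_PARAMS]

    @property
    def beta_names(self) -> list[str]:
        if not self.covariate:
            return []
        return [f"beta_B[{c}]" for c in self.conditions] + [
            f"beta_d[{c}]" for c in self.conditions
        ]

    @property
    def group_param_names(self) -> list[str]:
        return self.group_mean_names + self.group_sd_names + self.beta_names


def _truncnorm_logpdf(x, mean, sd, positive_mask):
    """Participant-level hierarchy density; truncated at 0 where masked."""
    z = (x - mean) / sd
    lp = -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI
    norm = np.where(positive_mask, log_ndtr(mean / sd), 0.0)
    lp = lp - norm
    invalid = positive_mask & (x <= 0)
    return np.where(invalid, -np.inf, lp)


class HierarchicalLBAModel:
    """Log joint density of the hierarchical LBA over named parameters.

    Exposes both a flat "named vector" interface (``param_names`` /
    ``log_joint``) and the blocked structure (participant blocks plus a
    group block) that the blocked DE-MCMC sampler exploits.
    """

    def __init__(self, trials: pd.DataFrame, spec: GroupModelSpec,
                 competitiveness: np.ndarray | None = None):
        self.spec = spec
        self.conditions = list(spec.conditions)
        required = {"participant_id", "condition", "correct", "rt_ms"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        self.participant_ids = sorted(trials["participant_id"].unique())
        self.n_participants = len(self.participant_ids)
        pindex = {p: i for i, p in enumerate(self.participant_ids)}
        cindex = {c: i for i, c in enumerate(self.conditions)}
        bad = set(trials["condition"]) - set(self.conditions)
        if bad:
            raise ValueError(f"unknown conditions in data: {sorted(bad)}")
        per = trials.groupby(["participant_id", "condition"], observed=True).size()
        for p in self.participant_ids:
            have = set(per.loc[p].index) if p in per.index.get_level_values(0) else set()
            if set(self.conditions) - have:
                raise ValueError(
                    f"participant {p!r} has no trials in condition(s) "
                    f"{sorted(set(self.conditions) - have)}"
                )
        order = np.argsort(trials["participant_id"].map(pindex).to_numpy(), kind="stable")
        t = trials.iloc[order]
        self.rt = t["rt_ms"].to_numpy(dtype=float) / 1000.0
        self.correct = t["correct"].to_numpy(dtype=bool)
        self.cond_idx = t["condition"].map(cindex).to_numpy(dtype=np.int64)
        self.part_idx = t["participant_id"].map(pindex).to_numpy(dtype=np.int64)
        # reduceat boundaries: trials sorted by participant
        counts = np.bincount(self.part_idx, minlength=self.n_participants)
        if self.n_participants and (counts == 0).any():
            raise ValueError("participant with zero trials")
        self.offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        # trials per participant x condition, for the window-mass term
        self.n_pc = np.zeros((self.n_participants, len(self.conditions)))
        np.add.at(self.n_pc, (self.part_idx, self.cond_idx), 1.0)
        if spec.rt_window is not None:
            lo, hi = spec.rt_window
            if (self.rt <= lo).any() or (self.rt >= hi).any():
                raise ValueError(
                    f"trial RTs outside the model's analysis window ({lo}, {hi}) s; "
                    "apply matching exclusions first or set rt_window=None"
                )

        if competitiveness is not None:
            zc = np.asarray(competitiveness, dtype=float)
            if zc.shape != (self.n_participants,):
                raise ValueError(
                    f"competitiveness must have one score per participant "
                    f"({self.n_participants}), got shape {zc.shape}"
                )
            sd = zc.std()
            self.z = (zc - zc.mean()) / sd if sd > 0 else np.zeros_like(zc)
        else:
            if spec.covariate:
                raise ValueError("covariate=True requires competitiveness scores")
            self.z = np.zeros(self.n_participants)

        self.k_part = len(PARTICIPANT_PARAMS)
        self.n_group = len(spec.group_param_names)
        self._names = spec.group_param_names + [
            f"{n}[{p}]" for p in self.participant_ids for n in PARTICIPANT_PARAMS
        ]

    # ------------------------------------------------------------------ names
    @property
    def param_names(self) -> list[str]:
        return list(self._names)

    @property
    def n_params(self) -> int:
        return len(self._names)

    # ------------------------------------------------------ blocked densities
    def log_likelihood_participants(self, part: np.ndarray) -> np.ndarray:
        """Trial log likelihood per participant.

        ``part`` has shape ``(..., P, K)`` with the participant-parameter
        layout of :data:`PARTICIPANT_PARAMS`; returns shape ``(..., P)``.
        Trial densities are summed in a fused numba kernel; the RT-window
        truncation term, constant within a participant x condition cell,
        is added per cell rather than per trial.
        """
        part = np.asarray(part, dtype=float)
        lead = part.shape[:-2]
        if self.n_participants == 0:  # prior-only model (no data)
            return np.zeros(lead + (0,))
        blocks = np.ascontiguousarray(part.reshape((-1,) + part.shape[-2:]))
        out = np.zeros((blocks.shape[0], self.n_participants))
        loglik_reduce(
            self.rt, self.correct, self.part_idx, self.cond_idx,
            blocks, float(self.spec.s_v), True, out,
        )
        if self.spec.rt_window is not None:
            lo, hi = self.spec.rt_window
            A = blocks[..., 0:1]
            t0 = blocks[..., 1:2]
            s = blocks[..., 2:3]
            B = blocks[..., 3:7]
            d = blocks[..., 7:11]
            with np.errstate(invalid="ignore", divide="ignore"):
                mass = _window_mass_arrays(
                    A + B, A, (s + d) / 2.0, (s - d) / 2.0,
                    self.spec.s_v, t0, lo, hi, True,
                )
                bad = ((mass <= 0.0) & (self.n_pc > 0)).any(axis=-1)
                term = np.where(
                    self.n_pc > 0, self.n_pc * np.log(np.maximum(mass, 1e-300)), 0.0
                ).sum(axis=-1)
            out = np.where(bad, -np.inf, out - term)
        return out.reshape(*lead, self.n_participants) if lead else out[0]

    def split_group(self, group: np.ndarray):
        """Split a group vector ``(..., G)`` into means, SDs, betas ``(..., K)``."""
        k = self.k_part
        mu = group[..., :k]
        sigma = group[..., k:2 * k]
        if self.spec.covariate:
            beta_B = group[..., 2 * k:2 * k + 4]
            beta_d = group[..., 2 * k + 4:2 * k + 8]
        else:
            beta_B = beta_d = None
        return mu, sigma, beta_B, beta_d

    def participant_means(self, group: np.ndarray) -> np.ndarray:
        """Hierarchy location per participant: ``mu`` plus covariate shift.

        ``group``: ``(..., G)``; returns ``(..., P, K)``.
        """
        mu, _, beta_B, beta_d = self.split_group(group)
        loc = np.broadcast_to(
            mu[..., None, :], mu.shape[:-1] + (self.n_participants, self.k_part)
        ).copy()
        if beta_B is not None:
            z = self.z  # (P,)
            loc[..., 3:7] = loc[..., 3:7] + beta_B[..., None, :] * z[:, None]
            loc[..., 7:11] = loc[..., 7:11] + beta_d[..., None, :] * z[:, None]
        return loc

    def log_prior_participants_per_param(self, part: np.ndarray,
                                         group: np.ndarray) -> np.ndarray:
        """Hierarchy density per participant and parameter: ``(..., P, K)``.

        Given the participant blocks, this factorises over the parameter
        axis ``K`` — the group posterior for ``(mu_k, sigma_k, beta_k)``
        depends only on column ``k`` — which the sampler exploits with
        small independent group updates.
        """
        _, sigma, _, _ = self.split_group(group)
        loc = self.participant_means(group)
        with np.errstate(invalid="ignore", divide="ignore"):
            return _truncnorm_logpdf(part, loc, sigma[..., None, :], PARTICIPANT_POSITIVE)

    def log_prior_participants(self, part: np.ndarray, group: np.ndarray) -> np.ndarray:
        """Hierarchy density of participant blocks given the group block.

        ``part``: ``(..., P, K)``, ``group``: ``(..., G)`` -> ``(..., P)``.
        """
        return self.log_prior_participants_per_param(part, group).sum(axis=-1)

    def log_prior_group_per_param(self, group: np.ndarray) -> np.ndarray:
        """Hyperprior density split by parameter type: ``(..., K)``.

        Column ``k`` carries the priors of ``mu_k``, ``sigma_k`` and, when
        the covariate is active and ``k`` is a ``B``/``d`` column, of the
        matching ``beta``.
        """
        mu, sigma, beta_B, beta_d = self.split_group(group)
        cols = []
        for j, name in enumerate(PARTICIPANT_PARAMS):
            cols.append(self.spec.mean_prior(name).logpdf(mu[..., j]))
        lp = np.stack(cols, axis=-1)
        # half-normal on SDs
        sd_prior = self.spec.prior_group_sd
        with np.errstate(invalid="ignore", divide="ignore"):
            z = sigma / sd_prior.sd
            lp_sd = np.where(
                sigma > 0,
                -0.5 * z * z - np.log(sd_prior.sd) - _LOG_SQRT_2PI + np.log(2.0),
                -np.inf,
            )
        lp = lp + lp_sd
        if beta_B is not None:
            lp[..., 3:7] = lp[..., 3:7] + self.spec.prior_beta.logpdf(beta_B)
            lp[..., 7:11] = lp[..., 7:11] + self.spec.prior_beta.logpdf(beta_d)
        return lp

    def log_prior_group(self, group: np.ndarray) -> np.ndarray:
        """Hyperprior density of the group block ``(..., G)`` -> ``(...)``."""
        return self.log_prior_group_per_param(group).sum(axis=-1)

    def group_block_indices(self, k: int) -> list[int]:
        """Indices into the group vector owned by parameter type ``k``."""
        idx = [k, self.k_part + k]
        if self.spec.covariate and k >= 3:
            idx.append(2 * self.k_part + (k - 3))
        return idx

    def group_column_logpdf(self, part: np.ndarray, group: np.ndarray,
                            k: int) -> np.ndarray:
        """Group-posterior factor for parameter type ``k`` (up to the
        likelihood, which does not involve the group block).

        ``part``: ``(..., P, K)``, ``group``: ``(..., G)`` -> ``(...)``.
        """
        K = self.k_part
        mu = group[..., k]
        sigma = group[..., K + k]
        beta = None
        if self.spec.covariate and k >= 3:
            beta = group[..., 2 * K + (k - 3)]
        x = part[..., k]
        loc = mu[..., None] + (beta[..., None] * self.z if beta is not None else 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            lp = _truncnorm_logpdf(
                x, loc, sigma[..., None], PARTICIPANT_POSITIVE[k]
            ).sum(axis=-1)
            lp = lp + self.spec.mean_prior(PARTICIPANT_PARAMS[k]).logpdf(mu)
            sd = self.spec.prior_group_sd.sd
            z2 = sigma / sd
            lp = lp + np.where(
                sigma > 0,
                -0.5 * z2 * z2 - np.log(sd) - _LOG_SQRT_2PI + np.log(2.0),
                -np.inf,
            )
        if beta is not None:
            lp = lp + self.spec.prior_beta.logpdf(beta)
        return lp

    # ------------------------------------------------------------- flat joint
    def log_joint(self, params) -> float:
        """Log joint density at a named parameter point.

        ``params`` is a dict name -> value or a flat vector ordered as
        ``param_names``. Returns ``-inf`` outside the support.
        """
        if isinstance(params, dict):
            vec = np.array([params[n] for n in self._names], dtype=float)
        else:
            vec = np.asarray(params, dtype=float)
            if vec.shape != (self.n_params,):
                raise ValueError(f"expected vector of length {self.n_params}")
        group = vec[: self.n_group]
        part = vec[self.n_group:].reshape(self.n_participants, self.k_part)
        lp = self.log_prior_group(group)
        if not np.isfinite(lp):
            return float(lp)
        lp = lp + self.log_prior_participants(part, group).sum()
        if not np.isfinite(lp):
            return float(lp)
        ll = self.log_likelihood_participants(part).sum()
        return float(lp + ll)

    # ------------------------------------------------------- initialisation
    def sample_group_from_prior(self, size, rng: np.random.Generator) -> np.ndarray:
        cols = []
        for name in PARTICIPANT_PARAMS:
            cols.append(self.spec.mean_prior(name).rvs(size, rng))
        for _ in PARTICIPANT_PARAMS:
            cols.append(np.abs(rng.normal(0.0, self.spec.prior_group_sd.sd, size=size)))
        if self.spec.covariate:
            for _ in range(8):
                cols.append(self.spec.prior_beta.rvs(size, rng))
        return np.stack(cols, axis=-1)

    def sample_participants_given_group(self, group: np.ndarray,
                                        rng: np.random.Generator) -> np.ndarray:
        """Draw participant blocks from the hierarchy, shape follows group."""
        _, sigma, _, _ = self.split_group(group)
        loc = self.participant_means(group)
        sig = np.broadcast_to(sigma[..., None, :], loc.shape)
        out = rng.normal(loc, np.maximum(sig, 1e-6))
        bad = PARTICIPANT_POSITIVE & (out <= 0)
        tries = 0
        while bad.any() and tries < 200:
            out = np.where(bad, rng.normal(loc, np.maximum(sig, 1e-6)), out)
            bad = PARTICIPANT_POSITIVE & (out <= 0)
            tries += 1
        if bad.any():
            out = np.where(bad, np.abs(loc) + 0.05, out)
        return out


def build_model(
    trials: pd.DataFrame,
    competitiveness=None,
    spec: GroupModelSpec | None = None,
) -> HierarchicalLBAModel:
    """Assemble the hierarchical LBA for a preprocessed trial table.

    ``competitiveness`` maps participants to trait scores (dict, Series
    indexed by participant id, or array in sorted-participant order); it is
    standardised internally. Every participant must have trials in every
    condition.
    """
    spec = spec or GroupModelSpec()
    if competitiveness is not None and not isinstance(competitiveness, np.ndarray):
        ids = sorted(trials["participant_id"].unique())
        if isinstance(competitiveness, dict):
            competitiveness = np.array([competitiveness[p] for p in ids], dtype=float)
        else:
            ser = pd.Series(competitiveness)
            competitiveness = ser.reindex(ids).to_numpy(dtype=float)
            if np.isnan(competitiveness).any():
                raise ValueError("competitiveness missing for some participants")
    if (pd.to_numeric(trials["rt_ms"]) <= 0).any():
        warnings.warn("trial table contains nonpositive RTs; they yield -inf likelihood")
    return HierarchicalLBAModel(trials, spec, competitiveness)


def condition_effects(samples, reference: str = "dyb") -> dict[str, np.ndarray]:
    """Per-draw condition effects relative to the reference condition.

    Returns draws of ``db_<c> = mu_b[c] - mu_b[ref]`` (threshold; the shared
    ``A`` cancels, so this equals the difference of threshold offsets) and
    ``dd_<c> = mu_d[c] - mu_d[ref]`` (rate difference), for each
    non-reference condition.
    """
    def get(name):
        try:
            return samples.stacked(name) if hasattr(samples, "stacked") else np.asarray(samples[name])
        except KeyError as e:
            raise KeyError(f"posterior draws are missing parameter {name!r}") from e

    out = {}
    ref_B = get(f"mu_B[{reference}]")
    ref_d = get(f"mu_d[{reference}]")
    for c in CONDITIONS:
        if c == reference:
            continue
        out[f"db_{c}"] = get(f"mu_B[{c}]") - ref_B
        out[f"dd_{c}"] = get(f"mu_d[{c}]") - ref_d
    return out
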