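"""Savage-Dickey density-ratio Bayes factors and evidence labels.

For a point null ``theta = 0`` nested in a model with prior ``p(theta)``,
the Bayes factor in favour of an effect is

    BF = p(theta = 0) / p(theta = 0 | data),

the prior density at the null divided by the posterior density at the
null. BF > 1 favours a difference, BF < 1 favours the null; the reciprocal
is always reported alongside. Evidence-strength labels follow the usual
1/3/10/30/100 bands (anecdotal / moderate / strong / very strong /
extreme), mirrored for evidence of no effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde, norm

from lbacomp.model import GroupModelSpec
from lbacomp.sampling import PosteriorSamples

__all__ = [
    "BayesFactorResult",
    "savage_dickey",
    "classify_evidence",
    "joint_savage_dickey",
    "covariate_bf",
]


@dataclass(frozen=True)
class BayesFactorResult:
    bf: float
    hypothesis_pair: str
    posterior_density_at_null: float
    prior_density_at_null: float
    method: str
    label: str

    @property
    def reciprocal(self) -> float:
        return np.inf if self.bf == 0 else 1.0 / self.bf

    def __str__(self) -> str:  # human-readable table row
        return (
            f"{self.hypothesis_pair}: BF = {self.bf:.4g} "
            f"(1/BF = {self.reciprocal:.4g}) — {self.label}"
        )


def classify_evidence(bf: float) -> str:
    """Evidence-strength label for a Bayes factor oriented toward an effect."""
    if not (bf > 0):
        raise ValueError("Bayes factor must be positive")
    bands = [(100.0, "extreme"), (30.0, "very strong"), (10.0, "strong"),
             (3.0, "moderate"), (1.0, "anecdotal")]
    if bf >= 1.0:
        for cut, word in bands:
            if bf > cut:
                return f"{word} evidence of a difference"
        return "no evidence either way"  # bf == 1 exactly
    inv = 1.0 / bf
    for cut, word in bands:
        if inv > cut:
            return f"{word} evidence of no difference"
    return "no evidence either way"


def _density_at_zero(draws: np.ndarray, method: str, ndim: int = 1) -> float:
    draws = np.asarray(draws, dtype=float)
    if method == "kde":
        kde = gaussian_kde(draws.T if ndim > 1 else draws, bw_method="silverman")
        return float(kde(np.zeros((ndim, 1)))[0])
    if method == "normal-approx":
        if ndim == 1:
            return float(norm.pdf(0.0, loc=draws.mean(), scale=draws.std(ddof=1)))
        mean = draws.mean(axis=0)
        cov = np.cov(draws.T)
        from scipy.stats import multivariate_normal

        return float(multivariate_normal.pdf(np.zeros(ndim), mean=mean, cov=cov))
    raise ValueError(f"unknown density method {method!r}")


def savage_dickey(
    effect_draws: np.ndarray,
    prior_draws: np.ndarray,
    method: str = "kde",
    hypothesis_pair: str = "effect vs no effect",
    prior_density_at_null: float | None = None,
) -> BayesFactorResult:
    """Savage-Dickey Bayes factor for a scalar effect with null at 0.

    Densities at 0 are estimated by Gaussian KDE with Silverman bandwidth
    (default) or by a moment-matched normal. ``prior_density_at_null``
    overrides the prior KDE when the prior density at 0 is known
    analytically. Zero estimated posterior density yields ``inf`` with a
    warning rather than an error.
    """
    effect_draws = np.asarray(effect_draws, dtype=float).reshape(-1)
    prior_draws = np.asarray(prior_draws, dtype=float).reshape(-1)
    if effect_draws.size < 1000 or (
        prior_density_at_null is None and prior_draws.size < 1000
    ):
        warnings.warn("fewer than 1000 draws; Savage-Dickey densities may be unstable")
    post0 = _density_at_zero(effect_draws, method)
    prior0 = (
        float(prior_density_at_null)
        if prior_density_at_null is not None
        else _density_at_zero(prior_draws, method)
    )
    if post0 <= 0.0:
        warnings.warn("estimated posterior density at 0 is zero; BF reported as inf")
        bf = np.inf
    else:
        bf = prior0 / post0
    return BayesFactorResult(
        bf=float(bf),
        hypothesis_pair=hypothesis_pair,
        posterior_density_at_null=post0,
        prior_density_at_null=prior0,
        method=method,
        label=classify_evidence(bf) if np.isfinite(bf) else "extreme evidence of a difference",
    )


def joint_savage_dickey(
    effect_draws_2d: np.ndarray,
    prior_draws_2d: np.ndarray,
    method: str = "kde",
    names: tuple[str, str] = ("threshold", "drift rate"),
) -> list[BayesFactorResult]:
    """Joint Bayes factors over a 2-D effect (threshold, rate difference).

    Four models share equal prior probability: no effect (both components
    null), threshold-only, rate-only, and both free. Savage-Dickey ratios
    give each restricted model's marginal likelihood relative to the
    both-free model:

    * ``w00`` — joint posterior/prior density ratio at (0, 0);
    * ``wb`` — marginal ratio at 0 for the rate component (threshold free);
    * ``wd`` — marginal ratio at 0 for the threshold component (rate free);
    * ``wbd = 1``.

    Each reported Bayes factor is the odds of one model against the
    average of the models in its complement hypothesis.
    """
    post = np.asarray(effect_draws_2d, dtype=float)
    prior = np.asarray(prior_draws_2d, dtype=float)
    if post.ndim != 2 or post.shape[1] != 2 or prior.ndim != 2 or prior.shape[1] != 2:
        raise ValueError("effect and prior draws must have shape (n, 2)")
    if post.shape[0] < 2000 or prior.shape[0] < 2000:
        warnings.warn("fewer than 2000 draws; joint KDE may be unstable")

    def ratio(post_d, prior_d, ndim):
        p0 = _density_at_zero(post_d, method, ndim)
        q0 = _density_at_zero(prior_d, method, ndim)
        if q0 <= 0:
            warnings.warn("prior density at null is zero; ratio reported as inf")
            return np.inf
        return p0 / q0

    w00 = ratio(post, prior, 2)
    wb = ratio(post[:, 1], prior[:, 1], 1)   # rate pinned at 0, threshold free
    wd = ratio(post[:, 0], prior[:, 0], 1)   # threshold pinned at 0, rate free
    wbd = 1.0
    b, d = names

    def result(bf, pair):
        return BayesFactorResult(
            bf=float(bf),
            hypothesis_pair=pair,
            posterior_density_at_null=np.nan,
            prior_density_at_null=np.nan,
            method=method,
            label=classify_evidence(bf) if np.isfinite(bf) and bf > 0 else
            ("extreme evidence of a difference" if bf == np.inf else "extreme evidence of no difference"),
        )

    return [
        result(w00 / ((wb + wd + wbd) / 3.0), "no effect vs at least one effect"),
        result(wb / ((w00 + wbd) / 2.0), f"effect on {b} only vs no effects or both"),
        result(wd / ((w00 + wbd) / 2.0), f"effect on {d} only vs no effects or both"),
        result(wbd / ((w00 + wb + wd) / 3.0), "effect on both vs only one effect or none"),
    ]


def covariate_bf(
    samples: PosteriorSamples,
    spec: GroupModelSpec,
    method: str = "kde",
) -> dict[tuple[str, str], BayesFactorResult]:
    """Bayes factors for the trait-competitiveness slopes being zero.

    One test per condition x {threshold, rate difference}, each comparing
    the slope's posterior density at 0 with the analytic density of its
    normal prior at 0. Requires a fit with the covariate enabled.
    """
    if not spec.covariate:
        raise ValueError("model was specified without the competitiveness covariate")
    prior0 = float(norm.pdf(0.0, loc=spec.prior_beta.mean, scale=spec.prior_beta.sd))
    out: dict[tuple[str, str], BayesFactorResult] = {}
    for kind, label in (("B", "threshold"), ("d", "rate_difference")):
        for c in spec.conditions:
            name = f"beta_{kind}[{c}]"
            if name not in samples:
                raise ValueError(f"posterior draws are missing {name!r}")
            out[(label, c)] = savage_dickey(
                samples.stacked(name),
                prior_draws=np.empty(0),
                method=method,
                hypothesis_pair=f"competitiveness effect on {label} ({c})",
                prior_density_at_null=prior0,
            )
    return out
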