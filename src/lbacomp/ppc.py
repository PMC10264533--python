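"""Posterior predictive checks and the packaged parameter-recovery study.

Predictive datasets are simulated at the observed per-participant,
per-condition trial counts (episode stopping rules add trial-count noise
the fitted decision model does not describe, so episodes are not
re-simulated). Summaries average within participant first and then across
participants, so each participant carries equal weight.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from lbacomp.lba import LBAParams, simulate_trials
from lbacomp.model import GroupModelSpec, build_model, condition_effects
from lbacomp.sampling import PosteriorSamples, SamplerConfig, prior_samples, sample_posterior
from lbacomp.schemes import CONDITIONS

__all__ = [
    "design_from_trials",
    "posterior_predict",
    "ppc_accuracy",
    "ppc_rt_quantiles",
    "run_recovery_study",
]


def design_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Observed trial counts per participant x condition."""
    return (
        trials.groupby(["participant_id", "condition"], observed=True)
        .size()
        .rename("n_trials")
        .reset_index()
    )


def _participant_params(samples: PosteriorSamples, chain: int, draw: int):
    """Participant-level LBA parameters for one stored posterior draw."""
    extra = samples.extra
    block = extra["participant_draws"][chain, draw]  # (P, K)
    ids = extra["participant_ids"]
    conds = extra["conditions"]
    out = {}
    for pi, pid in enumerate(ids):
        A, t0, s = block[pi, 0], block[pi, 1], block[pi, 2]
        for ci, c in enumerate(conds):
            B = block[pi, 3 + ci]
            d = block[pi, 7 + ci]
            out[(pid, c)] = LBAParams(
                b=A + B, A=A, v_correct=(s + d) / 2.0, v_error=(s - d) / 2.0,
                s_v=1.0, t0=t0,
            )
    return out


def posterior_predict(
    samples: PosteriorSamples,
    design: pd.DataFrame,
    n_posterior_draws: int = 100,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """Simulate one synthetic trial set per retained posterior draw.

    ``design`` lists ``participant_id``, ``condition`` and ``n_trials``;
    draws are thinned evenly over chains and iterations.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if "participant_draws" not in samples.extra:
        raise ValueError("samples carry no participant-level draws")
    C, T = samples.extra["participant_draws"].shape[:2]
    total = C * T
    if n_posterior_draws > total:
        raise ValueError(f"requested {n_posterior_draws} draws but only {total} available")
    picks = np.linspace(0, total - 1, n_posterior_draws).astype(int)
    sets = []
    for flat in picks:
        chain, draw = divmod(int(flat), T)
        params = _participant_params(samples, chain, draw)
        rows = []
        for rec in design.itertuples(index=False):
            n = int(rec.n_trials)
            if n == 0:
                continue
            correct, rt = simulate_trials(params[(rec.participant_id, rec.condition)], n, rng)
            stim = np.where(rng.random(n) < 0.5, "left", "right")
            resp = np.where(correct, stim, np.where(stim == "left", "right", "left"))
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": rec.participant_id,
                        "condition": rec.condition,
                        "correct": correct.astype(int),
                        "rt_ms": rt * 1000.0,
                        "response_side": resp,
                    }
                )
            )
        sets.append(pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["participant_id", "condition", "correct", "rt_ms", "response_side"]
        ))
    return sets


def _participant_then_group(trials: pd.DataFrame, value: str, by: list[str]) -> pd.Series:
    per = trials.groupby(by + ["participant_id"], observed=True)[value].mean()
    return per.groupby(level=list(range(len(by)))).mean()


def ppc_accuracy(simulated_sets: list[pd.DataFrame], observed: pd.DataFrame) -> pd.DataFrame:
    """Observed vs predicted per-condition accuracy with 95% intervals."""
    obs = _participant_then_group(observed, "correct", ["condition"])
    pred = np.stack(
        [
            _participant_then_group(s, "correct", ["condition"]).reindex(obs.index).to_numpy()
            for s in simulated_sets
        ]
    )
    return pd.DataFrame(
        {
            "condition": obs.index,
            "observed": obs.to_numpy(),
            "predicted_mean": pred.mean(axis=0),
            "predicted_lo": np.percentile(pred, 2.5, axis=0),
            "predicted_hi": np.percentile(pred, 97.5, axis=0),
        }
    )


def _quantile_table(trials: pd.DataFrame, probs) -> pd.DataFrame:
    """Per-participant RT quantiles averaged over participants, by stratum."""
    rows = []
    strata = trials.groupby(["condition", "response_side", "correct"], observed=True)
    for (cond, side, corr), grp in strata:
        per = []
        for _, sub in grp.groupby("participant_id", observed=True):
            if len(sub) < 2:
                continue
            per.append(np.quantile(sub["rt_ms"].to_numpy(), probs))  # linear interp
        if not per:
            warnings.warn(f"stratum {(cond, side, corr)} has <2 observations everywhere; skipped")
            continue
        mean_q = np.mean(per, axis=0)
        for p, q in zip(probs, mean_q):
            rows.append(
                {"condition": cond, "response_side": side, "correct": corr,
                 "prob": p, "rt_ms": q}
            )
    return pd.DataFrame(rows)


def ppc_rt_quantiles(
    simulated_sets: list[pd.DataFrame],
    observed: pd.DataFrame,
    probs=(0.1, 0.3, 0.5, 0.7, 0.9),
) -> pd.DataFrame:
    """Observed vs predicted RT quantiles by condition x side x correctness.

    Quantiles use linear interpolation between order statistics; strata
    with fewer than two observations for a participant are skipped.
    """
    probs = list(probs)
    obs = _quantile_table(observed, probs).rename(columns={"rt_ms": "observed"})
    keys = ["condition", "response_side", "correct", "prob"]
    preds = []
    for i, s in enumerate(simulated_sets):
        t = _quantile_table(s, probs).rename(columns={"rt_ms": f"sim{i}"})
        preds.append(t.set_index(keys))
    allp = pd.concat(preds, axis=1)
    out = obs.set_index(keys)
    sims = allp.reindex(out.index).to_numpy()
    out["predicted_mean"] = np.nanmean(sims, axis=1)
    out["predicted_lo"] = np.nanpercentile(sims, 2.5, axis=1)
    out["predicted_hi"] = np.nanpercentile(sims, 97.5, axis=1)
    return out.reset_index()


def run_recovery_study(
    scenario,
    n_replications: int = 10,
    seeds=None,
    spec: GroupModelSpec | None = None,
    sampler: SamplerConfig | None = None,
    n_prior: int = 20000,
) -> dict:
    """Simulate -> preprocess -> fit -> effects, repeatedly; report recovery.

    For every replication, data are generated from ``scenario``, the
    hierarchical model is refit, and each group-level mean is compared with
    its generating value (posterior mean, central 95% credible interval,
    coverage flag). Also records the posterior probability of a negative
    tournament threshold effect and the Savage-Dickey BFs of the condition
    effects. A failed replication is recorded, not fatal.
    """
    from lbacomp.evidence import savage_dickey
    from lbacomp.preprocess import apply_exclusions
    from lbacomp.simulate import generate_population, simulate_experiment

    spec = spec or GroupModelSpec()
    sampler = sampler or SamplerConfig()
    if seeds is None:
        seeds = list(range(1, n_replications + 1))
    if len(seeds) != n_replications:
        raise ValueError("need one seed per replication")
    group = scenario.group
    truth = {
        "mu_A": group.mean_A,
        "mu_t0": group.mean_t0,
        "mu_s": group.mean_s,
        **{f"mu_B[{c}]": group.mean_B(c) for c in CONDITIONS},
        **{f"mu_d[{c}]": group.mean_d[c] for c in CONDITIONS},
    }
    rows = []
    reps = []
    for rep, seed in enumerate(seeds):
        try:
            rng = np.random.default_rng(seed)
            profiles = generate_population(scenario.n_participants, group, rng=rng)
            trials, _ = simulate_experiment(profiles, scenario, rng=rng)
            kept, _ = apply_exclusions(trials)
            model = build_model(kept, spec=spec)
            fit = sample_posterior(model, dataclasses.replace(sampler, seed=seed))
            effects = condition_effects(fit)
            prior = prior_samples(spec, n=n_prior, seed=seed + 10**6)
            rep_info = {"replication": rep, "seed": seed, "status": "ok"}
            for name, tval in truth.items():
                draws = fit.stacked(name)
                lo, hi = np.percentile(draws, [2.5, 97.5])
                rows.append(
                    {
                        "replication": rep,
                        "parameter": name,
                        "truth": tval,
                        "posterior_mean": float(draws.mean()),
                        "ci_lo": float(lo),
                        "ci_hi": float(hi),
                        "covered": bool(lo <= tval <= hi),
                    }
                )
            rep_info["p_db_tournament_neg"] = float(
                (effects["db_tournament"] < 0).mean()
            )
            for c in CONDITIONS:
                if c == "dyb":
                    continue
                prior_db = prior[f"mu_B[{c}]"] - prior["mu_B[dyb]"]
                prior_dd = prior[f"mu_d[{c}]"] - prior["mu_d[dyb]"]
                rep_info[f"bf_db_{c}"] = savage_dickey(
                    effects[f"db_{c}"], prior_db,
                    hypothesis_pair=f"threshold effect ({c})").bf
                rep_info[f"bf_dd_{c}"] = savage_dickey(
                    effects[f"dd_{c}"], prior_dd,
                    hypothesis_pair=f"rate effect ({c})").bf
            reps.append(rep_info)
        except Exception as exc:  # noqa: BLE001 — per-replication isolation
            reps.append({"replication": rep, "seed": seed, "status": f"failed: {exc}"})
    table = pd.DataFrame(rows)
    coverage = float(table["covered"].mean()) if len(table) else np.nan
    return {
        "parameters": table,
        "replications": pd.DataFrame(reps),
        "coverage": coverage,
        "truth": truth,
    }
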