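"""Shared fixtures: small synthetic experiments and one reference fit.

Everything is generated at test time from seeds; the reference fit is
session-scoped because posterior sampling is the expensive step shared by
the posterior-predictive and diagnostics tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lbacomp import (
    GroupConfig,
    SamplerConfig,
    Scenario,
    apply_exclusions,
    build_model,
    generate_population,
    sample_posterior,
    simulate_experiment,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_experiment(n_participants, episodes, seed, group=None):
    g = group or GroupConfig()
    r = np.random.default_rng(seed)
    profiles = generate_population(n_participants, g, rng=r)
    scenario = Scenario(n_participants=n_participants, episodes_per_condition=episodes,
                        group=g)
    trials, episodes_tbl = simulate_experiment(profiles, scenario, rng=r)
    return profiles, trials, episodes_tbl


@pytest.fixture(scope="session")
def small_experiment():
    """6 participants x 2 episodes/condition: cheap pipeline input."""
    profiles, trials, episodes = make_experiment(6, 2, seed=2024)
    return profiles, trials, episodes


@pytest.fixture(scope="session")
def reference_fit():
    """One fitted hierarchical model shared across posterior-based tests."""
    profiles, trials, _ = make_experiment(8, 3, seed=77)
    kept, _ = apply_exclusions(trials)
    model = build_model(kept)
    fit = sample_posterior(
        model, SamplerConfig(n_chains=24, n_warmup=500, n_draws=300, seed=77, thin=2)
    )
    return profiles, kept, model, fit


@pytest.fixture()
def toy_trials():
    """Five RTs straddling both exclusion boundaries."""
    return pd.DataFrame(
        {
            "participant_id": "p001",
            "condition": "dyb",
            "episode_index": 1,
            "trial_index": range(1, 6),
            "stimulus_side": "left",
            "response_side": "left",
            "correct": 1,
            "rt_ms": [200.0, 250.0, 300.0, 4999.0, 5000.0],
            "is_practice": 0,
            "participant_score_after": range(1, 6),
            "opponent_score_after": np.nan,
        }
    )
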