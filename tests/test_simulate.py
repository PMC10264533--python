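"""Synthetic-experiment generator: scheme rules, episode bookkeeping,
population structure, opponent calibration.

Deterministic episode arithmetic is forced through near-degenerate LBA
agents (vanishing drift variability), which pin every decision's RT.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lbacomp import (
    CONDITIONS,
    SCHEMES,
    GroupConfig,
    LBAParams,
    Scenario,
    SchemeSpec,
    calibrate_opponent,
    generate_competitiveness,
    generate_population,
    simulate_episode,
    simulate_experiment,
)
from lbacomp.io import validate_trials


def clockwork_agent(rt: float, t0: float = 0.0) -> LBAParams:
    """An agent that always responds correctly after exactly ``rt`` seconds."""
    return LBAParams(b=1.0, A=0.0, v_correct=1.0 / (rt - t0), v_error=-1.0,
                     s_v=1e-9, t0=t0)


def clockwork_profile(rt_by_condition: dict) -> "object":
    from lbacomp.simulate import ParticipantProfile

    return ParticipantProfile(
        participant_id="p001",
        competitiveness=3.0,
        z_competitiveness=0.0,
        params_by_condition={c: clockwork_agent(rt_by_condition.get(c, 2.0))
                             for c in CONDITIONS},
    )


class TestSchemes:
    def test_table_of_features(self):
        assert SCHEMES["tournament"].deadline_s == 20.0
        assert SCHEMES["tournament"].goal_points is None
        assert SCHEMES["tournament"].has_opponent
        assert SCHEMES["race"].deadline_s is None
        assert SCHEMES["race"].goal_points == 8
        assert SCHEMES["race"].has_opponent
        assert SCHEMES["igp"] == SchemeSpec("igp", 20.0, 8, False)
        assert SCHEMES["dyb"] == SchemeSpec("dyb", 20.0, None, False)

    def test_scheme_requires_termination_rule(self):
        with pytest.raises(ValueError):
            SchemeSpec("dyb", None, None, False)


class TestCompetitiveness:
    def test_degenerate_population_scores_exactly_three(self, rng):
        scores = generate_competitiveness(50, rng, latent_mean=3.0, latent_sd=0.0)
        assert np.all(scores == 3.0)

    def test_saturated_items_give_boundary_score(self, rng):
        scores = generate_competitiveness(50, rng, latent_mean=50.0, latent_sd=0.0)
        assert np.all(scores == 5.0)

    def test_scores_bounded_and_mean_near_population(self, rng):
        scores = generate_competitiveness(10**4, rng, latent_mean=3.4, latent_sd=0.6)
        assert scores.min() >= 1.0 and scores.max() <= 5.0
        se = scores.std() / 100
        # item rounding/clipping shifts the mean by < 0.05 at these settings
        assert scores.mean() == pytest.approx(3.4, abs=3 * se + 0.05)


class TestPopulation:
    def test_degenerate_hierarchy_reproduces_group_means(self):
        g = GroupConfig(sd_A=0.0, sd_t0=0.0, sd_s=0.0, sd_B_base=0.0,
                        sd_B_cond=0.0, sd_d=0.0)
        profiles = generate_population(5, g, seed=0)
        for p in profiles:
            for c in CONDITIONS:
                lp = p.params_by_condition[c]
                assert lp.b == pytest.approx(g.mean_b[c])
                assert lp.A == pytest.approx(g.mean_A)
                assert lp.t0 == pytest.approx(g.mean_t0)
                assert lp.v_correct + lp.v_error == pytest.approx(g.mean_s)
                assert lp.v_correct - lp.v_error == pytest.approx(g.mean_d[c])

    def test_reproducible_given_seed(self):
        a = generate_population(10, seed=5)
        b = generate_population(10, seed=5)
        for x, y in zip(a, b):
            assert x.competitiveness == y.competitiveness
            assert x.params_by_condition == y.params_by_condition

    def test_covariate_slope_recovered_by_regression(self):
        g = GroupConfig(slopes={("tournament", "d"): 0.1})
        profiles = generate_population(10**4, g, seed=11)
        z = np.array([p.z_competitiveness for p in profiles])
        d = np.array([
            p.params_by_condition["tournament"].v_correct
            - p.params_by_condition["tournament"].v_error
            for p in profiles
        ])
        slope = np.polyfit(z, d, 1)[0]
        se = g.sd_d / np.sqrt(len(z))
        assert slope == pytest.approx(0.1, abs=3 * se)


class TestEpisodes:
    def test_race_clockwork_win(self, rng):
        """Participant nets a point every 2.0 s, opponent every 2.5 s."""
        prof = clockwork_profile({"race": 2.0})
        res = simulate_episode(prof, SCHEMES["race"], clockwork_agent(2.5), rng)
        assert res.outcome == "win"
        assert len(res.trials) == 8
        assert res.participant_score == 8
        assert res.elapsed_s == pytest.approx(16.0, abs=1e-6)

    def test_tournament_tie_counts_as_loss(self, rng):
        prof = clockwork_profile({"tournament": 2.0})
        res = simulate_episode(prof, SCHEMES["tournament"], clockwork_agent(2.0), rng)
        assert res.participant_score == res.opponent_score
        assert res.outcome == "loss"

    def test_dyb_deadline_truncates_trial_count(self, rng):
        # 9 x 2.217 = 19.953 <= 20 < 10 cycles
        prof = clockwork_profile({"dyb": 2.217})
        res = simulate_episode(prof, SCHEMES["dyb"], None, rng)
        assert len(res.trials) == 9
        assert res.outcome == "time_expired"

    def test_igp_goal_met_stops_episode(self, rng):
        prof = clockwork_profile({"igp": 2.0})
        res = simulate_episode(prof, SCHEMES["igp"], None, rng)
        assert res.outcome == "goal_met"
        assert len(res.trials) == 8

    def test_opponent_required_iff_scheme_has_one(self, rng):
        prof = clockwork_profile({})
        with pytest.raises(ValueError):
            simulate_episode(prof, SCHEMES["race"], None, rng)

    def test_score_conservation(self, small_experiment):
        _, trials, episodes = small_experiment
        merged = (
            trials.groupby(["participant_id", "condition", "episode_index"])
            .apply(lambda t: (t["correct"] * 2 - 1).sum(), include_groups=False)
            .rename("recomputed")
            .reset_index()
            .merge(episodes, on=["participant_id", "condition", "episode_index"])
        )
        assert (merged["recomputed"] == merged["participant_score"]).all()

    def test_no_trial_outruns_deadline(self, small_experiment):
        _, trials, _ = small_experiment
        for (pid, cond, ep), grp in trials.groupby(
            ["participant_id", "condition", "episode_index"]
        ):
            deadline = SCHEMES[cond].deadline_s
            if deadline is not None:
                assert grp["rt_ms"].sum() / 1000.0 <= deadline + 1e-9


class TestExperiment:
    def test_single_profile_covers_all_conditions(self):
        profiles = generate_population(1, seed=3)
        sc = Scenario(n_participants=1, episodes_per_condition=1)
        trials, episodes = simulate_experiment(profiles, sc, seed=3)
        assert len(episodes) == 4
        assert sorted(episodes["condition"]) == sorted(CONDITIONS)

    def test_fixed_seed_reproducible_table(self, tmp_path):
        profiles = generate_population(3, seed=8)
        sc = Scenario(n_participants=3, episodes_per_condition=2)
        t1, _ = simulate_experiment(profiles, sc, seed=9)
        t2, _ = simulate_experiment(profiles, sc, seed=9)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        t1.to_csv(a, index=False)
        t2.to_csv(b, index=False)
        assert a.read_bytes() == b.read_bytes()

    def test_trial_counts_scale_with_episodes(self):
        profiles = generate_population(3, seed=4)
        n1 = len(simulate_experiment(
            profiles, Scenario(n_participants=3, episodes_per_condition=2), seed=5)[1])
        n2 = len(simulate_experiment(
            profiles, Scenario(n_participants=3, episodes_per_condition=4), seed=5)[1])
        assert n2 == 2 * n1

    def test_output_conforms_to_trial_schema(self, small_experiment):
        _, trials, _ = small_experiment
        validate_trials(trials)

    def test_race_is_balanced_against_equal_opponent(self):
        """A participant with the opponent's own parameters wins ~half of races."""
        from lbacomp.simulate import ParticipantProfile, default_opponent

        opp = default_opponent()
        prof = ParticipantProfile("p001", 3.0, 0.0,
                                  {c: opp for c in CONDITIONS})
        rng = np.random.default_rng(77)
        wins = sum(
            simulate_episode(prof, SCHEMES["race"], opp, rng,
                             opponent_max_decision_s=None).outcome == "win"
            for _ in range(2000)
        )
        assert 0.4 <= wins / 2000 <= 0.6


class TestOpponentCalibration:
    def test_always_correct_clockwork(self, rng):
        assert calibrate_opponent(clockwork_agent(2.5), goal_points=8, n_sims=3,
                                  rng=rng) == pytest.approx(20.0, abs=1e-6)
        assert calibrate_opponent(clockwork_agent(2.0), goal_points=8, n_sims=3,
                                  rng=rng) == pytest.approx(16.0, abs=1e-6)

    def test_default_opponent_takes_about_twenty_seconds(self):
        from lbacomp.simulate import default_opponent

        mean = calibrate_opponent(default_opponent(), n_sims=10**4, seed=42)
        assert 19.0 <= mean <= 21.0

    def test_nonpositive_net_rate_rejected(self, rng):
        bad = LBAParams(b=1.0, A=0.3, v_correct=0.5, v_error=0.5)  # 50% accuracy
        with pytest.raises(ValueError):
            calibrate_opponent(bad, rng=rng)
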