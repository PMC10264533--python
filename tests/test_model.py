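"""Hierarchical model: parameter maps, log joint against a hand-rolled
re-implementation, condition effects, and prior support."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from lbacomp import (
    GroupModelSpec,
    LBAParams,
    PriorSpec,
    build_model,
    condition_effects,
    log_likelihood,
    prior_samples,
    rates_from_sum_diff,
    rates_to_sum_diff,
)
from lbacomp.model import PARTICIPANT_PARAMS
from lbacomp.schemes import CONDITIONS


class TestRateMaps:
    def test_symmetric_split(self):
        assert rates_from_sum_diff(2.0, 0.0) == (1.0, 1.0)
        assert rates_from_sum_diff(2.0, 2.0) == (2.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_round_trip_identity(self, vc, ve):
        s, d = rates_to_sum_diff(vc, ve)
        assert rates_from_sum_diff(s, d) == pytest.approx((vc, ve))


def tiny_table(rts_by_condition):
    rows = []
    for c, rts in rts_by_condition.items():
        for i, (rt, corr) in enumerate(rts):
            rows.append({"participant_id": "p1", "condition": c,
                         "correct": corr, "rt_ms": rt * 1000.0})
    return pd.DataFrame(rows)


class TestLogJoint:
    def test_matches_independent_reimplementation(self):
        """One participant, five trials: compare against scipy-only arithmetic."""
        trials = tiny_table({
            "tournament": [(0.8, 1), (1.2, 0)],
            "race": [(0.9, 1)],
            "igp": [(1.1, 1)],
            "dyb": [(0.7, 0)],
        })
        spec = GroupModelSpec(rt_window=None)
        model = build_model(trials, spec=spec)
        point = {}
        g = {"mu_A": 0.4, "mu_t0": 0.3, "mu_s": 1.8}
        sd = {"sigma_A": 0.2, "sigma_t0": 0.1, "sigma_s": 0.3}
        part = {"A": 0.35, "t0": 0.32, "s": 1.9}
        for c in CONDITIONS:
            g[f"mu_B[{c}]"] = 0.6
            sd[f"sigma_B[{c}]"] = 0.25
            part[f"B[{c}]"] = 0.55
            g[f"mu_d[{c}]"] = 1.0
            sd[f"sigma_d[{c}]"] = 0.2
            part[f"d[{c}]"] = 1.1
        point.update(g)
        point.update(sd)
        point.update({f"{k}[p1]": v for k, v in part.items()})
        got = model.log_joint(point)

        # independent oracle: hyperpriors + truncated-normal hierarchy + LBA
        def tnorm_logpdf(x, m, s):  # truncated at 0
            return norm.logpdf(x, m, s) - norm.logcdf(m / s)

        expect = 0.0
        expect += tnorm_logpdf(g["mu_A"], 0.5, 0.3)
        expect += tnorm_logpdf(g["mu_t0"], 0.3, 0.15)
        expect += tnorm_logpdf(g["mu_s"], 2.0, 1.0)
        for c in CONDITIONS:
            expect += tnorm_logpdf(g[f"mu_B[{c}]"], 0.5, 0.5)
            expect += norm.logpdf(g[f"mu_d[{c}]"], 1.0, 1.0)
        for v in sd.values():
            expect += norm.logpdf(v, 0.0, 0.3) + np.log(2.0)
        expect += tnorm_logpdf(part["A"], g["mu_A"], sd["sigma_A"])
        expect += tnorm_logpdf(part["t0"], g["mu_t0"], sd["sigma_t0"])
        expect += tnorm_logpdf(part["s"], g["mu_s"], sd["sigma_s"])
        for c in CONDITIONS:
            expect += tnorm_logpdf(part[f"B[{c}]"], g[f"mu_B[{c}]"], sd[f"sigma_B[{c}]"])
            expect += norm.logpdf(part[f"d[{c}]"], g[f"mu_d[{c}]"], sd[f"sigma_d[{c}]"])
        for c, rows in {
            "tournament": [(0.8, 1), (1.2, 0)],
            "race": [(0.9, 1)],
            "igp": [(1.1, 1)],
            "dyb": [(0.7, 0)],
        }.items():
            vc, ve = rates_from_sum_diff(part["s"], part[f"d[{c}]"])
            lp = LBAParams(b=part["A"] + part[f"B[{c}]"], A=part["A"],
                           v_correct=vc, v_error=ve, t0=part["t0"])
            expect += log_likelihood(
                [("correct" if corr else "error", rt) for rt, corr in rows], lp
            )
        assert got == pytest.approx(expect, rel=1e-10)

    def test_covariate_off_has_no_beta_parameters(self):
        trials = tiny_table({c: [(0.8, 1)] for c in CONDITIONS})
        model = build_model(trials, spec=GroupModelSpec(rt_window=None))
        assert not any(n.startswith("beta") for n in model.param_names)

    def test_covariate_requires_scores(self):
        trials = tiny_table({c: [(0.8, 1)] for c in CONDITIONS})
        with pytest.raises(ValueError, match="competitiveness"):
            build_model(trials, spec=GroupModelSpec(covariate=True, rt_window=None))

    def test_empty_data_gives_prior_only_joint(self):
        empty = pd.DataFrame(columns=["participant_id", "condition", "correct", "rt_ms"])
        model = build_model(empty)
        vec = model.sample_group_from_prior(1, np.random.default_rng(0))[0]
        assert model.log_joint(vec) == pytest.approx(
            float(model.log_prior_group(vec[None])[0])
        )

    def test_missing_condition_is_build_error(self):
        trials = tiny_table({"dyb": [(0.8, 1)], "race": [(0.9, 1)]})
        with pytest.raises(ValueError, match="condition"):
            build_model(trials, spec=GroupModelSpec(rt_window=None))

    def test_out_of_window_rts_rejected_at_build(self):
        trials = tiny_table({c: [(0.8, 1), (6.0, 1)] for c in CONDITIONS})
        with pytest.raises(ValueError, match="window"):
            build_model(trials)


class FakeSamples(dict):
    def stacked(self, name):
        return np.asarray(self[name])


class TestConditionEffects:
    def test_identical_means_give_zero_effects(self):
        draws = FakeSamples()
        for c in CONDITIONS:
            draws[f"mu_B[{c}]"] = np.full(100, 0.6)
            draws[f"mu_d[{c}]"] = np.full(100, 1.0)
        eff = condition_effects(draws)
        assert set(eff) == {
            "db_tournament", "db_race", "db_igp",
            "dd_tournament", "dd_race", "dd_igp",
        }
        for v in eff.values():
            assert np.all(v == 0.0)

    def test_shift_moves_effect_linearly(self):
        draws = FakeSamples()
        for c in CONDITIONS:
            draws[f"mu_B[{c}]"] = np.full(100, 0.6)
            draws[f"mu_d[{c}]"] = np.full(100, 1.0)
        draws["mu_B[race]"] = draws["mu_B[race]"] + 0.1
        eff = condition_effects(draws)
        assert np.allclose(eff["db_race"], 0.1)
        assert np.allclose(eff["db_tournament"], 0.0)

    def test_missing_parameter_is_schema_error(self):
        with pytest.raises(KeyError, match="mu_B"):
            condition_effects(FakeSamples())


class TestPriorSupport:
    def test_prior_draws_respect_lba_invariants(self):
        """b >= A always holds because threshold offsets are truncated positive."""
        spec = GroupModelSpec()
        draws = prior_samples(spec, n=5000, seed=0)
        for name in PARTICIPANT_PARAMS:
            if name != "d" and not name.startswith("d["):
                assert (draws[f"mu_{name}"] > 0).all()

    def test_degenerate_priors_collapse_to_mean(self):
        spec = GroupModelSpec(prior_mean_s=PriorSpec(2.0, 0.0, lower=0.0))
        draws = prior_samples(spec, n=100, seed=1)
        assert np.all(draws["mu_s"] == 2.0)

    def test_truncated_mean_matches_closed_form(self):
        spec = GroupModelSpec()
        n = 50000
        draws = prior_samples(spec, n=n, seed=2)["mu_A"]
        expect = spec.prior_mean_A.analytic_mean()
        se = draws.std() / np.sqrt(n)
        assert draws.mean() == pytest.approx(expect, abs=3 * se)
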