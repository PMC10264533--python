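"""Synthetic competition experiments with LBA agents.

Generates complete datasets with the structure the downstream analysis
assumes: a hierarchical population of participants, four competition
schemes per participant, an LBA-driven computerised opponent where the
scheme has one, and a trait-competitiveness score per participant.

Episode bookkeeping
-------------------
Points start at 0; a correct decision scores +1, an incorrect one -1.
After every decision the task shows a progress screen for ``feedback_s``
seconds. By default the deadline clock counts decision time only (the
clock pauses during feedback screens); set ``count_feedback=True`` to
charge feedback time against the deadline as well. A decision whose RT
would complete after the deadline is censored: not recorded, not scored.
A tournament tie at the deadline counts as a loss for the participant, and
an exact race tie resolves in the opponent's favour.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lbacomp.lba import LBAParams, simulate_trials
from lbacomp.model import rates_from_sum_diff
from lbacomp.schemes import CONDITIONS, SCHEMES, SchemeSpec

__all__ = [
    "GroupConfig",
    "ParticipantProfile",
    "EpisodeResult",
    "Scenario",
    "default_opponent",
    "default_scenario",
    "generate_competitiveness",
    "generate_population",
    "simulate_episode",
    "simulate_experiment",
    "calibrate_opponent",
]


# Group-level generating means near the fitted regime of the real study:
# thresholds b (dyb 0.95, tournament 0.89, race 1.00, igp 1.04) and rate
# differences d (1.10, 1.04, 1.10, 1.01); A, t0 and the rate sum s are
# shared across conditions and chosen so a typical synthetic participant
# shows ~77% accuracy and ~1.2-s mean RT in the do-your-best scheme.
_DEFAULT_B_MEAN = {"tournament": 0.89, "race": 1.00, "igp": 1.04, "dyb": 0.95}
_DEFAULT_D_MEAN = {"tournament": 1.04, "race": 1.10, "igp": 1.01, "dyb": 1.10}


@dataclass(frozen=True)
class GroupConfig:
    """Hyperparameters of the generating population.

    Participant parameters are drawn from normals truncated to the LBA
    support: start-point range ``A``, nondecision time ``t0``, rate sum
    ``s`` and threshold offsets ``B_c = b_c - A`` are positive; rate
    differences ``d_c`` are unconstrained. ``slopes`` maps
    ``(condition, "B" | "d")`` to a linear effect of standardised trait
    competitiveness on that parameter's participant-level mean.
    """

    mean_A: float = 0.30
    sd_A: float = 0.08
    mean_t0: float = 0.45
    sd_t0: float = 0.05
    mean_s: float = 1.6
    sd_s: float = 0.25
    mean_b: dict = field(default_factory=lambda: dict(_DEFAULT_B_MEAN))
    # Threshold offsets decompose into a stable between-person caution
    # component (shared by all four conditions) plus a small
    # condition-specific deviation: people differ a lot in overall caution
    # but by much less in how a given scheme shifts it. The reported
    # condition-difference credible intervals are an order of magnitude
    # tighter than the condition-mean intervals, which forces this
    # within-person correlation.
    sd_B_base: float = 0.10
    sd_B_cond: float = 0.05
    mean_d: dict = field(default_factory=lambda: dict(_DEFAULT_D_MEAN))
    sd_d: float = 0.18
    slopes: dict = field(default_factory=dict)
    competitiveness_mean: float = 3.4
    competitiveness_sd: float = 0.6

    def mean_B(self, condition: str) -> float:
        off = self.mean_b[condition] - self.mean_A
        if off <= 0:
            raise ValueError(
                f"mean threshold {self.mean_b[condition]} for {condition!r} must exceed mean_A"
            )
        return off


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    competitiveness: float
    z_competitiveness: float
    params_by_condition: dict

    def __post_init__(self) -> None:
        missing = set(CONDITIONS) - set(self.params_by_condition)
        if missing:
            raise ValueError(f"profile missing conditions {sorted(missing)}")


@dataclass
class EpisodeResult:
    episode_id: str
    condition: str
    trials: pd.DataFrame
    participant_score: int
    opponent_score: int | None
    outcome: str
    elapsed_s: float


@dataclass(frozen=True)
class Scenario:
    """A full synthetic-experiment configuration."""

    n_participants: int = 100
    episodes_per_condition: int = 15
    feedback_s: float = 1.0
    count_feedback: bool = False
    opponent_max_decision_s: float | None = 5.0
    group: GroupConfig = field(default_factory=GroupConfig)
    opponent: LBAParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.opponent is None:
            object.__setattr__(self, "opponent", default_opponent())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def default_opponent() -> LBAParams:
    """Opponent LBA calibrated to take ~20 s to net 8 points.

    A single fixed parameter set plays every opponent episode, mimicking an
    opponent fit once to pilot data. With these values the opponent is
    ~79% accurate with a ~1.4-s mean decision time, which puts its mean
    time-to-goal for 8 points inside [19, 21] s (see ``calibrate_opponent``).
    """
    return LBAParams(b=1.6, A=0.3, v_correct=1.55, v_error=0.45, s_v=1.0, t0=0.4)


def default_scenario(**overrides) -> Scenario:
    return Scenario(**overrides)


def generate_competitiveness(
    n: int,
    rng: np.random.Generator,
    latent_mean: float = 3.4,
    latent_sd: float = 0.6,
    n_items: int = 14,
) -> np.ndarray:
    """Trait-competitiveness scores: means of ``n_items`` 5-point Likert items.

    Each participant has a latent level ``~ Normal(latent_mean, latent_sd)``;
    item responses are the latent level plus unit-SD item noise, rounded to
    the nearest integer and clipped to 1..5. Scores therefore lie in [1, 5].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    latent = rng.normal(latent_mean, latent_sd, size=n)
    # degenerate population: no item noise either, so scores are exact
    noise = (
        rng.normal(0.0, 1.0, size=(n, n_items)) if latent_sd > 0
        else np.zeros((n, n_items))
    )
    items = np.clip(np.rint(latent[:, None] + noise), 1, 5)
    return items.mean(axis=1)


def _truncnorm_pos(mean, sd, size, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf), elementwise mean allowed."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    if sd == 0:
        if np.any(mean <= 0):
            raise ValueError("degenerate truncated normal with nonpositive mean")
        return mean
    out = np.empty(size)
    pending = np.arange(out.size)
    flat_mean = mean.reshape(-1)
    for _ in range(1000):
        draws = rng.normal(flat_mean[pending], sd)
        ok = draws > 0
        out.reshape(-1)[pending[ok]] = draws[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    raise ValueError("truncated-normal rejection failed: mean too far below 0")


def generate_population(
    n_participants: int,
    group: GroupConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[ParticipantProfile]:
    """Draw a hierarchical population of participant LBA profiles.

    ``A``, ``t0`` and the rate sum are shared across a participant's four
    conditions; the threshold offset ``B_c`` and rate difference ``d_c``
    are condition-specific. Competitiveness slopes in ``group.slopes``
    shift the participant-level means by ``slope * z`` where ``z`` is the
    standardised competitiveness score.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    group = group or GroupConfig()
    comp = generate_competitiveness(
        n_participants, rng, group.competitiveness_mean, group.competitiveness_sd
    )
    z = (comp - comp.mean()) / comp.std() if comp.std() > 0 else np.zeros_like(comp)

    A = _truncnorm_pos(group.mean_A, group.sd_A, (n_participants,), rng)
    t0 = _truncnorm_pos(group.mean_t0, group.sd_t0, (n_participants,), rng)
    s = _truncnorm_pos(group.mean_s, group.sd_s, (n_participants,), rng)
    B = {}
    d = {}
    base_B = (
        rng.normal(0.0, group.sd_B_base, size=n_participants)
        if group.sd_B_base > 0 else np.zeros(n_participants)
    )
    for c in CONDITIONS:
        slope_B = group.slopes.get((c, "B"), 0.0)
        slope_d = group.slopes.get((c, "d"), 0.0)
        B[c] = _truncnorm_pos(
            group.mean_B(c) + base_B + slope_B * z, group.sd_B_cond,
            (n_participants,), rng,
        )
        d[c] = rng.normal(group.mean_d[c] + slope_d * z, group.sd_d) if group.sd_d > 0 else (
            group.mean_d[c] + slope_d * z
        )
    profiles = []
    for i in range(n_participants):
        params = {}
        for c in CONDITIONS:
            v_c, v_e = rates_from_sum_diff(s[i], float(np.asarray(d[c])[i]))
            params[c] = LBAParams(
                b=A[i] + B[c][i],
                A=A[i],
                v_correct=float(v_c),
                v_error=float(v_e),
                s_v=1.0,
                t0=t0[i],
            )
        profiles.append(
            ParticipantProfile(
                participant_id=f"p{i + 1:03d}",
                competitiveness=float(comp[i]),
                z_competitiveness=float(z[i]),
                params_by_condition=params,
            )
        )
    return profiles


def _decision_stream(params: LBAParams, max_trials: int, rng: np.random.Generator):
    """Simulated decisions with cumulative decision-time clock."""
    correct, rt = simulate_trials(params, max_trials, rng)
    return correct, rt, np.cumsum(rt)


def _stream_until(params, rng, needed_time=None, needed_score=None, feedback_s=0.0,
                  batch=32, max_rt=None):
    """Grow a decision stream until it spans the deadline or reaches a score."""
    correct = np.empty(0, dtype=bool)
    rt = np.empty(0)
    while True:
        c, r = simulate_trials(params, batch, rng, max_rt=max_rt)
        correct = np.concatenate([correct, c])
        rt = np.concatenate([rt, r])
        clock = np.cumsum(rt + feedback_s)
        score = np.cumsum(np.where(correct, 1, -1))
        if needed_time is not None and clock[-1] > needed_time:
            return correct, rt, clock, score
        if needed_score is not None and score.max(initial=-10**9) >= needed_score:
            return correct, rt, clock, score
        if len(rt) > 10000:
            raise RuntimeError("episode failed to terminate after 10000 trials")


def simulate_episode(
    profile: ParticipantProfile,
    scheme: SchemeSpec,
    opponent: LBAParams | None,
    rng: np.random.Generator,
    feedback_s: float = 1.0,
    count_feedback: bool = False,
    opponent_max_decision_s: float | None = 5.0,
    episode_id: str = "e01",
) -> EpisodeResult:
    """Simulate one competitive episode; returns trials plus outcome.

    The clock charged against the deadline is the cumulative decision time,
    plus ``feedback_s`` per decision when ``count_feedback`` is set. The
    opponent (when present) runs an independent stream under the same clock
    convention.
    """
    if feedback_s <= 0:
        raise ValueError("feedback_s must be positive")
    if scheme.has_opponent and opponent is None:
        raise ValueError(f"scheme {scheme.name!r} requires an opponent")
    if not scheme.has_opponent:
        opponent = None
    fb = feedback_s if count_feedback else 0.0
    params = profile.params_by_condition[scheme.name]

    deadline = scheme.deadline_s if scheme.deadline_s is not None else np.inf
    goal = scheme.goal_points

    correct, rt, clock, score = _stream_until(
        params, rng,
        needed_time=deadline if np.isfinite(deadline) else None,
        needed_score=goal,
        feedback_s=fb,
    )
    # completion time of decision i is clock[i] - fb (feedback follows it)
    complete = clock - fb if fb else clock
    within = complete <= deadline

    opp_correct = opp_rt = opp_clock = opp_score = None
    opp_goal_time = np.inf
    if opponent is not None:
        opp_correct, opp_rt, opp_clock, opp_score = _stream_until(
            opponent, rng,
            needed_time=deadline if np.isfinite(deadline) else None,
            needed_score=goal,
            feedback_s=fb,
            max_rt=opponent_max_decision_s,
        )
        if goal is not None:
            reached = np.nonzero(opp_score >= goal)[0]
            if reached.size:
                opp_goal_time = float(opp_clock[reached[0]] - fb)

    if goal is not None:
        reached = np.nonzero((score >= goal) & within)[0]
        own_goal_time = float(complete[reached[0]]) if reached.size else np.inf
    else:
        own_goal_time = np.inf

    # Episode end per scheme.
    if scheme.name == "race":
        end_time = min(own_goal_time, opp_goal_time)
        won = own_goal_time < opp_goal_time  # exact tie favours the opponent
        outcome = "win" if won else "loss"
    elif scheme.name == "tournament":
        end_time = deadline
        outcome = None  # decided after scores are fixed
    elif scheme.name == "igp":
        end_time = min(deadline, own_goal_time)
        outcome = "goal_met" if own_goal_time <= deadline else "goal_missed"
    else:  # dyb
        end_time = deadline
        outcome = "time_expired"

    keep = complete <= end_time
    if goal is not None and np.isfinite(own_goal_time):
        keep &= complete <= own_goal_time
    n_keep = int(keep.sum())
    correct, rt, complete = correct[:n_keep], rt[:n_keep], complete[:n_keep]
    part_score = int(np.sum(np.where(correct, 1, -1)))

    final_opp_score = None
    if opponent is not None:
        opp_complete = opp_clock - fb if fb else opp_clock
        opp_keep = opp_complete <= min(end_time, opp_goal_time)
        final_opp_score = int(np.sum(np.where(opp_correct[opp_keep], 1, -1)))
        if scheme.name == "tournament":
            outcome = "win" if part_score > final_opp_score else "loss"

    stim = np.where(rng.random(n_keep) < 0.5, "left", "right")
    resp = np.where(correct, stim, np.where(stim == "left", "right", "left"))
    trials = pd.DataFrame(
        {
            "participant_id": profile.participant_id,
            "condition": scheme.name,
            "episode_index": 0,  # filled by simulate_experiment
            "trial_index": np.arange(1, n_keep + 1),
            "stimulus_side": stim,
            "response_side": resp,
            "correct": correct.astype(int),
            "rt_ms": rt * 1000.0,
            "is_practice": 0,
            "participant_score_after": np.cumsum(np.where(correct, 1, -1)),
            "opponent_score_after": np.nan,
        }
    )
    if opponent is not None:
        # opponent score as of each participant decision's completion time
        opp_complete = opp_clock - fb if fb else opp_clock
        opp_cum = np.cumsum(np.where(opp_correct, 1, -1))
        idx = np.searchsorted(opp_complete, complete, side="right")
        capped = opp_complete <= opp_goal_time
        idx = np.minimum(idx, int(capped.sum()))
        trials["opponent_score_after"] = np.where(idx > 0, opp_cum[np.maximum(idx - 1, 0)], 0)

    elapsed = float(complete[-1]) if n_keep else 0.0
    if np.isfinite(end_time):
        elapsed = min(max(elapsed, 0.0), end_time) if scheme.name == "race" else end_time
    return EpisodeResult(
        episode_id=episode_id,
        condition=scheme.name,
        trials=trials,
        participant_score=part_score,
        opponent_score=final_opp_score,
        outcome=outcome,
        elapsed_s=elapsed,
    )


def simulate_experiment(
    profiles: list[ParticipantProfile],
    scenario: Scenario | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    schemes: dict[str, SchemeSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full design; returns ``(trial_table, episode_table)``.

    Each participant completes every scheme in a freshly randomised order,
    with ``scenario.episodes_per_condition`` episodes per scheme. Episode
    and trial indices are 1-based.
    """
    scenario = scenario or Scenario()
    schemes = schemes or SCHEMES
    if rng is None:
        rng = np.random.default_rng(seed)
    trial_parts = []
    episode_rows = []
    names = list(schemes)
    for profile in profiles:
        order = [names[i] for i in rng.permutation(len(names))]
        for cond in order:
            scheme = schemes[cond]
            for ep in range(1, scenario.episodes_per_condition + 1):
                res = simulate_episode(
                    profile,
                    scheme,
                    scenario.opponent if scheme.has_opponent else None,
                    rng,
                    feedback_s=scenario.feedback_s,
                    count_feedback=scenario.count_feedback,
                    opponent_max_decision_s=scenario.opponent_max_decision_s,
                    episode_id=f"{profile.participant_id}-{cond}-{ep:02d}",
                )
                res.trials["episode_index"] = ep
                trial_parts.append(res.trials)
                episode_rows.append(
                    {
                        "participant_id": profile.participant_id,
                        "condition": cond,
                        "episode_index": ep,
                        "participant_score": res.participant_score,
                        "opponent_score": res.opponent_score,
                        "outcome": res.outcome,
                        "elapsed_s": res.elapsed_s,
                        "n_trials": len(res.trials),
                        "competitiveness": profile.competitiveness,
                    }
                )
    trials = pd.concat(trial_parts, ignore_index=True) if trial_parts else pd.DataFrame()
    episodes = pd.DataFrame(episode_rows)
    return trials, episodes


def calibrate_opponent(
    opponent: LBAParams,
    goal_points: int = 8,
    feedback_s: float = 1.0,
    count_feedback: bool = False,
    max_decision_s: float | None = 5.0,
    n_sims: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float:
    """Mean wall-clock time for the opponent to first net ``goal_points``.

    Uses the same clock convention as episodes. Opponent decisions slower
    than ``max_decision_s`` are redrawn, as in episodes: the raw LBA
    passage time has no finite mean, so the uncapped quantity would not
    converge. Raises if the opponent's net point rate is nonpositive (it
    would never reach the goal).
    """
    from lbacomp.lba import response_probability

    if rng is None:
        rng = np.random.default_rng(seed)
    p_c = response_probability(opponent, "correct")
    p_e = response_probability(opponent, "error")
    if abs(p_c + p_e - 1.0) > 0.01:
        # quadrature misses spike-like densities (near-deterministic
        # agents); fall back to a Monte Carlo accuracy estimate
        correct, _ = simulate_trials(opponent, 2000, rng)
        p_c = float(correct.mean())
    if 2.0 * p_c - 1.0 <= 1e-6:
        raise ValueError(
            f"opponent net point rate 2p-1 = {2 * p_c - 1:.3f} <= 0: goal unreachable"
        )
    fb = feedback_s if count_feedback else 0.0
    times = np.empty(n_sims)
    for i in range(n_sims):
        _, _, clock, score = _stream_until(
            opponent, rng, needed_score=goal_points, feedback_s=fb,
            max_rt=max_decision_s,
        )
        j = int(np.nonzero(score >= goal_points)[0][0])
        times[i] = clock[j] - fb
    return float(times.mean())
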