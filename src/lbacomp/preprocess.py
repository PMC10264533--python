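"""Trial exclusions and descriptive condition summaries.

Practice rounds are dropped first; then implausibly fast decisions
(<= 250 ms, likely anticipations) and implausibly slow ones (>= 5000 ms,
likely attentional lapses). Both boundaries are removed inclusively.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

__all__ = ["ExclusionReport", "apply_exclusions", "condition_summaries"]


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_removed_practice: int
    n_removed_fast: int
    n_removed_slow: int

    @property
    def n_removed(self) -> int:
        return self.n_removed_practice + self.n_removed_fast + self.n_removed_slow

    @property
    def proportion_removed(self) -> float:
        """Removed / all input rows (practice included in the denominator)."""
        return self.n_removed / self.n_input if self.n_input else 0.0

    @property
    def proportion_removed_excl_practice(self) -> float:
        """RT-based removals / non-practice rows (alternative denominator)."""
        denom = self.n_input - self.n_removed_practice
        return (self.n_removed_fast + self.n_removed_slow) / denom if denom else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_removed"] = self.n_removed
        d["proportion_removed"] = self.proportion_removed
        d["proportion_removed_excl_practice"] = self.proportion_removed_excl_practice
        return d


def apply_exclusions(
    trials: pd.DataFrame,
    fast_cutoff_ms: float = 250.0,
    slow_cutoff_ms: float = 5000.0,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop practice trials and RT outliers; row order is preserved.

    Boundary values are removed on both sides (RT <= fast cutoff or
    RT >= slow cutoff). Idempotent: re-applying to the output removes
    nothing further.
    """
    if "rt_ms" not in trials.columns:
        raise ValueError("trial table is missing required column 'rt_ms'")
    n_input = len(trials)
    practice = (
        trials["is_practice"].astype(bool)
        if "is_practice" in trials.columns
        else pd.Series(False, index=trials.index)
    )
    kept = trials.loc[~practice]
    rt = pd.to_numeric(kept["rt_ms"])
    fast = rt <= fast_cutoff_ms
    slow = rt >= slow_cutoff_ms
    report = ExclusionReport(
        n_input=n_input,
        n_removed_practice=int(practice.sum()),
        n_removed_fast=int(fast.sum()),
        n_removed_slow=int(slow.sum()),
    )
    return kept.loc[~(fast | slow)].copy(), report


def condition_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition accuracy and mean RT, weighting participants equally.

    Each participant's trials are averaged first and the participant means
    are then averaged, so participants with more recorded decisions do not
    dominate. Conditions with no trials are simply absent from the output.
    """
    per_part = (
        trials.groupby(["condition", "participant_id"], observed=True)
        .agg(accuracy=("correct", "mean"), mean_rt_ms=("rt_ms", "mean"))
        .reset_index()
    )
    out = (
        per_part.groupby("condition", observed=True)
        .agg(
            accuracy=("accuracy", "mean"),
            mean_rt_ms=("mean_rt_ms", "mean"),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
    )
    counts = trials.groupby("condition", observed=True).size().rename("n_trials")
    return out.merge(counts, on="condition")
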