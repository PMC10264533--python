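"""Trial-table file formats.

The trial table is a plain CSV, one row per decision. Times are stored in
milliseconds on disk and converted to seconds everywhere inside the library.
Condition labels are lower-case canonical (``tournament``, ``race``, ``igp``,
``dyb``); anything else is rejected rather than silently coerced.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from lbacomp.schemes import CONDITIONS

__all__ = ["TRIAL_COLUMNS", "read_trials", "write_trials", "validate_trials"]

#: Required columns of the trial CSV, in canonical order.
TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "episode_index",
    "trial_index",
    "stimulus_side",
    "response_side",
    "correct",
    "rt_ms",
    "is_practice",
    "participant_score_after",
    "opponent_score_after",
]

_SIDES = {"left", "right"}


class SchemaError(ValueError):
    """A trial table does not conform to the documented CSV schema."""


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table in place; returns it for chaining."""
    for col in TRIAL_COLUMNS:
        if col == "opponent_score_after":
            continue  # optional: empty for opponent-free schemes
        if col not in table.columns:
            raise SchemaError(f"trial table is missing required column {col!r}")
    bad = set(table["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise SchemaError(
            f"unknown condition labels {sorted(bad)!r}; canonical labels are {CONDITIONS}"
        )
    for col in ("stimulus_side", "response_side"):
        bad = set(table[col].unique()) - _SIDES
        if bad:
            raise SchemaError(f"column {col!r} contains non left/right values: {sorted(bad)!r}")
    rt = pd.to_numeric(table["rt_ms"], errors="coerce")
    if rt.isna().any():
        row = int(table.index[rt.isna()][0]) + 2  # +2: header + 1-based
        raise SchemaError(f"malformed rt_ms value near file line {row}")
    if (rt <= 0).any():
        raise SchemaError("rt_ms must be positive")
    mism = table["correct"].astype(int) != (
        table["response_side"] == table["stimulus_side"]
    ).astype(int)
    if mism.any():
        raise SchemaError("correct flag inconsistent with response_side == stimulus_side")
    return table


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV. Unknown columns are preserved."""
    table = pd.read_csv(path)
    return validate_trials(table)


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV (UTF-8, '.' decimal), canonical columns first."""
    extra = [c for c in table.columns if c not in TRIAL_COLUMNS]
    cols = [c for c in TRIAL_COLUMNS if c in table.columns] + extra
    out = table[cols].copy()
    if "opponent_score_after" in out.columns:
        # keep integer look in CSV despite NaNs for opponent-free schemes
        out["opponent_score_after"] = out["opponent_score_after"].astype("Int64")
    out.to_csv(path, index=False)


def rt_seconds(table: pd.DataFrame) -> np.ndarray:
    """RTs in seconds (library-internal unit)."""
    return table["rt_ms"].to_numpy(dtype=float) / 1000.0
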