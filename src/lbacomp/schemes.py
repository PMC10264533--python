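"""Competition scheme definitions.

Four schemes manipulate the structure of a points-scoring episode:

* ``tournament`` — beat an opponent's score within a 20-s deadline;
* ``race`` — reach an 8-point goal before the opponent (no deadline);
* ``igp`` — individual goal pursuit: reach 8 points within 20 s, no opponent;
* ``dyb`` — do-your-best: score as many points as possible within 20 s.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SchemeSpec", "SCHEMES", "CONDITIONS"]

CONDITIONS = ("tournament", "race", "igp", "dyb")


@dataclass(frozen=True)
class SchemeSpec:
    """Structure of one competition type.

    ``deadline_s``/``goal_points`` are ``None`` when the scheme has no
    deadline/goal; ``has_opponent`` marks schemes with a computerised rival.
    """

    name: str
    deadline_s: float | None
    goal_points: int | None
    has_opponent: bool

    def __post_init__(self) -> None:
        if self.name not in CONDITIONS:
            raise ValueError(f"unknown scheme {self.name!r}; expected one of {CONDITIONS}")
        if self.deadline_s is not None and self.deadline_s <= 0:
            raise ValueError("deadline_s must be positive")
        if self.goal_points is not None and self.goal_points <= 0:
            raise ValueError("goal_points must be positive")
        if self.deadline_s is None and self.goal_points is None:
            raise ValueError("a scheme needs a deadline or a goal to terminate")


SCHEMES: dict[str, SchemeSpec] = {
    "tournament": SchemeSpec("tournament", deadline_s=20.0, goal_points=None, has_opponent=True),
    "race": SchemeSpec("race", deadline_s=None, goal_points=8, has_opponent=True),
    "igp": SchemeSpec("igp", deadline_s=20.0, goal_points=8, has_opponent=False),
    "dyb": SchemeSpec("dyb", deadline_s=20.0, goal_points=None, has_opponent=False),
}
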