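"""Behavioral trial records and rule-based trial selection.

A trial of the two-target maze task starts with maze onset (t = 0 ms): two
reach targets appear, each either easy to reach, hard to reach (extra
barriers), or blocked.  On a subset of trials one key barrier changes during
the delay.  The Go cue arrives at ``delay`` ms and movement onset at
``delay + rt``.

The derived ``trial_class`` is a pure function of the initial barrier
configuration, the barrier change (if any), and the eventual choice:

- ``forced``: one side blocked throughout, no change.
- ``free``: both sides passable throughout, no change.
- ``free_to_forced``: started free; a change blocked one side.
- ``encouraged_switch_taken`` / ``..._untaken``: started forced; a change
  opened the blocked side; taken if the newly opened side was chosen.
- ``biasing_likely_change`` / ``..._unlikely_change``: free throughout with
  one easy and one hard side; a change altered a side's difficulty; "likely
  change" if the chosen side was *not* the initially easy one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

PASSABLE = ("easy", "hard")
DIFFICULTIES = ("easy", "hard", "blocked")
SIDES = ("L", "R")

TRIAL_CLASSES = (
    "forced",
    "free",
    "free_to_forced",
    "encouraged_switch_taken",
    "encouraged_switch_untaken",
    "biasing_likely_change",
    "biasing_unlikely_change",
    "other",
)


@dataclass
class BarrierChange:
    """A mid-delay change of one side's difficulty."""

    time: float            # ms relative to maze onset
    side: str              # "L" or "R"
    new_difficulty: str    # member of DIFFICULTIES

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "side": self.side,
            "new_difficulty": self.new_difficulty,
        }


@dataclass
class TrialRecord:
    trial_id: int
    maze_family: str                     # "T" or "S"
    initial_difficulty: Dict[str, str]   # side -> difficulty
    delay: float                         # Go time, ms (0 = no delay)
    move_onset: float                    # ms relative to maze onset
    choice: str                          # "L" or "R"
    success: bool
    barrier_change: Optional[BarrierChange] = None
    trial_class: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.choice not in SIDES:
            raise ValueError(f"choice must be in {SIDES}, got {self.choice!r}")
        for side in SIDES:
            if self.initial_difficulty.get(side) not in DIFFICULTIES:
                raise ValueError(
                    f"initial_difficulty[{side!r}] must be one of {DIFFICULTIES}"
                )
        if self.move_onset <= self.delay:
            raise ValueError("move_onset must exceed delay (rt > 0)")
        if not self.trial_class:
            self.trial_class = derive_trial_class(
                self.initial_difficulty, self.barrier_change, self.choice
            )

    @property
    def rt(self) -> float:
        """Reaction time: movement onset minus Go cue, ms."""
        return self.move_onset - self.delay

    def final_difficulty(self) -> Dict[str, str]:
        out = dict(self.initial_difficulty)
        if self.barrier_change is not None:
            out[self.barrier_change.side] = self.barrier_change.new_difficulty
        return out

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "maze_family": self.maze_family,
            "initial_difficulty": dict(self.initial_difficulty),
            "delay": self.delay,
            "move_onset": self.move_onset,
            "choice": self.choice,
            "success": self.success,
            "barrier_change": (
                None if self.barrier_change is None else self.barrier_change.to_dict()
            ),
            "trial_class": self.trial_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        bc = d.get("barrier_change")
        return cls(
            trial_id=int(d["trial_id"]),
            maze_family=d["maze_family"],
            initial_difficulty=dict(d["initial_difficulty"]),
            delay=float(d["delay"]),
            move_onset=float(d["move_onset"]),
            choice=d["choice"],
            success=bool(d["success"]),
            barrier_change=None if bc is None else BarrierChange(
                time=float(bc["time"]),
                side=bc["side"],
                new_difficulty=bc["new_difficulty"],
            ),
            trial_class=d.get("trial_class", ""),
        )


def other_side(side: str) -> str:
    return "R" if side == "L" else "L"


def derive_trial_class(
    initial_difficulty: Dict[str, str],
    barrier_change: Optional[BarrierChange],
    choice: str,
) -> str:
    """Classify a trial from its configuration, change, and choice."""
    init = dict(initial_difficulty)
    blocked = [s for s in SIDES if init[s] == "blocked"]
    if len(blocked) == 2:
        return "other"

    if barrier_change is None:
        if len(blocked) == 1:
            return "forced"
        return "free"

    side, new = barrier_change.side, barrier_change.new_difficulty
    if new == init[side]:
        # a no-op change carries no information; treat as unchanged
        return derive_trial_class(init, None, choice)

    if len(blocked) == 0:
        if new == "blocked":
            return "free_to_forced"
        # free throughout, one side's difficulty changed: biasing change.
        # "Likely change" if the chosen target was not the initially easy one.
        if init[choice] == "easy":
            return "biasing_unlikely_change"
        return "biasing_likely_change"

    # one side initially blocked
    if blocked[0] == side and new in PASSABLE:
        # forced became free: encouraged switch
        if choice == side:
            return "encouraged_switch_taken"
        return "encouraged_switch_untaken"
    return "other"


#: Criteria vocabulary for :func:`select_trials`.
_CRITERIA = {
    "success",            # bool
    "trial_class",        # str or sequence of str
    "min_delay",          # float
    "max_delay",          # float
    "zero_delay",         # bool: delay == 0 (True) / delay > 0 (False)
    "no_barrier_change",  # bool
    "has_barrier_change", # bool
    "min_rt",             # float
    "max_rt",             # float
    "choice",             # "L"/"R"
}


def select_trials(trials: Sequence[TrialRecord], **criteria) -> List[int]:
    """Return trial_ids of trials meeting all criteria, in input order.

    Criteria are drawn from a fixed vocabulary (``success``, ``trial_class``,
    ``min_delay``, ``max_delay``, ``zero_delay``, ``no_barrier_change``,
    ``has_barrier_change``, ``min_rt``, ``max_rt``, ``choice``); an unknown
    name raises ``ValueError``.
    """
    unknown = set(criteria) - _CRITERIA
    if unknown:
        raise ValueError(f"unknown selection criteria: {sorted(unknown)}")

    def ok(t: TrialRecord) -> bool:
        if "success" in criteria and t.success != criteria["success"]:
            return False
        if "trial_class" in criteria:
            wanted = criteria["trial_class"]
            if isinstance(wanted, str):
                wanted = (wanted,)
            if t.trial_class not in wanted:
                return False
        if "min_delay" in criteria and t.delay < criteria["min_delay"]:
            return False
        if "max_delay" in criteria and t.delay > criteria["max_delay"]:
            return False
        if "zero_delay" in criteria:
            if criteria["zero_delay"] != (t.delay == 0):
                return False
        if "no_barrier_change" in criteria and criteria["no_barrier_change"]:
            if t.barrier_change is not None:
                return False
        if "has_barrier_change" in criteria and criteria["has_barrier_change"]:
            if t.barrier_change is None:
                return False
        if "min_rt" in criteria and t.rt < criteria["min_rt"]:
            return False
        if "max_rt" in criteria and t.rt > criteria["max_rt"]:
            return False
        if "choice" in criteria and t.choice != criteria["choice"]:
            return False
        return True

    return [t.trial_id for t in trials if ok(t)]
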