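"""Simplified-PEST adaptive brightness staircase with collapsing steps.

Two staircases run in parallel — one for the high-probability (HP) distractor
side of the screen, one for the low-probability (LP) side.  On every probe
trial one side shows the fixed *standard* color and the other side shows its
staircase's current value; that side's staircase is the *tested* one.  After
the response the tested staircase moves one step toward the value at which the
observer would pick either patch equally often.  Response-side alternations
are tracked globally across the two staircases; after three consecutive
alternations the tested staircase's step halves (floored at ``min_step``),
collapsing the track onto the 50% point.  At each block boundary both
staircases restart ``block_reset_offset`` degrees away from their previous
ending point with a fresh full-size step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("salsup.staircase")

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "StaircasePair",
    "init_staircase",
    "ending_points",
    "STAIRCASE_LOG_COLUMNS",
]

Side = Literal["HP", "LP"]

#: Long-format staircase log schema; replay mode consumes the same columns.
STAIRCASE_LOG_COLUMNS = [
    "participant",
    "block",
    "probe_index",
    "tested_side",
    "value_shown",
    "step_before",
    "step_after",
    "choice_side",
    "value_after",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Tunable constants of the adaptive track (degrees on the 0-509 spectrum)."""

    initial_step: float = 64.0
    start_values: tuple[float, float] = (28.0, 350.0)
    block_reset_offset: float = 96.0
    alternations_to_halve: int = 3
    spectrum_range: tuple[float, float] = (0.0, 509.0)
    min_step: float = 1.0
    polarity: Literal["brighter", "darker"] = "brighter"
    #: Audit switch: apply the divergent update the task description prints
    #: (choosing the staircased patch makes it *brighter* next time) instead of
    #: the convergent reading used by default.
    literal_update_rule: bool = False

    def __post_init__(self) -> None:
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")
        lo, hi = self.spectrum_range
        for v in self.start_values:
            if not (lo <= v <= hi):
                raise ValueError(f"start value {v} outside spectrum range {self.spectrum_range}")
        if self.polarity not in ("brighter", "darker"):
            raise ValueError(f"invalid polarity {self.polarity!r}")


@dataclass
class StaircaseState:
    """One side's adaptive track."""

    side: Side
    current_value: float
    step: float
    history: list[tuple[float, bool]] = field(default_factory=list)  # (value shown, chose staircased)

    def clamp(self, config: StaircaseConfig) -> None:
        lo, hi = config.spectrum_range
        self.current_value = min(max(self.current_value, lo), hi)


def init_staircase(
    config: StaircaseConfig,
    side: Side,
    previous_end: float | None,
    rng: np.random.Generator,
) -> StaircaseState:
    """Start (or restart) one side's staircase.

    First block: the value is drawn uniformly from ``config.start_values``.
    Later blocks: ``previous_end`` plus or minus ``block_reset_offset`` with
    random sign, clamped to the spectrum.  The step resets to ``initial_step``.
    """
    if previous_end is None:
        value = float(rng.choice(config.start_values))
    else:
        lo, hi = config.spectrum_range
        if not (lo <= previous_end <= hi):
            raise ValueError(f"previous_end {previous_end} outside spectrum range")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        value = previous_end + sign * config.block_reset_offset
    state = StaircaseState(side=side, current_value=value, step=config.initial_step)
    state.clamp(config)
    return state


class StaircasePair:
    """The HP and LP staircases plus the global alternation counter.

    Alternation bookkeeping (did the observer pick a different *side* than on
    the previous probe trial?) is shared between the two tracks; step halving
    applies only to the staircase that was tested on the triggering trial, and
    the counter resets after each halving.
    """

    def __init__(
        self,
        config: StaircaseConfig,
        rng: np.random.Generator,
        previous_ends: dict[Side, float] | None = None,
    ) -> None:
        self.config = config
        self.states: dict[Side, StaircaseState] = {
            side: init_staircase(
                config, side, None if previous_ends is None else previous_ends[side], rng
            )
            for side in ("HP", "LP")
        }
        self.last_choice_side: Side | None = None
        self.consecutive_alternations: int = 0

    def value(self, side: Side) -> float:
        return self.states[side].current_value

    def ending_values(self) -> dict[Side, float]:
        return {side: st.current_value for side, st in self.states.items()}

    def update(self, tested_side: Side, choice_side: Side) -> StaircaseState:
        """Advance the tested staircase after one probe response.

        The staircased (non-standard) patch was the one on ``tested_side``;
        ``choice_side`` is the side the observer selected.  Returns the updated
        state of the tested staircase.
        """
        if tested_side not in self.states:
            raise ValueError(f"unknown tested side {tested_side!r}")
        if choice_side not in ("HP", "LP"):
            raise ValueError(f"unknown choice side {choice_side!r}")
        state = self.states[tested_side]
        chose_staircased = choice_side == tested_side
        state.history.append((state.current_value, chose_staircased))

        # Convergent direction: under the brighter task, picking the
        # staircased patch means it looked brighter than the standard, so its
        # value moves down toward the subjective match; not picking it moves
        # the value up.  The darker task mirrors this.  The literal rule from
        # the task description is divergent (chosen -> brighter).
        towards_dim = chose_staircased if self.config.polarity == "brighter" else not chose_staircased
        if self.config.literal_update_rule:
            towards_dim = not towards_dim
        state.current_value += -state.step if towards_dim else state.step
        state.clamp(self.config)

        if self.last_choice_side is not None:
            if choice_side != self.last_choice_side:
                self.consecutive_alternations += 1
            else:
                self.consecutive_alternations = 0
        self.last_choice_side = choice_side
        if self.consecutive_alternations >= self.config.alternations_to_halve:
            state.step = max(state.step / 2.0, self.config.min_step)
            self.consecutive_alternations = 0
        return state


def ending_points(logs: pd.DataFrame, n_blocks: int) -> pd.DataFrame:
    """Per-block, per-side staircase ending values plus cross-block means.

    ``logs`` is the long-format staircase log (:data:`STAIRCASE_LOG_COLUMNS`),
    possibly spanning several participants.  The ending point of a block is the
    staircase value after the final update of that side in that block.  Blocks
    with no update for a side are flagged missing and excluded from the mean.

    Returns a tidy frame with columns ``participant, side, block, ending_value``
    where ``block`` is 1..n_blocks or the string ``"mean"`` for the cross-block
    average.
    """
    required = {"participant", "block", "probe_index", "tested_side", "value_after"}
    missing = required - set(logs.columns)
    if missing:
        raise ValueError(f"staircase log is missing columns: {sorted(missing)}")
    rows = []
    for (pid, side), grp in logs.groupby(["participant", "tested_side"], sort=True):
        finals = {}
        for block in range(1, n_blocks + 1):
            blk = grp[grp["block"] == block]
            if blk.empty:
                logger.warning(
                    "participant %s side %s block %d has no staircase updates", pid, side, block
                )
                continue
            finals[block] = float(blk.sort_values("probe_index")["value_after"].iloc[-1])
        for block, val in finals.items():
            rows.append({"participant": pid, "side": side, "block": block, "ending_value": val})
        if finals:
            rows.append(
                {
                    "participant": pid,
                    "side": side,
                    "block": "mean",
                    "ending_value": float(np.mean(list(finals.values()))),
                }
            )
    return pd.DataFrame(rows, columns=["participant", "side", "block", "ending_value"])
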