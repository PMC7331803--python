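"""Adaptive step-height scheduling for the stepping-down task.

Each participant confronts up to six step heights from the fixed grid
0.025--0.150 m in 0.025 m increments, six stepping-down trials per height,
starting at 0.050 m.  The schedule brackets the critical switching height:
it seeks one height with six heel landings out of six (the *heel anchor*,
below the switching height) and one with six toe landings (the *toe
anchor*, above it).

The adaptation rule (the cited source protocol is not restated in the
published methods; this fixed rule reproduces its stated bracketing
behaviour) is: after each 6-trial block,

* all heel and no toe anchor yet -> smallest unvisited height above the
  current one;
* all toe and no heel anchor yet -> largest unvisited height below;
* mixed block -> move toward whichever anchor is missing (upward preferred
  when both are missing);
* stop when both anchors exist, the grid is exhausted in the needed
  direction, or all six heights have been visited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "HEIGHT_GRID",
    "TRIALS_PER_BLOCK",
    "STOP",
    "ProtocolState",
    "TrialRecord",
    "first_height",
    "next_height",
    "run_protocol",
]

HEIGHT_GRID: tuple[float, ...] = (0.025, 0.050, 0.075, 0.100, 0.125, 0.150)
TRIALS_PER_BLOCK = 6
STOP = "STOP"


@dataclass(frozen=True)
class TrialRecord:
    """One stepping-down trial."""

    participant_id: str
    condition: str  # 'low' | 'high'
    block_index: int
    trial_index: int
    step_height_m: float
    strategy: str  # 'heel' | 'toe'


@dataclass
class ProtocolState:
    visited: list[float] = field(default_factory=list)
    current: float | None = None
    blocks_completed: int = 0
    anchor_heel: bool = False  # a visited height with 6/6 heel landings
    anchor_toe: bool = False  # 6/6 toe landings


def first_height(start: float = 0.050) -> float:
    """The first evaluated step height (0.050 m unless overridden)."""
    if start not in HEIGHT_GRID:
        raise ValueError(f"start height {start} not on grid {HEIGHT_GRID}")
    return start


def _unvisited(state: ProtocolState):
    return [h for h in HEIGHT_GRID if h not in state.visited]


def next_height(state: ProtocolState, last_block_outcomes: Sequence[str]):
    """Next height per the bracketing rule, or ``STOP``.

    ``last_block_outcomes`` are the six strategy labels of the block just
    completed at ``state.current``; the state's anchors must already
    reflect that block.
    """
    if len(last_block_outcomes) != TRIALS_PER_BLOCK:
        raise ValueError(
            f"a block has exactly {TRIALS_PER_BLOCK} trials, "
            f"got {len(last_block_outcomes)}"
        )
    if state.current not in HEIGHT_GRID:
        raise ValueError(f"current height {state.current} off grid")
    if state.anchor_heel and state.anchor_toe:
        return STOP
    if len(state.visited) >= len(HEIGHT_GRID):
        return STOP

    n_heel = sum(1 for s in last_block_outcomes if s == "heel")
    above = [h for h in _unvisited(state) if h > state.current]
    below = [h for h in _unvisited(state) if h < state.current]

    if n_heel == TRIALS_PER_BLOCK:
        direction = "up"  # heel anchor found at/below here; hunt the toe anchor
    elif n_heel == 0:
        direction = "down"
    else:  # mixed block: move toward the missing anchor, up preferred
        direction = "up" if not state.anchor_toe else "down"

    if direction == "up":
        return min(above) if above else STOP
    return max(below) if below else STOP


def run_protocol(
    responder: Callable[[float], str],
    participant_id: str = "p0",
    condition: str = "low",
    start: float = 0.050,
) -> list[TrialRecord]:
    """Run the adaptive protocol against a responder callable.

    ``responder(step_height) -> 'heel' | 'toe'`` supplies one landing
    strategy per trial (synthetic participant or replayed recording).
    Returns at most 36 trial records, six per visited height.
    """
    state = ProtocolState(current=first_height(start))
    records: list[TrialRecord] = []
    while True:
        block: list[str] = []
        for j in range(TRIALS_PER_BLOCK):
            s = responder(state.current)
            if s not in ("heel", "toe"):
                raise ValueError(f"responder returned {s!r}")
            block.append(s)
            records.append(
                TrialRecord(
                    participant_id,
                    condition,
                    state.blocks_completed,
                    j,
                    state.current,
                    s,
                )
            )
        state.visited.append(state.current)
        state.blocks_completed += 1
        n_heel = block.count("heel")
        if n_heel == TRIALS_PER_BLOCK:
            state.anchor_heel = True
        elif n_heel == 0:
            state.anchor_toe = True
        nxt = next_height(state, block)
        if nxt == STOP:
            return records
        state.current = nxt
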