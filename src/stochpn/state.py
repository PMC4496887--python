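"""Shared simulation state, trajectory recording and constant-place updates."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expressions import ConditionalExpression, Expression, evaluate, evaluate_conditional
from .net import PetriNet

__all__ = ["SimulationState", "Trajectory", "update_constant_places"]

logger = logging.getLogger(__name__)

STATUS_RUNNING = "running"
STATUS_DEAD = "dead marking"


@dataclass
class SimulationState:
    """Mutable state threaded through every firing engine.

    ``clock`` is the simulated time in seconds (the ``Time`` variable);
    the asynchronous and synchronous modes never advance it.
    ``pending_times`` holds absolute scheduled firing times and is used
    only by the constant-rate stochastic mode.
    """

    net: PetriNet
    marking: dict[str, int]
    rng: np.random.Generator
    clock: float = 0.0
    step_count: int = 0
    pending_times: dict[str, float] = field(default_factory=dict)
    status: str = STATUS_RUNNING
    firing_counts: dict[str, int] = field(default_factory=dict)
    last_fired: str | None = None

    def count_firing(self, t: str, n: int = 1) -> None:
        self.firing_counts[t] = self.firing_counts.get(t, 0) + n

    def bindings(self) -> dict[str, float]:
        """Expression bindings: Time plus non-constant place token counts."""
        b: dict[str, float] = {
            p: float(c) for p, c in self.marking.items() if not self.net.is_constant(p)
        }
        b["Time"] = self.clock
        return b


@dataclass
class Trajectory:
    """Time-stamped markings plus the firing log.

    The first record always carries the initial marking with no fired
    transition.  ``times`` is simulated seconds for time-driven modes and
    the step index for the asynchronous/synchronous modes.
    """

    places: list[str]
    times: list[float] = field(default_factory=list)
    fired: list[str | None] = field(default_factory=list)
    counts: list[tuple[int, ...]] = field(default_factory=list)
    status: str = STATUS_RUNNING
    firing_counts: dict[str, int] = field(default_factory=dict)
    step_count: int = 0

    def record(self, time: float, fired: str | None, marking: Mapping[str, int]) -> None:
        self.times.append(time)
        self.fired.append(fired)
        self.counts.append(tuple(int(marking.get(p, 0)) for p in self.places))

    def __len__(self) -> int:
        return len(self.times)

    def marking_at(self, index: int) -> dict[str, int]:
        return dict(zip(self.places, self.counts[index]))

    def final_marking(self) -> dict[str, int]:
        return self.marking_at(-1)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per record, one column per place."""
        frame = pd.DataFrame(self.counts, columns=self.places)
        frame.insert(0, "time", self.times)
        frame.insert(1, "fired", [f if f is not None else "" for f in self.fired])
        return frame


def update_constant_places(
    state: SimulationState,
    expressions: Mapping[str, Expression | ConditionalExpression],
) -> set[str]:
    """Re-evaluate constant-place expressions against the current state.

    Called after every simulation step ("expressions are evaluated after
    each simulation step").  Non-integer values are rounded to the
    nearest integer; negative results clamp to zero with a warning since
    a marking cannot go negative.  Returns the places whose count
    changed, so engines can invalidate dependent waiting times or
    propensities.
    """
    bindings = state.bindings()
    changed: set[str] = set()
    for place, expr in expressions.items():
        if isinstance(expr, ConditionalExpression):
            value = evaluate_conditional(expr, bindings)
        else:
            value = evaluate(expr, bindings)
        count = int(round(value))
        if count < 0:
            logger.warning(
                "constant place %r evaluated to %g; clamping to 0", place, value
            )
            count = 0
        if state.marking.get(place, 0) != count:
            state.marking[place] = count
            changed.add(place)
    return changed
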