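"""Asynchronous, synchronous and constant-rate stochastic firing engines.

* **Asynchronous** — one uniformly chosen enabled transition fires per
  step; no time is consumed.
* **Synchronous** — a random subset of the enabled transitions (all of
  them by default, or a fraction) fires "simultaneously": the subset is
  fired in a uniformly random order, each transition re-checked against
  the evolving marking so that conflicts over shared tokens are resolved
  randomly with equal probability.
* **Stochastic (constant rate)** — every enabled transition waits an
  Exp(lambda) time with a per-transition, modeler-supplied firing rate;
  the transition with the smallest waiting time fires and the clock
  advances to it.  Waiting times are recomputed lazily: only for
  transitions whose pre-place counts changed (sound by memorylessness of
  the exponential), plus the post-transitions of constant places on
  every step.

Marking-dependent kinetics belong to the SSA engines in
:mod:`stochpn.gillespie`; the stochastic mode here uses constant rates.
"""

from __future__ import annotations

import math
from typing import Mapping

from .expressions import ConditionalExpression, Expression
from .net import fire, is_enabled
from .state import STATUS_DEAD, SimulationState, update_constant_places

__all__ = ["step_async", "step_sync", "schedule_stochastic", "step_stochastic"]

ConstantExprs = Mapping[str, "Expression | ConditionalExpression"]


def _enabled(state: SimulationState) -> list[str]:
    return [t for t in state.net.transitions if is_enabled(state.net, state.marking, t)]


def _after_step(state: SimulationState, constant_exprs: ConstantExprs | None) -> set[str]:
    if constant_exprs:
        return update_constant_places(state, constant_exprs)
    return set()


def step_async(
    state: SimulationState, constant_exprs: ConstantExprs | None = None
) -> SimulationState:
    """Fire one uniformly chosen enabled transition; clock unchanged."""
    enabled = _enabled(state)
    if not enabled:
        state.status = STATUS_DEAD
        return state
    t = enabled[int(state.rng.integers(len(enabled)))]
    state.marking = fire(state.net, state.marking, t)
    state.step_count += 1
    state.count_firing(t)
    state.last_fired = t
    _after_step(state, constant_exprs)
    return state


def step_sync(
    state: SimulationState,
    fraction: float = 1.0,
    constant_exprs: ConstantExprs | None = None,
) -> SimulationState:
    """Fire a random ceil(fraction*|enabled|)-subset in random order.

    Transitions disabled by earlier firings within the same step are
    skipped, not re-drawn.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    enabled = _enabled(state)
    if not enabled:
        state.status = STATUS_DEAD
        return state
    k = math.ceil(fraction * len(enabled))
    selected = state.rng.choice(len(enabled), size=k, replace=False)
    order = state.rng.permutation(selected)
    fired_now = []
    for idx in order:
        t = enabled[int(idx)]
        if is_enabled(state.net, state.marking, t):
            state.marking = fire(state.net, state.marking, t)
            state.count_firing(t)
            fired_now.append(t)
    state.last_fired = "+".join(fired_now) if fired_now else None
    state.step_count += 1
    _after_step(state, constant_exprs)
    return state


def _draw_exponential(state: SimulationState, lam: float) -> float:
    # inversion: -ln(1-U)/lambda, U uniform in [0,1)
    return -math.log1p(-state.rng.random()) / lam


def schedule_stochastic(state: SimulationState, t: str, lam: float) -> SimulationState:
    """Schedule ``t`` at clock + Exp(lam); requires ``t`` enabled, lam > 0."""
    if lam <= 0:
        raise ValueError(f"firing rate for {t!r} must be positive, got {lam}")
    if not is_enabled(state.net, state.marking, t):
        raise ValueError(f"cannot schedule disabled transition {t!r}")
    state.pending_times[t] = state.clock + _draw_exponential(state, lam)
    return state


def _sync_pending(state: SimulationState, rates: Mapping[str, float]) -> None:
    """Establish the invariant: pending times exactly for enabled transitions."""
    for t in state.net.transitions:
        enabled = is_enabled(state.net, state.marking, t)
        if enabled and t not in state.pending_times:
            schedule_stochastic(state, t, rates[t])
        elif not enabled and t in state.pending_times:
            del state.pending_times[t]


def step_stochastic(
    state: SimulationState,
    rates: Mapping[str, float],
    constant_exprs: ConstantExprs | None = None,
) -> SimulationState:
    """Fire the transition with the smallest pending waiting time.

    Ties are broken uniformly at random.  After firing, waiting times
    are refreshed only where required: for transitions whose pre-place
    token counts changed (including those newly enabled or disabled) and
    for all post-transitions of constant places.
    """
    _sync_pending(state, rates)
    if not state.pending_times:
        state.status = STATUS_DEAD
        return state
    tmin = min(state.pending_times.values())
    candidates = [t for t in state.net.transitions if state.pending_times.get(t) == tmin]
    if len(candidates) > 1:
        t = candidates[int(state.rng.integers(len(candidates)))]
    else:
        t = candidates[0]

    before = state.marking
    state.marking = fire(state.net, state.marking, t)
    state.clock = tmin
    state.step_count += 1
    state.count_firing(t)
    state.last_fired = t
    del state.pending_times[t]

    changed = {p for p in state.net.places if state.marking.get(p, 0) != before.get(p, 0)}
    changed |= _after_step(state, constant_exprs)

    stale = {t}
    for p in changed:
        stale |= state.net.post_transitions(p)
    for p in state.net.constant_places:
        stale |= state.net.post_transitions(p)
    for s in stale:
        state.pending_times.pop(s, None)
    # fresh draws (or removal) happen via _sync_pending on the next call;
    # do it now so pending_times reflects the post-step state
    _sync_pending(state, rates)
    return state
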