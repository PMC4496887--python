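"""Run orchestration: setups, single runs and seeded replicate sets.

A :class:`SimulationSetup` bundles everything a run needs besides the
net itself: the mode, the end condition (a step count or a simulated
end time), the seed, initial token counts or concentrations, constant
place expressions, per-transition rates, and tau-leaping configuration.
Replicate sets derive one independent RNG stream per replicate from the
master seed via ``numpy.random.SeedSequence.spawn``, so results are a
pure function of (setup, master seed, replicate index) and independent
of any worker scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expressions import ConditionalExpression, Expression, parse, parse_conditional
from .gillespie import LeapConfig, SSASimulator
from .modes import step_async, step_stochastic, step_sync
from .net import PetriNet
from .state import STATUS_RUNNING, SimulationState, Trajectory, update_constant_places
from .units import ConversionContext, RateSpec, concentration_to_molecules

__all__ = ["SimulationSetup", "ReplicateSet", "run", "run_replicates", "MODES"]

MODES = ("async", "sync", "stochastic", "ssa", "tau")

MAX_REPLICATES = 500


@dataclass
class SimulationSetup:
    """Everything needed to (re)run a simulation, serializable to XML."""

    mode: str
    steps: int | None = None
    t_end: float | None = None
    seed: int = 0
    initial_counts: dict[str, int] = field(default_factory=dict)
    initial_concentrations: dict[str, float] = field(default_factory=dict)
    volume: float | None = None
    avogadro: float = 6e23
    constant_expressions: dict[str, str] = field(default_factory=dict)
    rates: dict[str, RateSpec] = field(default_factory=dict)
    fraction: float = 1.0
    leap: LeapConfig = field(default_factory=LeapConfig)
    replicates: int = 1
    record_interval: float | None = None

    def conversion(self) -> ConversionContext | None:
        if self.volume is None:
            return None
        return ConversionContext(self.volume, self.avogadro)

    def validate(self, net: PetriNet) -> None:
        """Raise ValueError on any inconsistency, before simulation starts."""
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if (self.steps is None) == (self.t_end is None):
            raise ValueError("exactly one of steps / t_end must be set")
        if self.steps is not None and self.steps < 0:
            raise ValueError("steps must be non-negative")
        if self.t_end is not None and self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.replicates < 1 or self.replicates > MAX_REPLICATES:
            raise ValueError(f"replicates must be in [1, {MAX_REPLICATES}]")
        if self.initial_concentrations and self.volume is None:
            raise ValueError("initial concentrations given but no volume")
        places = set(net.places)
        transitions = set(net.transitions)
        for p, n in self.initial_counts.items():
            if p not in places:
                raise ValueError(f"initial count for unknown place {p!r}")
            if n < 0:
                raise ValueError(f"negative initial count for place {p!r}")
        for p in self.initial_concentrations:
            if p not in places:
                raise ValueError(f"initial concentration for unknown place {p!r}")
        for p in self.constant_expressions:
            if p not in places:
                raise ValueError(f"constant expression for unknown place {p!r}")
            if not net.is_constant(p):
                raise ValueError(f"place {p!r} is not a constant place")
        for t in self.rates:
            if t not in transitions:
                raise ValueError(f"rate for unknown transition {t!r}")
        if self.mode in ("ssa", "tau", "stochastic"):
            missing = transitions - set(self.rates)
            if missing:
                raise ValueError(f"no rate given for transitions {sorted(missing)}")

    def initial_marking(self, net: PetriNet) -> dict[str, int]:
        m = {p: 0 for p in net.places}
        m.update({p: int(n) for p, n in self.initial_counts.items()})
        if self.initial_concentrations:
            ctx = self.conversion()
            for p, conc in self.initial_concentrations.items():
                m[p] = concentration_to_molecules(conc, ctx)
        return m

    def compiled_constant_expressions(
        self,
    ) -> dict[str, Expression | ConditionalExpression]:
        out: dict[str, Expression | ConditionalExpression] = {}
        for p, text in self.constant_expressions.items():
            # a conditional is the general form; a bare expression is a
            # degenerate one-case conditional, so one parser covers both
            out[p] = parse_conditional(text)
        return out


@dataclass
class ReplicateSet:
    """Trajectories of independent replicates plus their derived seeds."""

    trajectories: list[Trajectory]
    seeds: list[int]
    master_seed: int

    def __len__(self) -> int:
        return len(self.trajectories)

    def summary(self, grid: np.ndarray | None = None) -> pd.DataFrame:
        """Per-place mean and standard deviation over a common time grid.

        Trajectories are sampled zero-order-hold (the marking between
        events is the marking after the previous event).
        """
        if not self.trajectories:
            raise ValueError("empty replicate set")
        places = self.trajectories[0].places
        if grid is None:
            t_max = min(tr.times[-1] for tr in self.trajectories)
            grid = np.linspace(0.0, t_max, 101)
        sampled = np.empty((len(self.trajectories), len(grid), len(places)))
        for i, tr in enumerate(self.trajectories):
            times = np.asarray(tr.times)
            counts = np.asarray(tr.counts)
            idx = np.clip(np.searchsorted(times, grid, side="right") - 1, 0, None)
            sampled[i] = counts[idx]
        frames = {"time": grid}
        for j, p in enumerate(places):
            frames[f"{p}_mean"] = sampled[:, :, j].mean(axis=0)
            frames[f"{p}_sd"] = sampled[:, :, j].std(axis=0, ddof=1) if len(self) > 1 else 0.0
        return pd.DataFrame(frames)


def _stochastic_rates(setup: SimulationSetup, net: PetriNet) -> dict[str, float]:
    rates = {}
    for t, spec in setup.rates.items():
        if spec.kind != "stochastic":
            raise ValueError(
                f"stochastic mode uses constant per-transition firing rates; "
                f"transition {t!r} has kind {spec.kind!r}"
            )
        rates[t] = float(spec.value)
    return rates


def _should_record(traj: Trajectory, time: float, interval: float | None) -> bool:
    if interval is None:
        return True
    return time - traj.times[-1] >= interval


def run(net: PetriNet, setup: SimulationSetup, rng: np.random.Generator | None = None) -> Trajectory:
    """Execute one simulation; deterministic given the setup's seed.

    Returns the trajectory including per-transition firing counts, the
    total step count, and a termination status ("running" means the end
    condition was reached; "dead marking" means no transition was
    enabled before that).
    """
    setup.validate(net)
    if rng is None:
        rng = np.random.default_rng(setup.seed)
    marking = setup.initial_marking(net)
    const_exprs = setup.compiled_constant_expressions()
    traj = Trajectory(places=list(net.places))

    if setup.mode in ("ssa", "tau"):
        sim = SSASimulator(
            net,
            marking,
            setup.rates,
            rng,
            conversion=setup.conversion(),
            constant_exprs=const_exprs,
            leap=setup.leap,
        )
        state = sim.state
        traj.record(state.clock, None, state.marking)
        step = sim.step_exact if setup.mode == "ssa" else sim.step_tau_leap
        while _more(state, setup):
            if not step():
                break
            if _should_record(traj, state.clock, setup.record_interval):
                traj.record(state.clock, state.last_fired, state.marking)
    else:
        state = SimulationState(net=net, marking=marking, rng=rng)
        if const_exprs:
            update_constant_places(state, const_exprs)
        traj.record(0.0, None, state.marking)
        rates = _stochastic_rates(setup, net) if setup.mode == "stochastic" else None
        while _more(state, setup):
            if setup.mode == "async":
                step_async(state, const_exprs)
            elif setup.mode == "sync":
                step_sync(state, setup.fraction, const_exprs)
            else:
                step_stochastic(state, rates, const_exprs)
            if state.status != STATUS_RUNNING:
                break
            time = state.clock if setup.mode == "stochastic" else float(state.step_count)
            if _should_record(traj, time, setup.record_interval):
                traj.record(time, state.last_fired, state.marking)

    final_time = state.clock if setup.mode in ("ssa", "tau", "stochastic") else float(state.step_count)
    if traj.times and traj.times[-1] != final_time:
        traj.record(final_time, state.last_fired, state.marking)
    traj.status = state.status
    traj.firing_counts = dict(state.firing_counts)
    traj.step_count = state.step_count
    return traj


def _more(state: SimulationState, setup: SimulationSetup) -> bool:
    if setup.steps is not None:
        return state.step_count < setup.steps
    return state.clock < setup.t_end


def run_replicates(
    net: PetriNet, setup: SimulationSetup, n: int, master_seed: int
) -> ReplicateSet:
    """Run ``n`` independent replicates with streams derived from one seed."""
    if n < 1:
        raise ValueError(f"replicate count must be >= 1, got {n}")
    if n > MAX_REPLICATES:
        raise ValueError(f"replicate count must be <= {MAX_REPLICATES}, got {n}")
    children = np.random.SeedSequence(master_seed).spawn(n)
    trajectories = []
    seeds = []
    for child in children:
        rng = np.random.Generator(np.random.PCG64(child))
        trajectories.append(run(net, replace(setup, replicates=1), rng=rng))
        seeds.append(int(child.generate_state(1)[0]))
    return ReplicateSet(trajectories, seeds, master_seed)
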