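"""Packaged models: insulin-receptor recycling and small test nets.

The insulin-receptor (IR) recycling model tracks one cell's receptor
pool through six species: free insulin (an externally regulated,
constant place), the free membrane receptor IR, the receptor-insulin
complex IR_I, its phosphorylated (active) form IR_I_P, the internalized
phosphorylated complex IR_I_P_Int, and the internal unbound pool
IR_Int.  Eleven mass-action reactions connect them: insulin binding and
dissociation, (de)phosphorylation at the membrane and in the cytosol,
internalization and recycling of both receptor forms, degradation of
the internal pool, and a zero-order synthesis whose rate switches to a
higher value when the internal pool (IR_Int + IR_I_P_Int) falls below
its steady-state concentration of 1e-13 M.

The reaction volume is 1e-9 l.  The external insulin level follows a
daily profile: a basal 6e-11 M, with meals at 09:00, 13:00 and 18:00
each jumping the level to 3.6e-10 M followed by a negative-exponential
return to basal within three hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .net import PetriNet
from .runner import SimulationSetup, run
from .state import Trajectory
from .units import ConversionContext, RateSpec, concentration_to_molecules

__all__ = [
    "IR_VOLUME",
    "InsulinProfileParams",
    "insulin_profile_expression",
    "build_ir_model",
    "run_ir_simulation",
    "build_birth_death",
]

IR_VOLUME = 1e-9  # liters

#: Initial concentrations (molar) of the IR model species.
IR_INITIAL_CONCENTRATIONS = {
    "IR": 9e-13,
    "IR_I": 0.0,
    "IR_I_P": 0.0,
    "IR_I_P_Int": 0.0,
    "IR_Int": 1e-13,
}

#: Mass-action rate constants; orders follow from the net structure
#: (Bind_Insulin is second order, Synthesis zero order, the rest first).
IR_RATE_CONSTANTS = {
    "Bind_Insulin": 1e6,  # M^-1 s^-1
    "Diss_Insulin": 3.33e-3,  # s^-1
    "Inter_IR": 5.56e-6,
    "Phos_IR_I": 41.66,
    "Dephos_IR_I_P": 3.33e-3,
    "Inter_IR_I_P": 3.5e-5,
    "Deinter_IR_I_P": 3.5e-6,
    "Dephos_IR_I_P_Int": 7.68e-3,
    "Deinter_IR": 5e-5,
    "Degradation": 2.783e-6,
}

SYNTHESIS_RATE_HIGH = 1.67e-18  # M s^-1, below the steady-state pool
SYNTHESIS_RATE_BASE = 2.78e-19  # M s^-1, at or above it
SYNTHESIS_THRESHOLD = 1e-13  # M, internal-pool steady state

IR_ARCS = [
    ("Insulin", "Bind_Insulin"),
    ("IR", "Bind_Insulin"),
    ("Bind_Insulin", "IR_I"),
    ("IR_I", "Diss_Insulin"),
    ("Diss_Insulin", "IR"),
    ("IR_I", "Phos_IR_I"),
    ("Phos_IR_I", "IR_I_P"),
    ("IR_I_P", "Dephos_IR_I_P"),
    ("Dephos_IR_I_P", "IR_I"),
    ("IR", "Inter_IR"),
    ("Inter_IR", "IR_Int"),
    ("IR_I_P", "Inter_IR_I_P"),
    ("Inter_IR_I_P", "IR_I_P_Int"),
    ("IR_I_P_Int", "Deinter_IR_I_P"),
    ("Deinter_IR_I_P", "IR_I_P"),
    ("IR_I_P_Int", "Dephos_IR_I_P_Int"),
    ("Dephos_IR_I_P_Int", "IR_Int"),
    ("IR_Int", "Deinter_IR"),
    ("Deinter_IR", "IR"),
    ("IR_Int", "Degradation"),
    ("Synthesis", "IR_Int"),
]


@dataclass(frozen=True)
class InsulinProfileParams:
    """Parameters of the daily external-insulin profile."""

    basal: float = 6e-11  # molar
    peak: float = 3.6e-10  # molar
    meal_times_hours: tuple[float, ...] = (9.0, 13.0, 18.0)
    return_hours: float = 3.0
    period_hours: float = 24.0

    def __post_init__(self) -> None:
        if not 0.0 < self.basal < self.peak:
            raise ValueError("need peak > basal > 0")
        if any(not 0.0 <= m < self.period_hours for m in self.meal_times_hours):
            raise ValueError("meal times must fall within one period")
        meals = sorted(self.meal_times_hours)
        for a, b in zip(meals, meals[1:]):
            if a + self.return_hours > b:
                raise ValueError(
                    f"meal windows overlap: meal at {a} h has not returned to "
                    f"basal before the meal at {b} h"
                )


def insulin_profile_expression(
    params: InsulinProfileParams | None = None,
    ctx: ConversionContext | None = None,
) -> str:
    """Conditional-expression text for the insulin constant place.

    One time-gated case per meal plus a final condition-free basal case;
    values are molecule counts (the concentration scaled by N_A * V).
    The post-meal decay is basal + (peak - basal) * exp(-(t - t_meal)/tau)
    with tau fixed so that the excess over basal has fallen to 5% of the
    basal level when the stated return-to-basal duration has elapsed.
    """
    params = params or InsulinProfileParams()
    ctx = ctx or ConversionContext(IR_VOLUME)
    basal_n = ctx.avogadro * params.basal * ctx.volume
    peak_n = ctx.avogadro * params.peak * ctx.volume
    delta_n = peak_n - basal_n
    return_s = params.return_hours * 3600.0
    tau = return_s / math.log(delta_n / (0.05 * basal_n))
    period_s = params.period_hours * 3600.0
    day = f"(Time % {period_s!r})"
    cases = []
    for meal_h in params.meal_times_hours:
        start = meal_h * 3600.0
        end = start + return_s
        cases.append(
            f"{day} >= {start!r} ; {day} < {end!r} : "
            f"{basal_n!r} + {delta_n!r} * exp(-({day} - {start!r}) / {tau!r})"
        )
    cases.append(f"{basal_n!r}")
    return " ; ".join(cases)


def build_ir_model(
    profile: InsulinProfileParams | None = None,
) -> tuple[PetriNet, SimulationSetup]:
    """The IR recycling net plus a ready-to-run exact-SSA setup.

    The setup covers a 48 h horizon with the daily insulin profile and
    records the marking once a simulated minute.
    """
    net = PetriNet()
    net.add_place("Insulin", constant=True)
    for p in ("IR", "IR_I", "IR_I_P", "IR_I_P_Int", "IR_Int"):
        net.add_place(p)
    transitions = list(IR_RATE_CONSTANTS) + ["Synthesis"]
    for t in transitions:
        net.add_transition(t)
    for source, target in IR_ARCS:
        net.add_arc(source, target)

    ctx = ConversionContext(IR_VOLUME)
    threshold_n = concentration_to_molecules(SYNTHESIS_THRESHOLD, ctx)
    synthesis = (
        f"IR_Int + IR_I_P_Int >= {threshold_n} : {SYNTHESIS_RATE_BASE!r} ; "
        f"{SYNTHESIS_RATE_HIGH!r}"
    )
    rates = {t: RateSpec.mass_action(k) for t, k in IR_RATE_CONSTANTS.items()}
    rates["Synthesis"] = RateSpec.conditional(synthesis)

    setup = SimulationSetup(
        mode="ssa",
        t_end=48 * 3600.0,
        seed=42,
        volume=IR_VOLUME,
        initial_concentrations=dict(IR_INITIAL_CONCENTRATIONS),
        constant_expressions={"Insulin": insulin_profile_expression(profile, ctx)},
        rates=rates,
        record_interval=60.0,
    )
    return net, setup


def run_ir_simulation(hours: float, seed: int) -> Trajectory:
    """Exact-SSA run of the IR model over ``hours`` with the daily profile."""
    if hours <= 0:
        raise ValueError(f"hours must be positive, got {hours}")
    net, setup = build_ir_model()
    setup.t_end = hours * 3600.0
    setup.seed = seed
    return run(net, setup)


def build_birth_death(
    c_birth: float, c_death: float, *, n0: int = 0, events: int = 1000, seed: int = 0
) -> tuple[PetriNet, SimulationSetup]:
    """Immigration-death net: 0 -> A at c_birth, A -> 0 at c_death.

    Under the exact SSA the stationary occupancy of A is
    Poisson(c_birth / c_death).
    """
    if c_birth < 0 or c_death <= 0:
        raise ValueError("need c_birth >= 0 and c_death > 0")
    net = PetriNet()
    net.add_place("A")
    net.add_transition("birth")
    net.add_transition("death")
    net.add_arc("birth", "A")
    net.add_arc("A", "death")
    setup = SimulationSetup(
        mode="ssa",
        steps=events,
        seed=seed,
        initial_counts={"A": n0},
        rates={
            "birth": RateSpec.stochastic(c_birth),
            "death": RateSpec.stochastic(c_death),
        },
    )
    return net, setup
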