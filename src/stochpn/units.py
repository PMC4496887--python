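"""Biological unit conversion: concentrations and mass-action constants.

Stochastic simulation works with discrete molecule counts and per-event
stochastic rate constants, while biologists report molar concentrations
and deterministic mass-action constants.  Given the reaction volume V
(liters) and the Avogadro constant N_A, a concentration [X] becomes

    n_X = N_A * [X] * V        molecules,

and a mass-action constant k of a reaction of order x (units
M^-(x-1) s^-1) becomes the stochastic constant

    c = k * prod_{p in pre(t)} f(p, t)! / (V * N_A)^(x-1),

where f(p, t) is the stoichiometric arc weight.  Special cases:
c = k * V * N_A for zero order, c = k for first order, c = k/(V*N_A)
for A+B -> C, and c = 2k/(V*N_A) for 2A -> B.

N_A defaults to 6e23 (two significant figures), configurable via
:class:`ConversionContext`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .expressions import ConditionalExpression, Expression, parse, parse_conditional
from .net import PetriNet

__all__ = [
    "ConversionContext",
    "RateSpec",
    "concentration_to_molecules",
    "molecules_to_concentration",
    "reaction_order",
    "mass_action_to_stochastic",
    "stoichiometric_factor",
]

AVOGADRO_DEFAULT = 6e23


@dataclass(frozen=True)
class ConversionContext:
    """Reaction volume in liters and the Avogadro constant."""

    volume: float
    avogadro: float = AVOGADRO_DEFAULT

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"volume must be positive, got {self.volume}")
        if self.avogadro <= 0:
            raise ValueError(f"avogadro must be positive, got {self.avogadro}")


@dataclass(frozen=True)
class RateSpec:
    """Per-transition rate: a constant, an expression, or a conditional.

    kind:
      * ``mass_action`` — constant k in M^-(x-1) s^-1; converted to a
        stochastic constant given the net and volume.
      * ``stochastic`` — constant c, used as-is (also the per-transition
        firing rate of the constant-rate stochastic mode).
      * ``expression`` / ``conditional`` — text evaluated at run time
        against Time and non-constant place counts; the evaluated value
        is interpreted in mass-action units and converted per evaluation.
    """

    kind: str
    value: float | None = None
    text: str | None = None
    compiled: Expression | ConditionalExpression | None = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if self.kind not in ("mass_action", "stochastic", "expression", "conditional"):
            raise ValueError(f"unknown RateSpec kind {self.kind!r}")
        if self.kind in ("mass_action", "stochastic"):
            if self.value is None or self.value < 0:
                raise ValueError(f"{self.kind} rate needs a non-negative value")
        else:
            if not self.text:
                raise ValueError(f"{self.kind} rate needs expression text")
            compiled = (
                parse(self.text) if self.kind == "expression" else parse_conditional(self.text)
            )
            object.__setattr__(self, "compiled", compiled)

    @classmethod
    def mass_action(cls, k: float) -> "RateSpec":
        return cls("mass_action", value=k)

    @classmethod
    def stochastic(cls, c: float) -> "RateSpec":
        return cls("stochastic", value=c)

    @classmethod
    def expression(cls, text: str) -> "RateSpec":
        return cls("expression", text=text)

    @classmethod
    def conditional(cls, text: str) -> "RateSpec":
        return cls("conditional", text=text)


def concentration_to_molecules(conc: float, ctx: ConversionContext) -> int:
    """Molar concentration -> integer molecule count, n = round(N_A [X] V).

    Rounding is to nearest with ties to even.
    """
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return int(round(ctx.avogadro * conc * ctx.volume))


def molecules_to_concentration(n: float, ctx: ConversionContext) -> float:
    """Molecule count -> molar concentration, [X] = n / (N_A V)."""
    if n < 0:
        raise ValueError(f"molecule count must be non-negative, got {n}")
    return n / (ctx.avogadro * ctx.volume)


def reaction_order(net: PetriNet, t: str) -> int:
    """Order x of the reaction = sum of pre-arc weights (0 for sources)."""
    return sum(net.pre_arcs(t).values())


def stoichiometric_factor(net: PetriNet, t: str, ctx: ConversionContext) -> float:
    """The conversion factor prod f! / (V N_A)^(x-1) for transition ``t``.

    Multiplying a mass-action constant (or an evaluated mass-action
    expression value) by this factor yields the stochastic constant.
    """
    x = reaction_order(net, t)
    fact = 1.0
    for w in net.pre_arcs(t).values():
        fact *= math.factorial(w)
    return fact / (ctx.volume * ctx.avogadro) ** (x - 1)


def mass_action_to_stochastic(
    k: RateSpec | float, net: PetriNet, t: str, ctx: ConversionContext
) -> float:
    """Convert a mass-action constant to the stochastic constant c(t)."""
    if isinstance(k, RateSpec):
        if k.kind != "mass_action":
            raise ValueError(
                f"expected a mass_action RateSpec for {t!r}, got kind {k.kind!r}; "
                "expression rates are converted per evaluation"
            )
        k = k.value
    return float(k) * stoichiometric_factor(net, t, ctx)
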