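"""Exact and approximate stochastic simulation algorithm (SSA) engines.

The exact engine is Gillespie's direct method: with propensities
r(T_i) = c(T_i) * prod_{p in pre(T_i)} C(m(p), f(p, T_i)) and total
a0 = sum r, the next waiting time is dt = -ln(1-U1)/a0 and the reaction
is the unique i with  sum_{j<i} r_j < U2*a0 <= sum_{j<=i} r_j.  A
dependency graph (after Gibson & Bruck) limits propensity recomputation
to the reactions whose reactant counts a firing can change; it is a
performance device only and never alters the sampled trajectory.

The approximate engine is tau-leaping with critical reactions: a
reaction that cannot fire at least ``critical_threshold`` (default 20)
more times is *critical* and simulated exactly; the remaining reactions
fire Poisson(r*tau) times over a leap tau chosen so that no propensity
changes by more than a fraction ``epsilon`` (default 0.03) in
expectation (the bounded mean/variance step-size criterion).  A leap
that would drive a count negative is rejected, tau halved and retried;
after ``max_halvings`` rejections one exact step is taken instead.

Constant places contribute their current counts to propensities but are
never consumed; the propensities of their post-transitions, and of any
transition with an expression-valued rate constant, are refreshed every
step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .expressions import ConditionalExpression, Expression, evaluate, evaluate_conditional
from .net import PetriNet
from .state import STATUS_DEAD, STATUS_RUNNING, SimulationState, update_constant_places
from .units import ConversionContext, RateSpec, stoichiometric_factor

__all__ = [
    "LeapConfig",
    "propensity",
    "draw_waiting_time",
    "select_reaction",
    "build_dependency_graph",
    "classify_critical",
    "select_tau_noncritical",
    "SSASimulator",
    "step_exact",
    "step_tau_leap",
]


@dataclass
class LeapConfig:
    """Tau-leaping tuning knobs."""

    critical_threshold: int = 20
    epsilon: float = 0.03
    max_halvings: int = 10

    def __post_init__(self) -> None:
        if self.critical_threshold < 1:
            raise ValueError("critical_threshold must be >= 1")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")


def propensity(net: PetriNet, m: Mapping[str, int], t: str, c: float) -> float:
    """r = c * prod C(m(p), f(p,t)) over pre-places (empty product = 1)."""
    if c < 0:
        raise ValueError(f"stochastic constant for {t!r} must be >= 0, got {c}")
    r = float(c)
    for p, w in net.pre_arcs(t).items():
        r *= math.comb(max(m.get(p, 0), 0), w)
        if r == 0.0:
            return 0.0
    return r


def draw_waiting_time(a0: float, u1: float) -> float:
    """Inversion sampling of the exponential waiting time, -ln(1-U1)/a0."""
    if a0 <= 0:
        raise ValueError(f"total propensity must be positive, got {a0}")
    return -math.log1p(-u1) / a0


def select_reaction(rates: Sequence[float], u2: float) -> int:
    """Index i with sum_{j<i} r_j < u2*a0 <= sum_{j<=i} r_j (0-based)."""
    a0 = float(sum(rates))
    if a0 <= 0:
        raise ValueError("cannot select a reaction: all rates are zero")
    threshold = u2 * a0
    cum = 0.0
    for i, r in enumerate(rates):
        cum += r
        if r > 0 and cum >= threshold:
            return i
    # guard against float round-off leaving threshold marginally above cum
    return max(i for i, r in enumerate(rates) if r > 0)


def build_dependency_graph(net: PetriNet) -> dict[str, set[str]]:
    """depends[t] = transitions whose propensity may change when t fires.

    Exactly the transitions with a pre-place whose token count changes
    (constant places never change by firing).  A conservative
    over-approximation would also be sound; an under-approximation is a
    correctness bug.
    """
    depends: dict[str, set[str]] = {}
    for t in net.transitions:
        pre = net.pre_arcs(t)
        post = net.post_arcs(t)
        affected = set()
        for p in set(pre) | set(post):
            if net.is_constant(p):
                continue
            if post.get(p, 0) - pre.get(p, 0) != 0:
                affected.add(p)
        deps = set()
        for p in affected:
            deps |= net.post_transitions(p)
        depends[t] = deps
    return depends


def max_firings(net: PetriNet, m: Mapping[str, int], t: str) -> float:
    """How many consecutive times t could fire; inf for source transitions."""
    pre = net.pre_arcs(t)
    if not pre:
        return math.inf
    return min(m.get(p, 0) // w for p, w in pre.items())


def classify_critical(
    net: PetriNet, m: Mapping[str, int], t: str, cfg: LeapConfig
) -> bool:
    """True iff t lacks the reactants to fire at least the threshold times."""
    return max_firings(net, m, t) < cfg.critical_threshold


def _hor_factor(net: PetriNet, m: Mapping[str, int], p: str) -> float:
    """g_p: highest-order-reaction correction of the leap-size criterion."""
    hor = 0
    max_w = 0
    for t in net.post_transitions(p):
        x = sum(net.pre_arcs(t).values())
        w = net.pre_arcs(t)[p]
        if x > hor:
            hor, max_w = x, w
        elif x == hor and w > max_w:
            max_w = w
    x_p = m.get(p, 0)
    if hor <= 1:
        return 1.0
    if hor == 2:
        if max_w >= 2 and x_p > 1:
            return 2.0 + 1.0 / (x_p - 1)
        return 2.0
    if hor == 3:
        if max_w >= 3 and x_p > 2:
            return 3.0 + 1.0 / (x_p - 1) + 2.0 / (x_p - 2)
        if max_w >= 2 and x_p > 1:
            return 1.5 * (2.0 + 1.0 / (x_p - 1))
        return 3.0
    return float(hor)


def select_tau_noncritical(
    net: PetriNet,
    m: Mapping[str, int],
    propensities: Mapping[str, float],
    noncritical: Sequence[str],
    cfg: LeapConfig,
) -> float:
    """Leap size bounding the expected relative propensity change by epsilon.

    For every reactant species p of the non-critical reactions, with
    mu_p = sum_j v_pj r_j and sigma2_p = sum_j v_pj^2 r_j (v the net
    stoichiometric change), tau is the minimum over p of
    max(eps*x_p/g_p, 1)/|mu_p| and max(eps*x_p/g_p, 1)^2/sigma2_p.
    Infinity when nothing constrains the leap.
    """
    species = set()
    for t in noncritical:
        for p in net.pre_arcs(t):
            if not net.is_constant(p):
                species.add(p)
    tau = math.inf
    for p in species:
        mu = 0.0
        sigma2 = 0.0
        for t in noncritical:
            v = net.post_arcs(t).get(p, 0) - net.pre_arcs(t).get(p, 0)
            if v == 0:
                continue
            r = propensities.get(t, 0.0)
            mu += v * r
            sigma2 += v * v * r
        bound = max(cfg.epsilon * m.get(p, 0) / _hor_factor(net, m, p), 1.0)
        if mu != 0.0:
            tau = min(tau, bound / abs(mu))
        if sigma2 > 0.0:
            tau = min(tau, bound * bound / sigma2)
    return tau


class SSASimulator:
    """Shared machinery for the exact and tau-leaping SSA engines.

    ``rates`` maps each transition to a stochastic constant (float), or
    a :class:`RateSpec`.  Mass-action and expression-valued specs are
    converted to stochastic constants using ``conversion`` (the volume /
    Avogadro context); expression and conditional specs are re-evaluated
    after every step against ``Time`` and the non-constant place counts.
    """

    def __init__(
        self,
        net: PetriNet,
        marking: Mapping[str, int],
        rates: Mapping[str, RateSpec | float],
        rng: np.random.Generator,
        *,
        conversion: ConversionContext | None = None,
        constant_exprs: Mapping[str, Expression | ConditionalExpression] | None = None,
        leap: LeapConfig | None = None,
        use_dependency_graph: bool = True,
        clock: float = 0.0,
    ):
        self.net = net
        self.ctx = conversion
        self.constant_exprs = dict(constant_exprs or {})
        self.leap = leap or LeapConfig()
        self.use_dependency_graph = use_dependency_graph
        self.order = list(net.transitions)
        self.state = SimulationState(
            net=net, marking=dict(marking), rng=rng, clock=clock
        )

        self._static_c: dict[str, float] = {}
        self._dynamic: dict[str, RateSpec] = {}
        self._factor: dict[str, float] = {}
        for t in self.order:
            spec = rates.get(t)
            if spec is None:
                raise ValueError(f"no rate given for transition {t!r}")
            if isinstance(spec, (int, float)):
                spec = RateSpec.stochastic(float(spec))
            if spec.kind == "stochastic":
                self._static_c[t] = float(spec.value)
            elif spec.kind == "mass_action":
                self._static_c[t] = float(spec.value) * self._conv_factor(t)
            else:
                self._dynamic[t] = spec
                self._factor[t] = self._conv_factor(t)

        # transitions refreshed every step regardless of the dependency graph
        self._always = set(self._dynamic)
        for p in net.constant_places:
            self._always |= net.post_transitions(p)
        self._depends = build_dependency_graph(net)

        self._c: dict[str, float] = dict(self._static_c)
        self._refresh_dynamic_c()
        # constant-place expressions define the marking from the start
        if self.constant_exprs:
            update_constant_places(self.state, self.constant_exprs)
        self._props: dict[str, float] = {
            t: propensity(net, self.state.marking, t, self._c[t]) for t in self.order
        }

    # -- rate bookkeeping --------------------------------------------------

    def _conv_factor(self, t: str) -> float:
        if self.ctx is None:
            raise ValueError(
                f"rate of {t!r} is in mass-action units; a ConversionContext "
                "(volume) is required"
            )
        return stoichiometric_factor(self.net, t, self.ctx)

    def _refresh_dynamic_c(self) -> None:
        if not self._dynamic:
            return
        bindings = self.state.bindings()
        for t, spec in self._dynamic.items():
            if spec.kind == "conditional":
                k = evaluate_conditional(spec.compiled, bindings)
            else:
                k = evaluate(spec.compiled, bindings)
            self._c[t] = max(k, 0.0) * self._factor[t]

    def _recompute(self, transitions) -> None:
        m = self.state.marking
        for t in transitions:
            self._props[t] = propensity(self.net, m, t, self._c[t])

    def _post_step(self, fired_affects: set[str]) -> None:
        """Common post-step: expressions re-evaluated, propensities refreshed."""
        changed = set()
        if self.constant_exprs:
            changed = update_constant_places(self.state, self.constant_exprs)
        self._refresh_dynamic_c()
        if self.use_dependency_graph:
            stale = set(fired_affects) | self._always
            for p in changed:
                stale |= self.net.post_transitions(p)
            self._recompute(stale)
        else:
            self._recompute(self.order)

    @property
    def total_propensity(self) -> float:
        return sum(self._props[t] for t in self.order)

    def propensities(self) -> dict[str, float]:
        return dict(self._props)

    # -- exact direct method ----------------------------------------------

    def step_exact(self) -> bool:
        """One direct-method event; False when the marking is dead."""
        a0 = self.total_propensity
        if a0 <= 0.0:
            self.state.status = STATUS_DEAD
            return False
        st = self.state
        dt = draw_waiting_time(a0, st.rng.random())
        idx = select_reaction([self._props[t] for t in self.order], st.rng.random())
        t = self.order[idx]
        self._execute(t)
        st.clock += dt
        st.step_count += 1
        st.count_firing(t)
        st.last_fired = t
        self._post_step(self._depends[t])
        return True

    def _execute(self, t: str) -> None:
        """Apply the stoichiometry of one firing (no enablement re-check:
        positive propensity guarantees sufficient tokens)."""
        m = self.state.marking
        for p, w in self.net.pre_arcs(t).items():
            if not self.net.is_constant(p):
                m[p] = m.get(p, 0) - w
        for p, w in self.net.post_arcs(t).items():
            if not self.net.is_constant(p):
                m[p] = m.get(p, 0) + w

    # -- tau-leaping -------------------------------------------------------

    def step_tau_leap(self) -> bool:
        """One tau-leap (or exact fallback); False when the marking is dead."""
        a0 = self.total_propensity
        if a0 <= 0.0:
            self.state.status = STATUS_DEAD
            return False
        st = self.state
        cfg = self.leap
        active = [t for t in self.order if self._props[t] > 0.0]
        critical = [
            t for t in active if classify_critical(self.net, st.marking, t, cfg)
        ]
        noncritical = [t for t in active if t not in set(critical)]

        tau1 = (
            select_tau_noncritical(self.net, st.marking, self._props, noncritical, cfg)
            if noncritical
            else math.inf
        )
        a0c = sum(self._props[t] for t in critical)
        tau2 = draw_waiting_time(a0c, st.rng.random()) if a0c > 0.0 else math.inf
        if math.isinf(tau1) and math.isinf(tau2):
            # nothing constrains the leap (e.g. only source reactions whose
            # propensities no species change can alter): leap semantics
            # degenerate to single exact events
            return self.step_exact()

        if tau2 <= tau1:  # tau1 == tau2 treated as the critical branch
            leap = tau2
            crit_rates = [self._props[t] if t in set(critical) else 0.0 for t in self.order]
            fired_critical: str | None = self.order[
                select_reaction(crit_rates, st.rng.random())
            ]
        else:
            leap = tau1
            fired_critical = None

        for _attempt in range(cfg.max_halvings + 1):
            counts = {t: int(st.rng.poisson(self._props[t] * leap)) for t in noncritical}
            delta: dict[str, int] = {}

            def _add(t: str, n: int) -> None:
                for p, w in self.net.pre_arcs(t).items():
                    if not self.net.is_constant(p):
                        delta[p] = delta.get(p, 0) - w * n
                for p, w in self.net.post_arcs(t).items():
                    if not self.net.is_constant(p):
                        delta[p] = delta.get(p, 0) + w * n

            for t, n in counts.items():
                if n:
                    _add(t, n)
            if fired_critical is not None:
                _add(fired_critical, 1)
            if all(st.marking.get(p, 0) + d >= 0 for p, d in delta.items()):
                for p, d in delta.items():
                    st.marking[p] = st.marking.get(p, 0) + d
                st.clock += leap
                st.step_count += 1
                for t, n in counts.items():
                    if n:
                        st.count_firing(t, n)
                if fired_critical is not None:
                    st.count_firing(fired_critical)
                st.last_fired = fired_critical
                self._post_step(set(self.order))
                return True
            # rejected: halve the leap; a shortened leap precedes the
            # critical event, which therefore no longer occurs in it
            leap /= 2.0
            fired_critical = None
        return self.step_exact()


def step_exact(sim: SSASimulator) -> bool:
    """Functional alias for :meth:`SSASimulator.step_exact`."""
    return sim.step_exact()


def step_tau_leap(sim: SSASimulator) -> bool:
    """Functional alias for :meth:`SSASimulator.step_tau_leap`."""
    return sim.step_tau_leap()
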