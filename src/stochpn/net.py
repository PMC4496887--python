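"""Place/transition Petri nets with constant places.

A Petri net is a bipartite directed graph of *places* (chemical species,
complexes, states) and *transitions* (reactions) joined by weighted arcs.
A *marking* assigns a non-negative integer token count to every place; a
transition is *enabled* when every pre-place carries at least the arc
weight in tokens, and *firing* moves tokens accordingly.

*Constant places* extend the standard formalism: their token count is set
by a user expression (see :mod:`stochpn.expressions`) and is never changed
by firing, although it still counts toward enablement and propensities.
They model boundary conditions such as an externally regulated hormone
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PetriNet",
    "PetriNetError",
    "Marking",
    "pre_places",
    "post_places",
    "is_enabled",
    "fire",
    "validate",
]

#: A marking is a plain mapping from place name to token count.
Marking = dict


class PetriNetError(ValueError):
    """Structural error in a Petri net or an illegal firing."""


@dataclass
class PetriNet:
    """A P/T net with positive integer arc weights and constant-place flags.

    Places and transitions are case-sensitive strings and must be disjoint.
    Arcs added twice between the same pair are merged by summing weights
    (the arc set is a set, so a duplicate means a larger weight).
    Insertion order of transitions is preserved and defines the fixed
    ordering used by the stochastic samplers.
    """

    # place -> constant flag; dicts preserve insertion order
    _places: dict[str, bool] = field(default_factory=dict)
    _transitions: dict[str, None] = field(default_factory=dict)
    # (place, transition) -> weight
    _in: dict[tuple[str, str], int] = field(default_factory=dict)
    # (transition, place) -> weight
    _out: dict[tuple[str, str], int] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    def add_place(self, name: str, constant: bool = False) -> None:
        if name in self._transitions:
            raise PetriNetError(f"name {name!r} already used by a transition")
        self._places[name] = constant

    def add_transition(self, name: str) -> None:
        if name in self._places:
            raise PetriNetError(f"name {name!r} already used by a place")
        self._transitions[name] = None

    def add_arc(self, source: str, target: str, weight: int = 1) -> None:
        """Add an arc place->transition or transition->place."""
        if weight < 1 or int(weight) != weight:
            raise PetriNetError(
                f"arc {source!r}->{target!r}: weight must be a positive integer, got {weight!r}"
            )
        weight = int(weight)
        if source in self._places and target in self._transitions:
            key = (source, target)
            self._in[key] = self._in.get(key, 0) + weight
        elif source in self._transitions and target in self._places:
            key = (source, target)
            self._out[key] = self._out.get(key, 0) + weight
        else:
            raise PetriNetError(
                f"arc {source!r}->{target!r} does not join an existing place and transition"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def places(self) -> list[str]:
        return list(self._places)

    @property
    def transitions(self) -> list[str]:
        return list(self._transitions)

    def is_constant(self, place: str) -> bool:
        self._check_place(place)
        return self._places[place]

    @property
    def constant_places(self) -> list[str]:
        return [p for p, c in self._places.items() if c]

    def pre_arcs(self, t: str) -> dict[str, int]:
        """Map pre-place -> arc weight f(p, t)."""
        self._check_transition(t)
        return {p: w for (p, tt), w in self._in.items() if tt == t}

    def post_arcs(self, t: str) -> dict[str, int]:
        """Map post-place -> arc weight f(t, p)."""
        self._check_transition(t)
        return {p: w for (tt, p), w in self._out.items() if tt == t}

    def post_transitions(self, p: str) -> set[str]:
        """Transitions having ``p`` as a pre-place."""
        self._check_place(p)
        return {t for (pp, t) in self._in if pp == p}

    def arc_weight(self, source: str, target: str) -> int:
        """Weight of the arc source->target, 0 if absent."""
        return self._in.get((source, target), self._out.get((source, target), 0))

    def _check_place(self, p: str) -> None:
        if p not in self._places:
            raise PetriNetError(f"unknown place {p!r}")

    def _check_transition(self, t: str) -> None:
        if t not in self._transitions:
            raise PetriNetError(f"unknown transition {t!r}")


# -- firing semantics ------------------------------------------------------


def pre_places(net: PetriNet, t: str) -> set[str]:
    """The set of places with an arc into transition ``t``."""
    return set(net.pre_arcs(t))


def post_places(net: PetriNet, t: str) -> set[str]:
    """The set of places with an arc out of transition ``t``."""
    return set(net.post_arcs(t))


def is_enabled(net: PetriNet, m: Marking, t: str) -> bool:
    """True iff every pre-place of ``t`` holds at least the arc weight.

    The inequality is inclusive: a place holding exactly the weight
    enables the transition.  A transition with no pre-places is always
    enabled.  Constant places count like any other pre-place.
    """
    return all(m.get(p, 0) >= w for p, w in net.pre_arcs(t).items())


def fire(net: PetriNet, m: Marking, t: str) -> Marking:
    """Fire ``t``: consume from pre-places, produce on post-places.

    Returns a new marking; ``m`` is not modified.  Constant places are
    left untouched on both sides.  Firing a disabled transition is a
    contract violation and raises, never silently yields negative counts.
    """
    if not is_enabled(net, m, t):
        raise PetriNetError(f"transition {t!r} is not enabled")
    out = dict(m)
    for p, w in net.pre_arcs(t).items():
        if not net.is_constant(p):
            out[p] = out.get(p, 0) - w
    for p, w in net.post_arcs(t).items():
        if not net.is_constant(p):
            out[p] = out.get(p, 0) + w
    return out


def validate(net: PetriNet) -> list[str]:
    """Return human-readable diagnostics; empty list for a well-formed net.

    The construction API already rejects most malformed input; this checks
    the remaining invariants on nets assembled by hand or read from files.
    """
    issues: list[str] = []
    places = set(net._places)
    transitions = set(net._transitions)
    clash = places & transitions
    for name in sorted(clash):
        issues.append(f"name {name!r} is both a place and a transition")
    for (p, t), w in net._in.items():
        if p not in places:
            issues.append(f"arc {p!r}->{t!r} references unknown place {p!r}")
        if t not in transitions:
            issues.append(f"arc {p!r}->{t!r} references unknown transition {t!r}")
        if w < 1:
            issues.append(f"arc {p!r}->{t!r} has non-positive weight {w}")
    for (t, p), w in net._out.items():
        if p not in places:
            issues.append(f"arc {t!r}->{p!r} references unknown place {p!r}")
        if t not in transitions:
            issues.append(f"arc {t!r}->{p!r} references unknown transition {t!r}")
        if w < 1:
            issues.append(f"arc {t!r}->{p!r} has non-positive weight {w}")
    return issues
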