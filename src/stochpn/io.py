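"""Persistence: TSV trajectories, XML simulation setups, PNML nets.

Setup XML schema (own, minimal; all numeric attributes use ``repr``
round-trippable decimal text)::

    <simulation-setup mode="ssa" seed="42" replicates="1">
      <end steps="1000"/>                  <!-- or t-end="3600.0" -->
      <volume liters="1e-09"/>             <!-- required with concentrations -->
      <avogadro value="6e+23"/>
      <places>
        <place name="IR" count="540"/>
        <place name="IR_I" concentration="9e-13"/>
        <place name="Insulin" expression="Time &lt; 300 : 1000 ; 0"/>
      </places>
      <rates>
        <rate transition="Bind_Insulin" kind="mass_action" value="1000000.0"/>
        <rate transition="Synthesis" kind="conditional" expression="..."/>
      </rates>
      <leap critical-threshold="20" epsilon="0.03" max-halvings="10"/>
      <sync fraction="1.0"/>
      <record interval="60.0"/>
    </simulation-setup>

PNML follows the ISO/IEC 15909-2 P/T-net subset.  Constant-place flags
and their expressions are stored in a ``<toolspecific tool="stochpn">``
annotation inside the place element; arcs without an inscription default
to weight 1; any net type other than a P/T net is rejected.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .gillespie import LeapConfig
from .net import PetriNet
from .runner import SimulationSetup
from .state import Trajectory
from .units import RateSpec

__all__ = [
    "export_tsv",
    "save_setup",
    "load_setup",
    "read_pnml",
    "write_pnml",
    "SetupFormatError",
    "PnmlFormatError",
]

PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"
PTNET_TYPE = "http://www.pnml.org/version-2009/grammar/ptnet"
TOOL_NAME = "stochpn"


class SetupFormatError(ValueError):
    """Malformed or unsupported simulation-setup XML."""


class PnmlFormatError(ValueError):
    """Malformed or unsupported PNML."""


# -- trajectories ----------------------------------------------------------


def export_tsv(trajectory: Trajectory, destination) -> None:
    """Write the trajectory as a tab-separated file.

    One header row (``time``, ``fired``, then one column per place in
    net order) followed by one row per recorded point.  Decimal points
    are always ``.`` regardless of locale.
    """
    if len(trajectory) == 0:
        raise ValueError("refusing to export an empty trajectory")
    trajectory.to_frame().to_csv(destination, sep="\t", index=False)


# -- setup XML -------------------------------------------------------------


def _fmt(x) -> str:
    return repr(float(x)) if isinstance(x, float) else str(x)


def save_setup(setup: SimulationSetup, destination) -> None:
    root = ET.Element(
        "simulation-setup",
        mode=setup.mode,
        seed=str(setup.seed),
        replicates=str(setup.replicates),
    )
    end = ET.SubElement(root, "end")
    if setup.steps is not None:
        end.set("steps", str(setup.steps))
    else:
        end.set("t-end", _fmt(setup.t_end))
    if setup.volume is not None:
        ET.SubElement(root, "volume", liters=_fmt(setup.volume))
    ET.SubElement(root, "avogadro", value=_fmt(setup.avogadro))
    places = ET.SubElement(root, "places")
    for name, count in setup.initial_counts.items():
        ET.SubElement(places, "place", name=name, count=str(count))
    for name, conc in setup.initial_concentrations.items():
        ET.SubElement(places, "place", name=name, concentration=_fmt(conc))
    for name, expr in setup.constant_expressions.items():
        ET.SubElement(places, "place", name=name, expression=expr)
    rates = ET.SubElement(root, "rates")
    for t, spec in setup.rates.items():
        el = ET.SubElement(rates, "rate", transition=t, kind=spec.kind)
        if spec.value is not None:
            el.set("value", _fmt(spec.value))
        if spec.text is not None:
            el.set("expression", spec.text)
    ET.SubElement(
        root,
        "leap",
        **{
            "critical-threshold": str(setup.leap.critical_threshold),
            "epsilon": _fmt(setup.leap.epsilon),
            "max-halvings": str(setup.leap.max_halvings),
        },
    )
    ET.SubElement(root, "sync", fraction=_fmt(setup.fraction))
    if setup.record_interval is not None:
        ET.SubElement(root, "record", interval=_fmt(setup.record_interval))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(destination, encoding="unicode", xml_declaration=True)


def _require(el: ET.Element, attr: str) -> str:
    value = el.get(attr)
    if value is None:
        raise SetupFormatError(f"element <{el.tag}> is missing attribute {attr!r}")
    return value


def load_setup(source) -> SimulationSetup:
    """Parse setup XML; ``load_setup(save_setup(x)) == x`` for all fields."""
    try:
        root = ET.parse(source).getroot()
    except ET.ParseError as exc:
        raise SetupFormatError(f"not well-formed XML: {exc}") from exc
    if root.tag != "simulation-setup":
        raise SetupFormatError(f"unexpected root element <{root.tag}>")
    setup = SimulationSetup(
        mode=_require(root, "mode"),
        seed=int(root.get("seed", "0")),
        replicates=int(root.get("replicates", "1")),
    )
    for el in root:
        if el.tag == "end":
            if (el.get("steps") is None) == (el.get("t-end") is None):
                raise SetupFormatError("<end> needs exactly one of steps / t-end")
            if el.get("steps") is not None:
                setup.steps = int(el.get("steps"))
            else:
                setup.t_end = float(el.get("t-end"))
        elif el.tag == "volume":
            setup.volume = float(_require(el, "liters"))
        elif el.tag == "avogadro":
            setup.avogadro = float(_require(el, "value"))
        elif el.tag == "places":
            for pl in el:
                if pl.tag != "place":
                    raise SetupFormatError(f"unknown element <{pl.tag}> in <places>")
                name = _require(pl, "name")
                given = [a for a in ("count", "concentration", "expression") if pl.get(a)]
                if len(given) != 1:
                    raise SetupFormatError(
                        f"place {name!r} needs exactly one of count/concentration/expression"
                    )
                if given[0] == "count":
                    setup.initial_counts[name] = int(pl.get("count"))
                elif given[0] == "concentration":
                    setup.initial_concentrations[name] = float(pl.get("concentration"))
                else:
                    setup.constant_expressions[name] = pl.get("expression")
        elif el.tag == "rates":
            for rt in el:
                if rt.tag != "rate":
                    raise SetupFormatError(f"unknown element <{rt.tag}> in <rates>")
                kind = _require(rt, "kind")
                t = _require(rt, "transition")
                if kind in ("mass_action", "stochastic"):
                    setup.rates[t] = RateSpec(kind, value=float(_require(rt, "value")))
                else:
                    setup.rates[t] = RateSpec(kind, text=_require(rt, "expression"))
        elif el.tag == "leap":
            setup.leap = LeapConfig(
                critical_threshold=int(el.get("critical-threshold", "20")),
                epsilon=float(el.get("epsilon", "0.03")),
                max_halvings=int(el.get("max-halvings", "10")),
            )
        elif el.tag == "sync":
            setup.fraction = float(_require(el, "fraction"))
        elif el.tag == "record":
            setup.record_interval = float(_require(el, "interval"))
        else:
            raise SetupFormatError(f"unknown element <{el.tag}> in <simulation-setup>")
    if (setup.steps is None) and (setup.t_end is None):
        raise SetupFormatError("setup is missing the <end> element")
    if setup.initial_concentrations and setup.volume is None:
        raise SetupFormatError(
            "initial concentrations given but the <volume> element is missing"
        )
    return setup


# -- PNML ------------------------------------------------------------------


def _q(tag: str) -> str:
    return f"{{{PNML_NS}}}{tag}"


def write_pnml(
    net: PetriNet,
    marking: dict[str, int] | None = None,
    destination=None,
    constant_expressions: dict[str, str] | None = None,
) -> None:
    """Write the net (and optional initial marking) as a P/T-net PNML file."""
    marking = marking or {}
    constant_expressions = constant_expressions or {}
    ET.register_namespace("", PNML_NS)
    pnml = ET.Element(_q("pnml"))
    netel = ET.SubElement(pnml, _q("net"), id="net0", type=PTNET_TYPE)
    page = ET.SubElement(netel, _q("page"), id="page0")
    for p in net.places:
        pel = ET.SubElement(page, _q("place"), id=p)
        name = ET.SubElement(pel, _q("name"))
        ET.SubElement(name, _q("text")).text = p
        if marking.get(p, 0):
            im = ET.SubElement(pel, _q("initialMarking"))
            ET.SubElement(im, _q("text")).text = str(int(marking[p]))
        if net.is_constant(p):
            tool = ET.SubElement(pel, _q("toolspecific"), tool=TOOL_NAME, version="1")
            ET.SubElement(tool, _q("constant")).text = "true"
            if p in constant_expressions:
                ET.SubElement(tool, _q("expression")).text = constant_expressions[p]
    for t in net.transitions:
        tel = ET.SubElement(page, _q("transition"), id=t)
        name = ET.SubElement(tel, _q("name"))
        ET.SubElement(name, _q("text")).text = t
    arc_id = 0
    for t in net.transitions:
        for p, w in net.pre_arcs(t).items():
            _write_arc(page, f"a{arc_id}", p, t, w)
            arc_id += 1
        for p, w in net.post_arcs(t).items():
            _write_arc(page, f"a{arc_id}", t, p, w)
            arc_id += 1
    tree = ET.ElementTree(pnml)
    ET.indent(tree)
    tree.write(destination, encoding="unicode", xml_declaration=True)


def _write_arc(page: ET.Element, aid: str, source: str, target: str, weight: int) -> None:
    arc = ET.SubElement(page, _q("arc"), id=aid, source=source, target=target)
    if weight != 1:
        insc = ET.SubElement(arc, _q("inscription"))
        ET.SubElement(insc, _q("text")).text = str(weight)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_pnml(source) -> tuple[PetriNet, dict[str, int], dict[str, str]]:
    """Read a P/T-net PNML file.

    Returns (net, initial marking, constant-place expression texts).
    ``write_pnml`` then ``read_pnml`` is the identity on the supported
    subset.  Net types other than P/T nets raise :class:`PnmlFormatError`.
    """
    try:
        root = ET.parse(source).getroot()
    except ET.ParseError as exc:
        raise PnmlFormatError(f"not well-formed XML: {exc}") from exc
    if _local(root.tag) != "pnml":
        raise PnmlFormatError(f"unexpected root element <{_local(root.tag)}>")
    nets = [el for el in root if _local(el.tag) == "net"]
    if len(nets) != 1:
        raise PnmlFormatError(f"expected exactly one <net>, found {len(nets)}")
    netel = nets[0]
    net_type = netel.get("type", PTNET_TYPE)
    if not net_type.endswith("ptnet"):
        raise PnmlFormatError(f"unsupported net type {net_type!r}: only P/T nets")

    net = PetriNet()
    marking: dict[str, int] = {}
    expressions: dict[str, str] = {}
    arcs: list[tuple[str, str, int]] = []

    def walk(el: ET.Element) -> None:
        for child in el:
            tag = _local(child.tag)
            if tag == "page":
                walk(child)
            elif tag == "place":
                pid = child.get("id")
                constant = False
                expr = None
                tokens = 0
                for sub in child:
                    stag = _local(sub.tag)
                    if stag == "initialMarking":
                        text = sub.findtext(_q("text")) or sub.findtext("text") or "0"
                        tokens = int(text.strip())
                    elif stag == "toolspecific" and sub.get("tool") == TOOL_NAME:
                        for ann in sub:
                            atag = _local(ann.tag)
                            if atag == "constant":
                                constant = (ann.text or "").strip().lower() == "true"
                            elif atag == "expression":
                                expr = (ann.text or "").strip()
                net.add_place(pid, constant=constant)
                if tokens:
                    marking[pid] = tokens
                if expr:
                    expressions[pid] = expr
            elif tag == "transition":
                net.add_transition(child.get("id"))
            elif tag == "arc":
                source_id, target_id = child.get("source"), child.get("target")
                w = 1
                for sub in child:
                    if _local(sub.tag) == "inscription":
                        text = sub.findtext(_q("text")) or sub.findtext("text")
                        if text:
                            w = int(text.strip())
                arcs.append((source_id, target_id, w))

    walk(netel)
    for source_id, target_id, w in arcs:
        net.add_arc(source_id, target_id, w)
    marking = {p: marking.get(p, 0) for p in net.places}
    return net, marking, expressions
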