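"""Topology and geometry of the 18-segment Circle of Willis circuit.

The circle is represented as a resistive network: four inlet nodes held at
arterial pressure (two internal carotids, two vertebrals), internal junction
nodes, and six terminal-outlet nodes where lumped peripheral beds drain the
anterior, middle, and posterior territories of each hemisphere to venous
pressure.

The bundled reference parameterization carries the segment dimensions
(length, diameter, bend curvature radius) of a physiological circle together
with the correction-formula assignment per segment: long curved vessels use
the tortuosity correction, short communicating/proximal vessels (A1, P1,
ACoA, PCoA) the entrance-effect correction.

All lengths are stored in SI (metres) internally; the editing helpers accept
millimetres, the dialect in which vessel dimensions are normally quoted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import yaml

from .errors import ConfigurationError
from .formulas import (
    MMHG_PA,
    FluidProperties,
    FormulaKind,
    SegmentGeometry,
)


class NodeKind(str, Enum):
    INLET = "inlet"              # fixed arterial pressure
    INTERNAL = "internal"        # unknown pressure, flow balance enforced
    TERMINAL_OUTLET = "outlet"   # unknown pressure, terminal bed attaches here


class Territory(str, Enum):
    ANTERIOR_L = "anterior_l"
    ANTERIOR_R = "anterior_r"
    MIDDLE_L = "middle_l"
    MIDDLE_R = "middle_r"
    POSTERIOR_L = "posterior_l"
    POSTERIOR_R = "posterior_r"


@dataclass
class Node:
    """A circuit node; ``pressure`` (Pa) is set only for INLET nodes."""

    name: str
    kind: NodeKind
    pressure: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == NodeKind.INLET and self.pressure is None:
            raise ConfigurationError(f"inlet node {self.name!r} needs a fixed pressure")
        if self.kind != NodeKind.INLET and self.pressure is not None:
            raise ConfigurationError(
                f"{self.kind.value} node {self.name!r} must not fix a pressure"
            )


@dataclass
class Segment:
    """One arterial element; positive flow runs from_node -> to_node."""

    name: str
    from_node: str
    to_node: str
    geometry: SegmentGeometry
    patent: bool = True


@dataclass
class TerminalBed:
    """Lumped peripheral bed of one territory.

    ``resistance`` is in Pa*s/m^3 and ``drain_pressure`` in Pa; the bed is an
    ordinary conductance between its attach node and the fixed venous drain.
    """

    territory: Territory
    attach_node: str
    resistance: float
    drain_pressure: float

    def __post_init__(self) -> None:
        if self.resistance <= 0.0:
            raise ConfigurationError(
                f"bed resistance must be > 0, got {self.resistance}"
            )


@dataclass
class CoWNetwork:
    nodes: dict[str, Node] = field(default_factory=dict)
    segments: dict[str, Segment] = field(default_factory=dict)
    beds: dict[Territory, TerminalBed] = field(default_factory=dict)
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def copy(self) -> "CoWNetwork":
        return copy.deepcopy(self)

    def segment(self, name: str) -> Segment:
        try:
            return self.segments[name]
        except KeyError:
            raise ConfigurationError(f"unknown segment: {name!r}") from None

    def inlets(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.kind == NodeKind.INLET]

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        cy = self.fluid.carreau_yasuda
        return {
            "fluid": {
                "density_kg_m3": self.fluid.density,
                "viscosity_pa_s": self.fluid.viscosity,
                "carreau_yasuda": None
                if cy is None
                else {
                    "eta_0": cy.eta_0,
                    "eta_inf": cy.eta_inf,
                    "lam": cy.lam,
                    "a": cy.a,
                    "n": cy.n,
                },
            },
            "nodes": [
                {
                    "name": n.name,
                    "kind": n.kind.value,
                    "pressure_mmhg": None
                    if n.pressure is None
                    else n.pressure / MMHG_PA,
                }
                for n in self.nodes.values()
            ],
            "segments": [
                {
                    "name": s.name,
                    "from": s.from_node,
                    "to": s.to_node,
                    "length_mm": s.geometry.length * 1e3,
                    "diameter_mm": s.geometry.diameter * 1e3,
                    "curvature_radius_mm": s.geometry.curvature_radius * 1e3,
                    "formula": s.geometry.formula.value,
                    "patent": s.patent,
                }
                for s in self.segments.values()
            ],
            "beds": [
                {
                    "territory": b.territory.value,
                    "attach_node": b.attach_node,
                    "resistance_pa_s_m3": b.resistance,
                    "drain_pressure_mmhg": b.drain_pressure / MMHG_PA,
                }
                for b in self.beds.values()
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CoWNetwork":
        from .formulas import CarreauYasudaParams

        fl = data.get("fluid", {})
        cy = fl.get("carreau_yasuda")
        fluid = FluidProperties(
            density=fl.get("density_kg_m3", 1050.0),
            viscosity=fl.get("viscosity_pa_s", 0.0035),
            carreau_yasuda=None if cy is None else CarreauYasudaParams(**cy),
        )
        nodes = {}
        for nd in data["nodes"]:
            p = nd.get("pressure_mmhg")
            nodes[nd["name"]] = Node(
                name=nd["name"],
                kind=NodeKind(nd["kind"]),
                pressure=None if p is None else p * MMHG_PA,
            )
        segments = {}
        for sd in data["segments"]:
            segments[sd["name"]] = Segment(
                name=sd["name"],
                from_node=sd["from"],
                to_node=sd["to"],
                geometry=SegmentGeometry(
                    length=sd["length_mm"] * 1e-3,
                    diameter=sd["diameter_mm"] * 1e-3,
                    curvature_radius=sd["curvature_radius_mm"] * 1e-3,
                    formula=FormulaKind(sd["formula"]),
                ),
                patent=sd.get("patent", True),
            )
        beds = {}
        for bd in data["beds"]:
            t = Territory(bd["territory"])
            beds[t] = TerminalBed(
                territory=t,
                attach_node=bd["attach_node"],
                resistance=bd["resistance_pa_s_m3"],
                drain_pressure=bd["drain_pressure_mmhg"] * MMHG_PA,
            )
        return cls(nodes=nodes, segments=segments, beds=beds, fluid=fluid)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CoWNetwork":
        return cls.from_dict(yaml.safe_load(text))


# -- reference parameterization ----------------------------------------------

#: inlet arterial pressure of the reference configuration [mmHg]
REFERENCE_INLET_MMHG = 93.0

#: fixed-resistance outlet boundary conditions of the reference
#: configuration: terminal resistance [Pa*s/m^3] per outlet class, draining
#: to 10 mmHg venous-side pressure
REFERENCE_BED_RESISTANCE = {"P2": 4.22e9, "M1": 3.52e9, "A2": 7.04e9}
REFERENCE_DRAIN_MMHG = 10.0

# name, from, to, length mm, diameter mm, curvature radius mm, formula
_REFERENCE_SEGMENTS = [
    ("ICAL", "ICAL.in", "ICA.term.L", 250.00, 4.00, 10.00, FormulaKind.TORTUOUS),
    ("ICAR", "ICAR.in", "ICA.term.R", 250.00, 4.00, 10.00, FormulaKind.TORTUOUS),
    ("VAL", "VAL.in", "BA.origin", 130.00, 3.70, 35.00, FormulaKind.TORTUOUS),
    ("VAR", "VAR.in", "BA.origin", 130.00, 3.70, 35.00, FormulaKind.TORTUOUS),
    ("BA", "BA.origin", "BA.top", 23.00, 4.00, 25.00, FormulaKind.TORTUOUS),
    ("M1L", "ICA.term.L", "M1L.out", 30.78, 2.70, 12.50, FormulaKind.TORTUOUS),
    ("M1R", "ICA.term.R", "M1R.out", 30.78, 2.70, 12.50, FormulaKind.TORTUOUS),
    ("A1L", "ICA.term.L", "ant.L", 13.17, 2.20, 5.00, FormulaKind.ENTRANCE),
    ("A1R", "ICA.term.R", "ant.R", 13.17, 2.20, 5.00, FormulaKind.ENTRANCE),
    ("A2L", "ant.L", "A2L.out", 32.37, 2.20, 15.00, FormulaKind.TORTUOUS),
    ("A2R", "ant.R", "A2R.out", 32.37, 2.20, 15.00, FormulaKind.TORTUOUS),
    ("ACoA", "ant.L", "ant.R", 5.00, 1.20, 40.00, FormulaKind.ENTRANCE),
    ("PCoAL", "ICA.term.L", "post.L", 10.30, 0.87, 5.00, FormulaKind.ENTRANCE),
    ("PCoAR", "ICA.term.R", "post.R", 10.30, 0.87, 5.00, FormulaKind.ENTRANCE),
    ("P1L", "BA.top", "post.L", 7.23, 1.90, 5.00, FormulaKind.ENTRANCE),
    ("P1R", "BA.top", "post.R", 7.23, 1.90, 5.00, FormulaKind.ENTRANCE),
    ("P2L", "post.L", "P2L.out", 29.07, 1.90, 12.00, FormulaKind.TORTUOUS),
    ("P2R", "post.R", "P2R.out", 29.07, 1.90, 12.00, FormulaKind.TORTUOUS),
]

_REFERENCE_BEDS = [
    (Territory.MIDDLE_L, "M1L.out", "M1"),
    (Territory.MIDDLE_R, "M1R.out", "M1"),
    (Territory.ANTERIOR_L, "A2L.out", "A2"),
    (Territory.ANTERIOR_R, "A2R.out", "A2"),
    (Territory.POSTERIOR_L, "P2L.out", "P2"),
    (Territory.POSTERIOR_R, "P2R.out", "P2"),
]


def reference_network(
    fluid: FluidProperties | None = None,
    inlet_pressure_mmhg: float = REFERENCE_INLET_MMHG,
) -> CoWNetwork:
    """The bundled physiological Circle of Willis.

    18 segments, four inlets at 93 mmHg, and fixed terminal resistances per
    outlet class draining to 10 mmHg (the configuration used to compare the
    0D model against a 3D CFD solution; autoregulated runs replace the beds).
    """
    fluid = fluid or FluidProperties()
    p_in = inlet_pressure_mmhg * MMHG_PA
    nodes: dict[str, Node] = {}
    for name in ("ICAL.in", "ICAR.in", "VAL.in", "VAR.in"):
        nodes[name] = Node(name, NodeKind.INLET, p_in)
    for name in ("BA.origin", "BA.top", "ICA.term.L", "ICA.term.R",
                 "post.L", "post.R", "ant.L", "ant.R"):
        nodes[name] = Node(name, NodeKind.INTERNAL)
    for name in ("M1L.out", "M1R.out", "A2L.out", "A2R.out", "P2L.out", "P2R.out"):
        nodes[name] = Node(name, NodeKind.TERMINAL_OUTLET)

    segments: dict[str, Segment] = {}
    for name, u, v, length, diameter, a_k, formula in _REFERENCE_SEGMENTS:
        segments[name] = Segment(
            name=name,
            from_node=u,
            to_node=v,
            geometry=SegmentGeometry(
                length=length * 1e-3,
                diameter=diameter * 1e-3,
                curvature_radius=a_k * 1e-3,
                formula=formula,
            ),
        )

    beds: dict[Territory, TerminalBed] = {}
    for territory, attach, klass in _REFERENCE_BEDS:
        beds[territory] = TerminalBed(
            territory=territory,
            attach_node=attach,
            resistance=REFERENCE_BED_RESISTANCE[klass],
            drain_pressure=REFERENCE_DRAIN_MMHG * MMHG_PA,
        )
    return CoWNetwork(nodes=nodes, segments=segments, beds=beds, fluid=fluid)


# -- editing ------------------------------------------------------------------


def apply_stenosis(net: CoWNetwork, segment_name: str, severity: float) -> CoWNetwork:
    """Return an edited copy with the named segment stenosed.

    ``severity`` is the fractional diameter reduction of the whole segment
    (the lumped model has no sub-segment localization); 1.0 marks the
    segment occluded (non-patent).
    """
    if not 0.0 <= severity <= 1.0:
        raise ConfigurationError(f"severity must be in [0, 1], got {severity}")
    out = net.copy()
    seg = out.segment(segment_name)
    if severity >= 1.0:
        seg.patent = False
    elif severity > 0.0:
        g = seg.geometry
        seg.geometry = SegmentGeometry(
            length=g.length,
            diameter=g.diameter * (1.0 - severity),
            curvature_radius=g.curvature_radius,
            formula=g.formula,
        )
    return out


def occlude(net: CoWNetwork, segment_name: str) -> CoWNetwork:
    """Return a copy with the named segment marked non-patent."""
    out = net.copy()
    out.segment(segment_name).patent = False
    return out


def set_diameter(net: CoWNetwork, segment_name: str, diameter_mm: float) -> CoWNetwork:
    """Return a copy with the named segment's diameter overridden (mm)."""
    if diameter_mm <= 0.0:
        raise ConfigurationError(f"diameter must be > 0, got {diameter_mm}")
    out = net.copy()
    seg = out.segment(segment_name)
    g = seg.geometry
    seg.geometry = SegmentGeometry(
        length=g.length,
        diameter=diameter_mm * 1e-3,
        curvature_radius=g.curvature_radius,
        formula=g.formula,
    )
    return out


# -- diagnostics ---------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    code: str
    message: str


def _reachable(net: CoWNetwork, sources: Iterable[str]) -> set[str]:
    adj: dict[str, set[str]] = {n: set() for n in net.nodes}
    for seg in net.segments.values():
        if not seg.patent:
            continue
        if seg.from_node in adj and seg.to_node in adj:
            adj[seg.from_node].add(seg.to_node)
            adj[seg.to_node].add(seg.from_node)
    seen = set()
    stack = [s for s in sources if s in adj]
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(adj[n] - seen)
    return seen


def validate_topology(net: CoWNetwork) -> list[Diagnostic]:
    """Structural audit; returns an empty list for a healthy network.

    Reports missing endpoint nodes, terminal beds attached to unknown
    nodes, territories with no patent arterial path from any inlet, and
    isolated non-inlet nodes.
    """
    out: list[Diagnostic] = []
    for seg in net.segments.values():
        for endpoint in (seg.from_node, seg.to_node):
            if endpoint not in net.nodes:
                out.append(Diagnostic(
                    "missing-node",
                    f"segment {seg.name} references unknown node {endpoint!r}",
                ))
    for bed in net.beds.values():
        if bed.attach_node not in net.nodes:
            out.append(Diagnostic(
                "missing-node",
                f"bed {bed.territory.value} attaches to unknown node "
                f"{bed.attach_node!r}",
            ))
    inlet_names = [n.name for n in net.inlets()]
    if not inlet_names:
        out.append(Diagnostic("no-inlet", "network has no inlet node"))
    fed = _reachable(net, inlet_names)
    for bed in net.beds.values():
        if bed.attach_node in net.nodes and bed.attach_node not in fed:
            out.append(Diagnostic(
                "unsupplied-territory",
                f"territory {bed.territory.value} has no patent arterial "
                f"path from any inlet",
            ))
    touched = set()
    for seg in net.segments.values():
        if seg.patent:
            touched.update((seg.from_node, seg.to_node))
    for node in net.nodes.values():
        if node.kind != NodeKind.INLET and node.name not in touched:
            out.append(Diagnostic(
                "dangling-node",
                f"node {node.name!r} touches no patent segment",
            ))
    return out
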