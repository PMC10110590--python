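"""Nodal-analysis solver for the lumped Circle of Willis circuit.

The circuit is solved by the node potential method: pressures at non-fixed
nodes are the unknowns, flow balance at every such node gives a linear
system once each segment has a resistance.  Because the segment resistances
depend on their own Reynolds numbers, the nonlinear mode wraps the linear
solve in a fixed-point iteration: solve, recompute Re per segment, update
the resistances through the tortuosity/entrance corrections (with
under-relaxation to damp oscillation at high Re), and repeat until the flow
field stops changing.

The same loop optionally lets a controller adjust the terminal-bed
resistances from the attach-node pressures at each sweep; the
autoregulation layer uses this so that the bed and segment fixed points are
interleaved rather than nested.

All assembly is done in SI units (Pa, m^3/s, Pa*s/m^3); results are
converted to mmHg, ml/min and mmHg*min/ml only when the solution state is
packaged for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ConvergenceError, TopologyError
from .formulas import (
    MMHG_PA,
    ML_MIN_M3S,
    PA_S_M3_TO_MMHG_MIN_ML,
    ResistanceMode,
    hagen_poiseuille_resistance,
    reynolds_number,
    segment_resistance,
)
from .network import CoWNetwork, NodeKind, Territory

#: absolute floor (m^3/s) for the convergence-test scale; ~6e-4 ml/min,
#: orders of magnitude below clinical relevance, so all-zero flow fields
#: (equal inlet and drain pressures) register as converged instead of
#: chasing machine noise
_FLOW_FLOOR = 1e-11


@dataclass(frozen=True)
class SolverSettings:
    mode: ResistanceMode = ResistanceMode.NONLINEAR
    rel_tolerance: float = 1e-8
    max_iterations: int = 200
    relaxation: float = 0.5

    def __post_init__(self) -> None:
        if self.rel_tolerance <= 0.0:
            raise ValueError("rel_tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 < self.relaxation <= 1.0:
            raise ValueError("relaxation must be in (0, 1]")


@dataclass
class SolutionState:
    """Converged circuit state, reported in clinical units.

    ``segment_flows`` are signed, positive from_node -> to_node.
    """

    node_pressures: dict[str, float]          # mmHg
    segment_flows: dict[str, float]           # ml/min
    segment_re: dict[str, float]              # dimensionless
    segment_resistances: dict[str, float]     # mmHg*min/ml
    bed_flows: dict[Territory, float] = field(default_factory=dict)  # ml/min
    iterations: int = 0
    converged: bool = False


BedController = Callable[[Territory, float], float]


def _assemble_and_solve(
    net: CoWNetwork,
    seg_resistance: dict[str, float],
    bed_resistance: dict[Territory, float],
) -> dict[str, float]:
    """One linear nodal solve; returns pressures (Pa) for every node."""
    unknown = [n.name for n in net.nodes.values() if n.kind != NodeKind.INLET]
    idx = {name: i for i, name in enumerate(unknown)}
    m = len(unknown)
    G = np.zeros((m, m))
    b = np.zeros(m)
    anchored = set()  # unknown nodes with a conductance path to a fixed potential

    def stamp(u: str, v: str, g: float, v_fixed_pressure: float | None = None):
        iu = idx.get(u)
        if v_fixed_pressure is None:
            iv = idx.get(v)
            pv = None
        else:
            iv, pv = None, v_fixed_pressure
        if iu is not None:
            G[iu, iu] += g
            if iv is not None:
                G[iu, iv] -= g
            else:
                pu_fixed = pv if pv is not None else net.nodes[v].pressure
                b[iu] += g * pu_fixed
                anchored.add(u)
        if iv is not None:
            G[iv, iv] += g
            if iu is not None:
                G[iv, iu] -= g
            else:
                b[iv] += g * net.nodes[u].pressure
                anchored.add(v)

    edges: list[tuple[str, str]] = []
    for seg in net.segments.values():
        if not seg.patent:
            continue
        g = 1.0 / seg_resistance[seg.name]
        u, v = seg.from_node, seg.to_node
        stamp(u, v, g)
        edges.append((u, v))
    for bed in net.beds.values():
        stamp(bed.attach_node, "__drain__", 1.0 / bed_resistance[bed.territory],
              v_fixed_pressure=bed.drain_pressure)

    # propagate anchoring through internal edges: any unknown node connected
    # to an anchored one is solvable
    adj: dict[str, set[str]] = {n: set() for n in unknown}
    for u, v in edges:
        if u in idx and v in idx:
            adj[u].add(v)
            adj[v].add(u)
    stack = list(anchored)
    seen = set(anchored)
    while stack:
        n = stack.pop()
        for nb in adj.get(n, ()):  # pragma: no branch
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    isolated = [n for n in unknown if n not in seen]
    if isolated:
        raise TopologyError(
            f"singular system: nodes {isolated} have no path to a fixed "
            f"pressure", nodes=isolated,
        )

    p = np.linalg.solve(G, b)
    pressures = {name: float(p[idx[name]]) for name in unknown}
    for node in net.inlets():
        pressures[node.name] = node.pressure
    return pressures


def _segment_flows_si(
    net: CoWNetwork,
    pressures: dict[str, float],
    seg_resistance: dict[str, float],
) -> dict[str, float]:
    flows = {}
    for seg in net.segments.values():
        if not seg.patent:
            flows[seg.name] = 0.0
        else:
            dp = pressures[seg.from_node] - pressures[seg.to_node]
            flows[seg.name] = dp / seg_resistance[seg.name]
    return flows


def _bed_flows_si(
    net: CoWNetwork,
    pressures: dict[str, float],
    bed_resistance: dict[Territory, float],
) -> dict[Territory, float]:
    return {
        bed.territory: (pressures[bed.attach_node] - bed.drain_pressure)
        / bed_resistance[bed.territory]
        for bed in net.beds.values()
    }


def _package_state(
    net: CoWNetwork,
    pressures: dict[str, float],
    seg_resistance: dict[str, float],
    bed_resistance: dict[Territory, float],
    iterations: int,
    converged: bool,
) -> SolutionState:
    flows_si = _segment_flows_si(net, pressures, seg_resistance)
    beds_si = _bed_flows_si(net, pressures, bed_resistance)
    re = {
        name: reynolds_number(flows_si[name], net.segments[name].geometry, net.fluid)
        if net.segments[name].patent
        else 0.0
        for name in net.segments
    }
    return SolutionState(
        node_pressures={n: p / MMHG_PA for n, p in pressures.items()},
        segment_flows={n: q / ML_MIN_M3S for n, q in flows_si.items()},
        segment_re=re,
        segment_resistances={
            n: r * PA_S_M3_TO_MMHG_MIN_ML for n, r in seg_resistance.items()
        },
        bed_flows={t: q / ML_MIN_M3S for t, q in beds_si.items()},
        iterations=iterations,
        converged=converged,
    )


def _hp_resistances(net: CoWNetwork) -> dict[str, float]:
    return {
        seg.name: hagen_poiseuille_resistance(seg.geometry, net.fluid)
        for seg in net.segments.values()
    }


def fixed_point_solve(
    net: CoWNetwork,
    settings: SolverSettings,
    bed_controller: Optional[BedController] = None,
    initial_bed_resistances: Optional[dict[Territory, float]] = None,
    initial_resistances: Optional[dict[str, float]] = None,
) -> tuple[SolutionState, dict[Territory, float]]:
    """Shared fixed-point loop over segment (and optionally bed) resistances.

    ``bed_controller(territory, attach_pressure_pa)`` returns the target bed
    resistance (Pa*s/m^3); when absent the beds keep their configured
    resistances.  Returns the packaged state and the final bed resistances
    in SI units.
    """
    seg_r = dict(initial_resistances) if initial_resistances else _hp_resistances(net)
    if initial_bed_resistances:
        bed_r = dict(initial_bed_resistances)
    else:
        bed_r = {b.territory: b.resistance for b in net.beds.values()}
    omega = settings.relaxation
    nonlinear_segments = settings.mode == ResistanceMode.NONLINEAR

    prev: Optional[np.ndarray] = None
    residual = np.inf
    patent = [s.name for s in net.segments.values() if s.patent]
    territories = list(bed_r)

    pressures = None
    for it in range(1, settings.max_iterations + 1):
        pressures = _assemble_and_solve(net, seg_r, bed_r)
        q_seg = _segment_flows_si(net, pressures, seg_r)
        q_bed = _bed_flows_si(net, pressures, bed_r)
        vec = np.array([q_seg[n] for n in patent] + [q_bed[t] for t in territories])

        if prev is not None:
            scale = max(float(np.max(np.abs(vec))), _FLOW_FLOOR)
            residual = float(np.max(np.abs(vec - prev))) / scale
            if residual <= settings.rel_tolerance:
                state = _package_state(net, pressures, seg_r, bed_r, it, True)
                return state, bed_r
        prev = vec

        if nonlinear_segments:
            for name in patent:
                target = segment_resistance(
                    net.segments[name].geometry, q_seg[name], net.fluid,
                    ResistanceMode.NONLINEAR,
                )
                seg_r[name] = (1.0 - omega) * seg_r[name] + omega * target
        if bed_controller is not None:
            for t in territories:
                attach = net.beds[t].attach_node
                target = bed_controller(t, pressures[attach])
                bed_r[t] = (1.0 - omega) * bed_r[t] + omega * target
        elif not nonlinear_segments:
            # nothing varies: the very next iterate is exact
            omega = 1.0

    state = _package_state(
        net, pressures, seg_r, bed_r, settings.max_iterations, False
    )
    raise ConvergenceError(
        f"no convergence after {settings.max_iterations} iterations "
        f"(flow residual {residual:.3e})",
        last_state=state,
        residual=residual,
    )


def solve_linear(net: CoWNetwork) -> SolutionState:
    """Single exact nodal solve with Hagen-Poiseuille resistances."""
    seg_r = _hp_resistances(net)
    bed_r = {b.territory: b.resistance for b in net.beds.values()}
    pressures = _assemble_and_solve(net, seg_r, bed_r)
    return _package_state(net, pressures, seg_r, bed_r, 1, True)


def solve_nonlinear(
    net: CoWNetwork,
    settings: SolverSettings | None = None,
    initial_resistances: Optional[dict[str, float]] = None,
) -> SolutionState:
    """Fixed point of (resistances <- corrections(Re(Q)); Q <- nodal solve)."""
    settings = settings or SolverSettings()
    state, _ = fixed_point_solve(
        net, settings, initial_resistances=initial_resistances
    )
    return state


def solve(net: CoWNetwork, settings: SolverSettings | None = None) -> SolutionState:
    """Dispatch on ``settings.mode``."""
    settings = settings or SolverSettings()
    if settings.mode == ResistanceMode.LINEAR:
        return solve_linear(net)
    return solve_nonlinear(net, settings)


def node_balance_residuals(
    state: SolutionState,
    net: CoWNetwork,
    bed_resistances: Optional[dict[Territory, float]] = None,
) -> dict[str, float]:
    """Signed flow imbalance (ml/min) at every non-inlet node.

    Bed outflows are recomputed from the reported node pressures and the
    bed resistances (the network's own unless overridden), so the audit is
    independent of the solver's internal bookkeeping.
    """
    residual = {
        n.name: 0.0 for n in net.nodes.values() if n.kind != NodeKind.INLET
    }
    for seg in net.segments.values():
        q = state.segment_flows.get(seg.name, 0.0)
        if seg.to_node in residual:
            residual[seg.to_node] += q
        if seg.from_node in residual:
            residual[seg.from_node] -= q
    for bed in net.beds.values():
        r = (bed_resistances or {}).get(bed.territory, bed.resistance)
        r_clin = r * PA_S_M3_TO_MMHG_MIN_ML
        p_attach = state.node_pressures[bed.attach_node]
        p_drain = bed.drain_pressure / MMHG_PA
        residual[bed.attach_node] -= (p_attach - p_drain) / r_clin
    return residual
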