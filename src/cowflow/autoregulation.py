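"""Ideal autoregulation of the terminal beds and the pressure reserve.

Cerebral autoregulation keeps territory blood flow constant across a range
of perfusion pressure by dilating or constricting the arteriolar bed.  Here
each territory's bed follows the ideal characteristic

    R_bed = clip( (P_attach - P_drain) / Q_target , R_min , R_max )

so that flow equals the territory target exactly while the required
resistance stays inside the physiological bounds, and saturates at the
bounds outside them.  With the tabulated bounds this saturation coincides
(up to rounding) with the classical 50-150 mmHg autoregulation pressure
window.

The autoregulation pressure reserve (APR) of a territory is the signed pair
of margins between the pressure at the level of the major cerebral arteries
(taken at the bed's attach node, the distal end of M1/A2/P2) and the lower
and upper autoregulation limits.  Both positive means flow is preserved; a
negative lower reserve signals exit from autoregulation by hypoperfusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .errors import ConfigurationError
from .formulas import MMHG_PA, PA_S_M3_TO_MMHG_MIN_ML, ML_MIN_M3S
from .network import CoWNetwork, Territory, apply_stenosis
from .solver import (
    SolutionState,
    SolverSettings,
    fixed_point_solve,
)


class RegulationState(str, Enum):
    WITHIN = "within"            # bed delivers its target flow
    BELOW_LOWER = "below_lower"  # maximally dilated, flow below target
    ABOVE_UPPER = "above_upper"  # maximally constricted, flow above target


@dataclass(frozen=True)
class TerritoryParams:
    """Autoregulation parameters of one territory (clinical units)."""

    q_target: float  # ml/min
    r_min: float     # mmHg*min/ml
    r_max: float     # mmHg*min/ml

    def __post_init__(self) -> None:
        if self.q_target <= 0.0:
            raise ConfigurationError("q_target must be > 0")
        if not 0.0 < self.r_min < self.r_max:
            raise ConfigurationError("need 0 < r_min < r_max")


@dataclass(frozen=True)
class AutoregulationParams:
    territories: dict[Territory, TerritoryParams]
    p_lower: float = 50.0          # mmHg, lower autoregulation limit
    p_upper: float = 150.0         # mmHg, upper limit
    drain_pressure: float = 0.0    # mmHg, venous reference for the beds

    def __post_init__(self) -> None:
        if not self.p_lower < self.p_upper:
            raise ConfigurationError("need p_lower < p_upper")


#: per-side target flow [ml/min] and resistance bounds [mmHg*min/ml]
_DEFAULT_TERRITORY_TABLE = {
    "anterior": TerritoryParams(q_target=111.0, r_min=0.46, r_max=1.31),
    "middle": TerritoryParams(q_target=162.0, r_min=0.32, r_max=0.90),
    "posterior": TerritoryParams(q_target=120.0, r_min=0.44, r_max=1.20),
}

_TERRITORY_CLASS = {
    Territory.ANTERIOR_L: "anterior",
    Territory.ANTERIOR_R: "anterior",
    Territory.MIDDLE_L: "middle",
    Territory.MIDDLE_R: "middle",
    Territory.POSTERIOR_L: "posterior",
    Territory.POSTERIOR_R: "posterior",
}


def default_autoregulation_params() -> AutoregulationParams:
    """Bundled per-territory targets and resistance bounds.

    Anterior 111 ml/min in [0.46, 1.31]; middle 162 in [0.32, 0.90];
    posterior 120 in [0.44, 1.20] mmHg*min/ml — per side — with a 50 to
    150 mmHg autoregulation window.
    """
    return AutoregulationParams(
        territories={
            t: _DEFAULT_TERRITORY_TABLE[klass]
            for t, klass in _TERRITORY_CLASS.items()
        }
    )


@dataclass
class RegulatedSolution:
    base: SolutionState
    bed_resistances: dict[Territory, float]             # mmHg*min/ml
    regulation_state: dict[Territory, RegulationState]
    perfusion_pressure: dict[Territory, float]          # mmHg at attach node
    apr_lower: dict[Territory, float]                   # mmHg
    apr_upper: dict[Territory, float]                   # mmHg
    network: CoWNetwork = field(repr=False, default=None)  # beds at final values


def _prepare_regulated_network(
    net: CoWNetwork, params: AutoregulationParams
) -> CoWNetwork:
    """Copy the network with bed drains moved to the autoregulation reference."""
    work = net.copy()
    for bed in work.beds.values():
        if bed.territory not in params.territories:
            raise ConfigurationError(
                f"no autoregulation parameters for territory "
                f"{bed.territory.value}"
            )
        bed.drain_pressure = params.drain_pressure * MMHG_PA
    return work


def _required_resistance_si(
    params: AutoregulationParams, territory: Territory, attach_pressure_pa: float
) -> float:
    """Unclipped resistance that would deliver the target flow, in SI."""
    tp = params.territories[territory]
    q_si = tp.q_target * ML_MIN_M3S
    return (attach_pressure_pa - params.drain_pressure * MMHG_PA) / q_si


def regulate(
    net: CoWNetwork,
    params: AutoregulationParams | None = None,
    settings: SolverSettings | None = None,
) -> RegulatedSolution:
    """Solve the circuit with ideally autoregulated terminal beds.

    The bed-resistance control law is interleaved with the segment
    resistance updates in one shared fixed-point loop; on convergence each
    territory is classified from the unclipped required resistance at the
    converged attach pressure.
    """
    params = params or default_autoregulation_params()
    settings = settings or SolverSettings()
    work = _prepare_regulated_network(net, params)

    bounds_si = {
        t: (
            tp.r_min / PA_S_M3_TO_MMHG_MIN_ML,
            tp.r_max / PA_S_M3_TO_MMHG_MIN_ML,
        )
        for t, tp in params.territories.items()
    }

    def controller(territory: Territory, attach_pressure_pa: float) -> float:
        r_req = _required_resistance_si(params, territory, attach_pressure_pa)
        lo, hi = bounds_si[territory]
        return min(max(r_req, lo), hi)

    # start each bed mid-range: inside the bounds regardless of geometry edits
    init_beds = {t: 0.5 * (lo + hi) for t, (lo, hi) in bounds_si.items()}
    state, bed_r_si = fixed_point_solve(
        work, settings, bed_controller=controller,
        initial_bed_resistances=init_beds,
    )

    regulation_state: dict[Territory, RegulationState] = {}
    perfusion: dict[Territory, float] = {}
    for bed in work.beds.values():
        t = bed.territory
        p_attach = state.node_pressures[bed.attach_node] * MMHG_PA
        r_req = _required_resistance_si(params, t, p_attach)
        lo, hi = bounds_si[t]
        # tolerance: classification should not flip on solver-level noise
        eps = 1e-6
        if r_req < lo * (1.0 - eps):
            regulation_state[t] = RegulationState.BELOW_LOWER
        elif r_req > hi * (1.0 + eps):
            regulation_state[t] = RegulationState.ABOVE_UPPER
        else:
            regulation_state[t] = RegulationState.WITHIN
        perfusion[t] = p_attach / MMHG_PA

    # persist the converged bed resistances on the working copy for audits
    for bed in work.beds.values():
        bed.resistance = bed_r_si[bed.territory]

    sol = RegulatedSolution(
        base=state,
        bed_resistances={
            t: r * PA_S_M3_TO_MMHG_MIN_ML for t, r in bed_r_si.items()
        },
        regulation_state=regulation_state,
        perfusion_pressure=perfusion,
        apr_lower={},
        apr_upper={},
        network=work,
    )
    sol.apr_lower, sol.apr_upper = compute_apr(sol, params)
    return sol


def compute_apr(
    sol: RegulatedSolution, params: AutoregulationParams
) -> tuple[dict[Territory, float], dict[Territory, float]]:
    """Signed pressure reserves (mmHg) per territory.

    lower reserve = P_attach - p_lower; upper reserve = p_upper - P_attach.
    Both positive: flow preserved.  A negative entry marks an exit from the
    autoregulation window on that side.
    """
    lower = {}
    upper = {}
    for t, p in sol.perfusion_pressure.items():
        lower[t] = p - params.p_lower
        upper[t] = params.p_upper - p
    return lower, upper


def _coerce_territory(territory: Territory | str) -> Territory:
    if isinstance(territory, Territory):
        return territory
    try:
        return Territory(territory.lower())
    except ValueError:
        raise ConfigurationError(f"unknown territory: {territory!r}") from None


def find_autoregulation_exit(
    net: CoWNetwork,
    params: AutoregulationParams,
    stenosed_segment: str | Sequence[str],
    territory: Territory | str,
    resolution: float = 0.001,
    settings: SolverSettings | None = None,
    coarse_step: float = 0.02,
) -> Optional[float]:
    """Smallest stenosis severity at which a territory leaves regulation.

    The named segment(s) are stenosed together by the same fractional
    diameter reduction; the severity axis is scanned coarsely and the first
    bracket where ``territory`` leaves the WITHIN state is refined by
    bisection to ``resolution``.  Returns None if the territory stays
    regulated through complete occlusion (severity 1).
    """
    if resolution <= 0.0:
        raise ConfigurationError("resolution must be > 0")
    territory = _coerce_territory(territory)
    if territory not in params.territories:
        raise ConfigurationError(f"no parameters for territory {territory.value}")
    segments = (
        [stenosed_segment] if isinstance(stenosed_segment, str) else list(stenosed_segment)
    )
    for name in segments:
        net.segment(name)  # raises on unknown segment
    settings = settings or SolverSettings()

    def exited(severity: float) -> bool:
        edited = net
        for name in segments:
            edited = apply_stenosis(edited, name, severity)
        sol = regulate(edited, params, settings)
        return sol.regulation_state[territory] != RegulationState.WITHIN

    if exited(0.0):
        return 0.0
    lo = 0.0
    hi = None
    s = coarse_step
    while s < 1.0:
        if exited(s):
            hi = s
            break
        lo = s
        s += coarse_step
    if hi is None:
        if exited(1.0):
            hi = 1.0
        else:
            return None
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if exited(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
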