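"""Scenario engine: declarative occlusion/stenosis experiments.

A scenario bundles a base network, a list of edits (diameter overrides,
stenoses, occlusions), an optional stenosis sweep, the solver mode, and
whether the terminal beds are autoregulated.  Running one yields a tidy
table — one row per (sweep point x segment or territory quantity) — suited
to plotting flow and pressure-reserve traces against stenosis severity.

Scenarios round-trip through YAML/JSON-compatible dictionaries so a run can
be reproduced from its exported configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .autoregulation import (
    AutoregulationParams,
    default_autoregulation_params,
    regulate,
)
from .errors import ConfigurationError
from .formulas import PA_S_M3_TO_MMHG_MIN_ML, ResistanceMode
from .network import (
    CoWNetwork,
    Territory,
    apply_stenosis,
    occlude,
    reference_network,
    set_diameter,
    validate_topology,
)
from .solver import SolverSettings, solve

_EDIT_KINDS = ("set_diameter", "stenosis", "occlude")


@dataclass(frozen=True)
class Edit:
    kind: str          # one of set_diameter | stenosis | occlude
    segment: str
    value: float = 0.0  # mm for set_diameter, severity fraction for stenosis

    def __post_init__(self) -> None:
        if self.kind not in _EDIT_KINDS:
            raise ConfigurationError(
                f"unknown edit kind {self.kind!r}; expected one of {_EDIT_KINDS}"
            )

    def apply(self, net: CoWNetwork) -> CoWNetwork:
        if self.kind == "set_diameter":
            return set_diameter(net, self.segment, self.value)
        if self.kind == "stenosis":
            return apply_stenosis(net, self.segment, self.value)
        return occlude(net, self.segment)


@dataclass(frozen=True)
class SweepSpec:
    segments: tuple[str, ...]
    severities: tuple[float, ...]
    simultaneous: bool = True

    def __post_init__(self) -> None:
        sev = np.asarray(self.severities, dtype=float)
        if sev.size == 0:
            raise ConfigurationError("sweep needs at least one severity")
        if np.any(sev < 0.0) or np.any(sev > 1.0):
            raise ConfigurationError("sweep severities must lie in [0, 1]")
        if np.any(np.diff(sev) <= 0.0):
            raise ConfigurationError("sweep severities must be strictly increasing")


@dataclass
class Scenario:
    name: str
    edits: list[Edit] = field(default_factory=list)
    sweep: Optional[SweepSpec] = None
    mode: ResistanceMode = ResistanceMode.NONLINEAR
    regulation: bool = False

    # -- config round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mode": self.mode.value,
            "regulation": self.regulation,
            "edits": [
                {"kind": e.kind, "segment": e.segment, "value": e.value}
                for e in self.edits
            ],
            "sweep": None
            if self.sweep is None
            else {
                "segments": list(self.sweep.segments),
                "severities": [float(s) for s in self.sweep.severities],
                "simultaneous": self.sweep.simultaneous,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        if "name" not in data:
            raise ConfigurationError("scenario config needs a 'name'")
        sweep = data.get("sweep")
        return cls(
            name=data["name"],
            mode=ResistanceMode(data.get("mode", "nonlinear")),
            regulation=bool(data.get("regulation", False)),
            edits=[
                Edit(
                    kind=e["kind"],
                    segment=e["segment"],
                    value=float(e.get("value", 0.0)),
                )
                for e in data.get("edits", [])
            ],
            sweep=None
            if sweep is None
            else SweepSpec(
                segments=tuple(sweep["segments"]),
                severities=tuple(float(s) for s in sweep["severities"]),
                simultaneous=bool(sweep.get("simultaneous", True)),
            ),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_dict(yaml.safe_load(text))


def _rows_for_solution(
    net: CoWNetwork,
    scenario: Scenario,
    swept: str,
    severity: float,
    params: AutoregulationParams,
    settings: SolverSettings,
) -> list[dict]:
    rows: list[dict] = []
    if scenario.regulation:
        sol = regulate(net, params, settings)
        state = sol.base
    else:
        sol = None
        state = solve(net, settings)
    for name, seg in net.segments.items():
        dp = (
            state.node_pressures[seg.from_node] - state.node_pressures[seg.to_node]
            if seg.patent
            else float("nan")
        )
        rows.append({
            "scenario": scenario.name,
            "swept_segment": swept,
            "severity": severity,
            "entity_kind": "segment",
            "entity": name,
            "flow_ml_min": state.segment_flows[name],
            "pressure_mmhg": dp,
            "reynolds": state.segment_re[name],
            "resistance_mmhg_min_ml": state.segment_resistances[name],
            "state": "patent" if seg.patent else "occluded",
            "apr_lower_mmhg": float("nan"),
            "apr_upper_mmhg": float("nan"),
        })
    for t in Territory:
        if t not in net.beds:
            continue
        bed = net.beds[t]
        attach_p = state.node_pressures[bed.attach_node]
        rows.append({
            "scenario": scenario.name,
            "swept_segment": swept,
            "severity": severity,
            "entity_kind": "territory",
            "entity": t.value,
            "flow_ml_min": state.bed_flows[t],
            "pressure_mmhg": attach_p,
            "reynolds": float("nan"),
            "resistance_mmhg_min_ml": sol.bed_resistances[t]
            if sol is not None
            else bed.resistance * PA_S_M3_TO_MMHG_MIN_ML,
            "state": sol.regulation_state[t].value if sol is not None else "fixed",
            "apr_lower_mmhg": sol.apr_lower[t] if sol is not None else float("nan"),
            "apr_upper_mmhg": sol.apr_upper[t] if sol is not None else float("nan"),
        })
    return rows


def run_scenario(
    scenario: Scenario,
    base: CoWNetwork | None = None,
    params: AutoregulationParams | None = None,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Execute a scenario and return the tidy result table.

    Deterministic: identical inputs give an identical table (stable row and
    column order, no hidden randomness).
    """
    net = (base or reference_network()).copy()
    for edit in scenario.edits:
        net = edit.apply(net)
    diagnostics = [d for d in validate_topology(net) if d.code == "missing-node"]
    if diagnostics:
        raise ConfigurationError(
            f"scenario {scenario.name!r}: " + "; ".join(d.message for d in diagnostics)
        )
    params = params or default_autoregulation_params()
    settings = settings or SolverSettings(mode=scenario.mode)
    if settings.mode != scenario.mode:
        settings = SolverSettings(
            mode=scenario.mode,
            rel_tolerance=settings.rel_tolerance,
            max_iterations=settings.max_iterations,
            relaxation=settings.relaxation,
        )

    rows: list[dict] = []
    if scenario.sweep is None:
        rows.extend(
            _rows_for_solution(net, scenario, "", 0.0, params, settings)
        )
    elif scenario.sweep.simultaneous:
        label = "+".join(scenario.sweep.segments)
        for severity in scenario.sweep.severities:
            edited = net
            for name in scenario.sweep.segments:
                edited = apply_stenosis(edited, name, severity)
            rows.extend(
                _rows_for_solution(edited, scenario, label, severity, params, settings)
            )
    else:
        for name in scenario.sweep.segments:
            for severity in scenario.sweep.severities:
                edited = apply_stenosis(net, name, severity)
                rows.extend(
                    _rows_for_solution(edited, scenario, name, severity, params, settings)
                )
    return pd.DataFrame(rows)


# -- occlusion presets ---------------------------------------------------------

#: named occlusion configurations of the classic supply-failure experiments
OCCLUSION_PRESETS: dict[str, tuple[str, ...]] = {
    "reference": (),
    "ical-blocked": ("ICAL",),
    "ba-blocked": ("BA",),
    "ical-var-blocked": ("ICAL", "VAR"),
}


def occlusion_scenario(preset: str, mode: ResistanceMode = ResistanceMode.NONLINEAR) -> Scenario:
    """Build a no-regulation scenario for one of the named occlusion presets."""
    try:
        blocked = OCCLUSION_PRESETS[preset]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {preset!r}; expected one of {sorted(OCCLUSION_PRESETS)}"
        ) from None
    return Scenario(
        name=preset,
        edits=[Edit(kind="occlude", segment=s) for s in blocked],
        mode=mode,
        regulation=False,
    )


# -- fixture generation --------------------------------------------------------


def generate_fixture_networks(
    seed: int, count: int, perturbation: float
) -> list[CoWNetwork]:
    """Deterministic family of anatomically plausible circle variants.

    Each fixture scales every segment diameter by an independent factor
    drawn uniformly from [1-perturbation, 1+perturbation]; occasionally a
    communicating artery (ACoA or one PCoA) is removed, emulating the most
    common incomplete-circle variants.  All fixtures pass the topology
    audit.
    """
    if not 0.0 <= perturbation < 0.5:
        raise ConfigurationError("perturbation must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    fixtures = []
    for _ in range(count):
        net = reference_network()
        for seg in net.segments.values():
            factor = float(rng.uniform(1.0 - perturbation, 1.0 + perturbation))
            if factor != 1.0:
                net = set_diameter(
                    net, seg.name, net.segment(seg.name).geometry.diameter * 1e3 * factor
                )
        if perturbation > 0.0:
            dropped = rng.choice(["none", "none", "ACoA", "PCoAL", "PCoAR"])
            if dropped != "none":
                net = occlude(net, str(dropped))
        bad = [d for d in validate_topology(net) if d.code == "missing-node"]
        assert not bad
        fixtures.append(net)
    return fixtures
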