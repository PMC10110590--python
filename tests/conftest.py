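import math

import pytest
from hypothesis import HealthCheck, settings

import cowflow as cf
from cowflow.formulas import (
    MMHG_PA,
    PA_S_M3_TO_MMHG_MIN_ML,
    FluidProperties,
    FormulaKind,
    SegmentGeometry,
)
from cowflow.network import CoWNetwork, Node, NodeKind, Segment, TerminalBed
from cowflow.network import Territory

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fluid() -> FluidProperties:
    return FluidProperties()


@pytest.fixture()
def reference_net() -> CoWNetwork:
    return cf.reference_network()


@pytest.fixture(scope="session")
def ica_geometry() -> SegmentGeometry:
    return SegmentGeometry(
        length=0.250, diameter=0.004, curvature_radius=0.010,
        formula=FormulaKind.TORTUOUS,
    )


@pytest.fixture(scope="session")
def acoa_geometry() -> SegmentGeometry:
    return SegmentGeometry(
        length=0.005, diameter=0.0012, curvature_radius=0.040,
        formula=FormulaKind.ENTRANCE,
    )


def geometry_for_resistance(
    resistance_clinical: float,
    fluid: FluidProperties,
    diameter: float = 0.003,
) -> SegmentGeometry:
    """Straight-tube geometry whose Hagen-Poiseuille resistance equals the
    requested value in mmHg*min/ml (used to build toy circuits)."""
    r_si = resistance_clinical / PA_S_M3_TO_MMHG_MIN_ML
    length = r_si * math.pi * diameter**4 / (128.0 * fluid.viscosity)
    return SegmentGeometry(
        length=length, diameter=diameter, curvature_radius=1.0,
        formula=FormulaKind.ENTRANCE,
    )


def series_chain_network(
    inlet_mmhg: float,
    segment_resistance_clinical: float,
    bed_resistance_clinical: float,
    fluid: FluidProperties,
) -> CoWNetwork:
    """Inlet -> one segment -> outlet node with a terminal bed to 0 mmHg."""
    geom = geometry_for_resistance(segment_resistance_clinical, fluid)
    return CoWNetwork(
        nodes={
            "src": Node("src", NodeKind.INLET, inlet_mmhg * MMHG_PA),
            "mid": Node("mid", NodeKind.TERMINAL_OUTLET),
        },
        segments={"s1": Segment("s1", "src", "mid", geom)},
        beds={
            Territory.MIDDLE_L: TerminalBed(
                Territory.MIDDLE_L, "mid",
                bed_resistance_clinical / PA_S_M3_TO_MMHG_MIN_ML, 0.0,
            )
        },
        fluid=fluid,
    )
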