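"""Self-contained validation harness against 3D CFD reference flows.

The lumped model was benchmarked against a finite-volume (CFD) solution of
the same Circle of Willis geometry with identical boundary conditions.  The
finest-mesh CFD flows through the left middle cerebral artery (M1L) and the
published error bounds are bundled here as constants, so the harness needs
no external files or network access.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import occlude, reference_network
from .solver import solve_linear, solve_nonlinear

#: finest-mesh CFD flow through M1L [ml/min], physiological configuration
CFD_M1L_REFERENCE = 161.99
#: finest-mesh CFD flow through M1L [ml/min], left ICA occluded
CFD_M1L_ICAL_BLOCKED = 92.52

#: published relative-error bounds of the lumped model against CFD
BOUND_NONLINEAR_REFERENCE = 0.026
BOUND_NONLINEAR_ASYMMETRIC = 0.099
BOUND_LINEAR_REFERENCE = 0.144


@dataclass(frozen=True)
class ValidationRecord:
    case: str
    quantity: str
    model_value: float
    reference_value: float
    relative_error: float
    bound: float

    @property
    def passed(self) -> bool:
        return self.relative_error <= self.bound


def _record(case: str, model: float, reference: float, bound: float) -> ValidationRecord:
    return ValidationRecord(
        case=case,
        quantity="M1L flow [ml/min]",
        model_value=model,
        reference_value=reference,
        relative_error=abs(model - reference) / reference,
        bound=bound,
    )


def validate_against_cfd() -> list[ValidationRecord]:
    """Recompute the benchmark cases and compare against the CFD flows.

    Three cases: the physiological circle in nonlinear and linear mode, and
    the left-ICA-occluded circle in nonlinear mode.
    """
    net = reference_network()
    blocked = occlude(net, "ICAL")
    return [
        _record(
            "reference/nonlinear",
            solve_nonlinear(net).segment_flows["M1L"],
            CFD_M1L_REFERENCE,
            BOUND_NONLINEAR_REFERENCE,
        ),
        _record(
            "ICAL-blocked/nonlinear",
            solve_nonlinear(blocked).segment_flows["M1L"],
            CFD_M1L_ICAL_BLOCKED,
            BOUND_NONLINEAR_ASYMMETRIC,
        ),
        _record(
            "reference/linear",
            solve_linear(net).segment_flows["M1L"],
            CFD_M1L_REFERENCE,
            BOUND_LINEAR_REFERENCE,
        ),
    ]
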