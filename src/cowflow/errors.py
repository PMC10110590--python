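"""Exception hierarchy."""

from __future__ import annotations


class CowflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CowflowError, ValueError):
    """Invalid parameter, unit tag, or scenario configuration."""


class TopologyError(CowflowError):
    """Structurally unsolvable network (disconnected unknown nodes)."""

    def __init__(self, message: str, nodes: list[str] | None = None):
        super().__init__(message)
        self.nodes = nodes or []


class ConvergenceError(CowflowError):
    """Fixed-point iteration failed to converge.

    Carries the last iterate so callers can inspect where it stalled.
    """

    def __init__(self, message: str, last_state=None, residual: float | None = None):
        super().__init__(message)
        self.last_state = last_state
        self.residual = residual
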