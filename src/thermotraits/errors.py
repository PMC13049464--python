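"""Exception hierarchy.

Grouped by pipeline stage so the CLI can map failures to distinct exit
codes (config=2, ingestion=3, fit=4, simulation=5).
"""


class ThermoTraitsError(Exception):
    """Base class for all package errors."""


class ConfigError(ThermoTraitsError):
    """Invalid configuration or parameter values."""


class IngestionError(ThermoTraitsError):
    """Invalid or insufficient input data."""


class AssayTooSparseError(IngestionError):
    """Too few distinct screening temperatures for the requested fit."""


class UncoveredDateError(IngestionError):
    """A date falls outside every configured season window."""


class CoverageError(IngestionError):
    """A forcing or field series does not cover the modeled period."""


class FitError(ThermoTraitsError):
    """Thermal-trait fitting failures."""


class DegenerateFitError(FitError):
    """Stage-1 regression produced a non-positive slope."""


class FitFailureError(FitError):
    """Nonlinear optimizer failed to converge; carries the residual norm."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class NoOptimumError(FitError):
    """Derivative condition has no root in the search bracket."""


class UndefinedQ10Error(FitError):
    """Q10 undefined: t_min at or above the lower interval bound."""


class DegenerateTraitsError(FitError):
    """Trait set evaluates to zero rate at its critical temperature."""


class SimulationError(ThermoTraitsError):
    """Budget-integration and scenario errors."""


class AlignmentError(SimulationError):
    """Control and treatment forcing series do not cover the same hours."""


class DomainError(SimulationError):
    """Arithmetic input outside its valid domain (e.g. control total <= 0)."""
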