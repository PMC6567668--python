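"""Exception types shared across the package."""


class SoyCO2Error(Exception):
    """Base class for all package errors."""


class DomainError(SoyCO2Error, ValueError):
    """An input violates a mathematical precondition (e.g. T_r <= 0)."""


class FitError(SoyCO2Error, RuntimeError):
    """A model fit could not be carried out (too few points, no admissible
    partition, degenerate design)."""


class AnalysisError(SoyCO2Error, ValueError):
    """A spatial or statistical analysis is not defined for the input
    (e.g. Ripley's K on fewer than two points)."""


class PackingError(SoyCO2Error, RuntimeError):
    """Hard-core point simulation could not place the requested number of
    points at the requested inhibition distance."""


class SchemaError(SoyCO2Error, ValueError):
    """A CSV/config input is missing required columns/keys or contains
    values that cannot be parsed."""
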