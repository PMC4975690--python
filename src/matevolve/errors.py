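"""Typed error signals shared across the package."""


class MatevolveError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MatevolveError, ValueError):
    """A parameter value violates its documented invariant."""


class DegenerateSeriesError(MatevolveError, ValueError):
    """A correlation was requested on a zero-variance series.

    Raised instead of silently returning NaN, e.g. for the lag-1
    autocorrelation of ``sin(f*t)`` at ``f = 0`` or for a frozen
    maternal-phenotype series in a constant environment.
    """


class DivergenceError(MatevolveError, RuntimeError):
    """The recursion left its domain of validity.

    Phenotypic variances tend to infinity as the mean maternal-effect
    coefficient approaches +/-1, so the iterator aborts with the offending
    generation index rather than emitting NaNs.
    """

    def __init__(self, message: str, generation: int | None = None):
        super().__init__(message)
        self.generation = generation


class ExtinctionError(MatevolveError, RuntimeError):
    """Fewer than two individuals survived selection in the simulator."""

    def __init__(self, message: str, generation: int | None = None):
        super().__init__(message)
        self.generation = generation


class ConfigError(MatevolveError, ValueError):
    """A run-configuration file failed schema or invariant validation."""
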