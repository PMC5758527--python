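"""Exception hierarchy for the pearlclim analysis library."""


class PearlclimError(Exception):
    """Base class for all pearlclim errors."""


class InvalidMeasurementError(PearlclimError):
    """A shell measurement violates its physical invariants (e.g. L <= 0)."""


class InsufficientDataError(PearlclimError):
    """Too few observations for the requested statistic."""


class DegenerateDistributionError(PearlclimError):
    """Input is constant where a distribution with spread is required."""


class ModelFitError(PearlclimError):
    """A regression design is degenerate or collinear."""


class UndefinedCorrelationError(PearlclimError):
    """Correlation requested against a constant vector."""


class LocationError(PearlclimError):
    """A point falls outside the climate grid bounds."""


class MissingClimateError(PearlclimError):
    """A temperature window is not fully covered by the grid.

    Carries a human-readable reason describing which years/months are absent.
    """


class MeasureUndefinedError(PearlclimError):
    """A percentage-based accuracy measure is undefined (non-positive values)."""


class NonAsymptoticGrowthError(PearlclimError):
    """Ford-Walford slope outside (0, 1): growth series is not asymptotic."""


class AgeUndefinedError(PearlclimError):
    """Length at or above the asymptotic length: age is undefined."""


class ThresholdDerivationError(PearlclimError):
    """Population groups are not separable (viable mean >= declining mean)."""


class MaskMismatchError(PearlclimError):
    """Suitability maps being summarised do not share the same cell mask."""
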