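"""Exception hierarchy for the metboost pipeline.

Every stage raises a subclass of :class:`MetboostError` so callers can
distinguish pipeline failures from programming errors.
"""


class MetboostError(Exception):
    """Base class for all metboost errors."""


class InvalidConfigError(MetboostError):
    """A configuration object violates its invariants."""


class LayoutError(MetboostError):
    """Field dimensions cannot host the requested trial layout."""


class EstimabilityError(MetboostError):
    """The fixed-effects design is singular (aliased terms)."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(
            "singular fixed-effects design; aliased terms: " + ", ".join(self.aliased)
        )


class UndefinedMetricError(MetboostError):
    """A metric is undefined for the given inputs (e.g. zero variance)."""


class InvalidStepError(MetboostError):
    """Coordinate-binning step parameter must be positive."""


class ImputationRequiredError(MetboostError):
    """A matrix contains missing cells where a complete matrix is required."""


class KeyMismatchError(MetboostError):
    """Join keys present in one table but absent from another."""

    def __init__(self, message, offenders=()):
        self.offenders = sorted(offenders)
        if self.offenders:
            message = f"{message}: {', '.join(map(str, self.offenders))}"
        super().__init__(message)


class MissingSampleError(MetboostError):
    """Requested individuals absent from the genotype data."""


class MarkerOrderError(MetboostError):
    """Markers are not sorted by chromosome and position."""


class MonomorphicMarkerError(MetboostError):
    """A monomorphic marker would produce a zero denominator in a GRM."""


class SchemaError(MetboostError):
    """Train/validation feature schemas disagree."""


class SplitError(MetboostError):
    """A cross-validation plan cannot be built from the given records."""
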