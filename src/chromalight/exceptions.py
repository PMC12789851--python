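"""Exception hierarchy shared across the package."""


class ChromalightError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ChromalightError, ValueError):
    """A configuration or physical parameter is outside its valid range."""


class IncompatibleGridError(ChromalightError, ValueError):
    """Two objects defined on different wavelength or spatial grids were combined."""


class DegenerateSpectrumError(ChromalightError, ValueError):
    """A spectrum has zero absorption where a ratio requires a positive value."""


class InvalidOpticsError(ChromalightError, ValueError):
    """Negative absorption or otherwise unphysical optical input."""


class InvalidForcingError(ChromalightError, ValueError):
    """Forcing values outside their physical range (e.g. negative PAR)."""


class NoLightError(ChromalightError, ValueError):
    """An operation that needs non-zero irradiance received all zeros."""


class IntegrationFailureError(ChromalightError, RuntimeError):
    """The time stepper produced a NaN or negative pool."""


class MissingWindowError(ChromalightError, ValueError):
    """A decadal statistic was requested on an incomplete 120-month window."""


class DegenerateClassesError(ChromalightError, ValueError):
    """Fewer distinct values than requested classes."""


class DegenerateNormalizationError(ChromalightError, ValueError):
    """Baseline min equals max, so min-max scaling is undefined."""


class EmptyConcordanceError(ChromalightError, ValueError):
    """All cells were excluded from a sign-concordance table."""


class UndefinedCorrelationError(ChromalightError, ValueError):
    """Rank correlation of a constant input is undefined."""


class SchemaError(ChromalightError, ValueError):
    """A gridded-array file or config is missing a required dimension or key."""
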