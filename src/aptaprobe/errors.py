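"""Exception hierarchy.

Three broad classes map onto the CLI exit codes: validation problems
(bad parameters or configs, exit 2), data problems (malformed or
incompatible inputs, exit 3), and everything else (internal, exit 4).
"""


class AptaprobeError(Exception):
    """Base class for all package errors."""


class ValidationError(AptaprobeError):
    """Invalid parameter or configuration value."""


class InvalidParameterError(ValidationError):
    pass


class GenerationFailureError(AptaprobeError):
    """A synthetic generator exhausted its retry budget."""


class DataError(AptaprobeError):
    """Malformed, incompatible, or insufficient input data."""


class GridMismatchError(DataError):
    """Two curves live on different momentum-transfer grids."""


class InvalidModelError(DataError):
    """A particle model is empty or otherwise unusable."""


class InvalidUncertaintyError(DataError):
    """A sigma column is missing, zero, or negative where it is needed."""


class InsufficientDataError(DataError):
    """Too few points/objects for the requested operation."""


class NoGuinierRegionError(DataError):
    """The low-angle region has non-negative slope; Rg is undefined."""


class UndefinedScaleError(DataError):
    """The calculated curve is identically zero; no scale factor exists."""


class UndefinedFractionError(DataError):
    """Fraction requested from an empty height distribution."""


class EmptyRangeError(DataError):
    """No pixels or bins fall inside the usable momentum-transfer range."""


class RegularizationFailureError(DataError):
    """The indirect-transform system is singular; try a larger alpha."""


class ConfigurationMismatchError(DataError):
    """Input frames or curves disagree on required metadata."""


class DependencyError(DataError):
    """A pipeline stage output required by a later stage is missing."""
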