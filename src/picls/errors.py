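"""Exception hierarchy for the PICLS plate-analysis pipeline.

Every error raised by the package derives from :class:`PiclsError`, so
callers can catch one type at a pipeline boundary.
"""


class PiclsError(Exception):
    """Base class for all PICLS pipeline errors."""


class ParseError(PiclsError):
    """A plate file could not be parsed (wrong dimensions, bad block)."""


class MissingDataError(PiclsError):
    """A well assigned in the layout has no reading in the data file."""


class DuplicateKeyError(PiclsError):
    """The same (plate, well, age day) appears more than once."""


class DataValidationError(PiclsError):
    """A reading is non-finite, negative, or otherwise ill-typed."""


class AssayDesignError(PiclsError):
    """The plate lacks required control wells."""


class InvalidPlateError(PiclsError):
    """Controls are inverted: the dead (boiled) control is not brighter
    than the unstained control after OD normalization."""


class BelowRangeError(PiclsError):
    """A well OD is below the validated normalization floor."""


class DegenerateInputError(PiclsError):
    """Too few points, or no variance, for a fit to be defined."""


class UndefinedSeparationError(DegenerateInputError):
    """Z-factor arms have identical means; the window is undefined."""


class InsufficientReplicatesError(PiclsError):
    """Fewer replicate values than the statistic requires."""


class NoLinearRangeError(PiclsError):
    """No subset of the calibration series reaches the R-squared threshold."""


class NonInvertibleError(PiclsError):
    """A zero-slope calibration cannot be inverted."""


class IncomparableError(PiclsError):
    """Two calibrations cover non-overlapping OD ranges."""


class InvalidAnchorError(PiclsError):
    """The day-1 anchor point is missing or non-positive."""


class UnidentifiableError(PiclsError):
    """The survival curve carries no information about mortality
    parameters (all points at 100% or 0%)."""


class InsufficientDataError(PiclsError):
    """Not enough age days or wells for the requested summary."""
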