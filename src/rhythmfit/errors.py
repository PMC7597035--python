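"""Exception hierarchy for rhythmfit.

All package errors derive from :class:`RhythmfitError` so callers can catch
one base class; subclasses distinguish schema problems in input files from
statistical/fitting failures.
"""


class RhythmfitError(Exception):
    """Base class for all rhythmfit errors."""


class SchemaError(RhythmfitError):
    """An input table is missing required columns or has the wrong layout."""


class ParseError(RhythmfitError):
    """A cell in an input table could not be parsed as a number."""


class ValidationError(RhythmfitError):
    """Arguments violate a documented precondition."""


class FittingError(RhythmfitError):
    """A regression could not be fitted (too few points, rank deficiency...)."""


class ConvergenceError(FittingError):
    """An iterative fit failed to converge after the documented restarts."""


class InfeasibleError(RhythmfitError):
    """A design-of-experiments target cannot be reached for any sample size."""


class ResolutionError(ValidationError):
    """An evaluation grid is too coarse for the requested quantity."""
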