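"""Exception types raised across the package."""


class EnamelSeasonError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EnamelSeasonError, ValueError):
    """Non-finite or otherwise unusable numeric input."""


class ScaleMismatchError(EnamelSeasonError, ValueError):
    """A delta value is tagged with the wrong reference scale for the operation."""


class ResolutionError(EnamelSeasonError, ValueError):
    """Discretization step too coarse for the requested geometry."""


class OutOfRangeError(EnamelSeasonError, ValueError):
    """A sample position falls outside the model grid."""


class InsufficientDataError(EnamelSeasonError, ValueError):
    """Too few samples or replicates for the requested computation."""


class DegenerateDesignError(EnamelSeasonError, ValueError):
    """Regression design matrix is singular (e.g. constant predictor)."""


class SingularSystemError(EnamelSeasonError, ValueError):
    """Inverse problem is singular; a positive damping factor is required."""


class ConfigError(EnamelSeasonError, ValueError):
    """Invalid or incomplete run configuration."""


class ParseError(EnamelSeasonError, ValueError):
    """Malformed input file."""
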