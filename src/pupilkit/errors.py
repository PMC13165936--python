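"""Exception hierarchy.

Errors are grouped so the command-line layer can map them onto exit codes:
configuration problems, data/format problems and statistically insufficient
input are distinguishable without string matching.
"""


class PupilkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PupilkitError, ValueError):
    """Invalid configuration value or unknown bodypart/column name."""


class ContractError(PupilkitError, ValueError):
    """A caller violated an operation precondition (e.g. length mismatch)."""


class FormatError(PupilkitError, ValueError):
    """Malformed input file structure (headers, duplicate frames, ...)."""


class ParseError(FormatError):
    """A cell could not be parsed as a number; names the row and column."""


class InsufficientDataError(PupilkitError, ValueError):
    """Too few usable observations for the requested computation."""


class DegenerateInputError(PupilkitError, ValueError):
    """Geometric input admits no unique fit (too few/collinear points)."""


class NonEllipseError(DegenerateInputError):
    """A fitted conic is not an ellipse; the frame should be invalidated."""


class DegenerateTestError(PupilkitError, ValueError):
    """A statistical test is undefined on this input (e.g. all-zero diffs)."""


class UndefinedCorrelationError(PupilkitError, ValueError):
    """Correlation undefined because one variable has zero rank variance."""
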