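"""Exception hierarchy.

All package errors derive from :class:`NirmcError` so callers (and the CLI)
can distinguish user/data errors from genuine bugs.
"""


class NirmcError(Exception):
    """Base class for all nirmc errors."""


class FormatError(NirmcError):
    """Malformed input file (ragged rows, bad header, unparsable values)."""


class GridError(NirmcError):
    """Invalid wavelength grid (non-monotonic, out of range, too short)."""


class ConsistencyError(NirmcError):
    """Metadata that must be constant within a group is not."""


class ArgumentError(NirmcError):
    """Invalid argument to an operation (contract violation)."""


class CoverageError(NirmcError):
    """An origin present in the data is covered by neither split list."""


class LookupError_(NirmcError):
    """A target wavelength has no grid point within tolerance."""


class DegenerateSpectrumError(NirmcError):
    """A spectrum is constant/zero where a nonzero denominator is required."""


class DegenerateFitError(NirmcError):
    """A fitted parameter is too close to zero to invert (e.g. EMSC slope)."""


class RankError(NirmcError):
    """Requested more components than the data rank supports."""


class CollinearityError(NirmcError):
    """Rank-deficient regression design; carries the offending columns."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class ConvergenceError(NirmcError):
    """An iterative algorithm failed to converge."""


class LeverageError(NirmcError):
    """A leverage value is (numerically) 1: leverage correction undefined."""


class SelectionError(NirmcError):
    """Fewer admissible peaks than requested; carries the count found."""

    def __init__(self, message, n_found=0):
        super().__init__(message)
        self.n_found = int(n_found)


class InsufficientDataError(NirmcError):
    """Too few samples remain for the requested model."""


class ConfigError(NirmcError):
    """Invalid simulation or workflow configuration."""
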