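"""Exception hierarchy shared across the package."""


class SpecLAIError(Exception):
    """Base class for all package errors."""


class DesignError(SpecLAIError, ValueError):
    """Experimental design cannot be constructed as requested."""


class ParameterError(SpecLAIError, ValueError):
    """A numeric parameter is outside its valid domain."""


class GridError(SpecLAIError, ValueError):
    """Band grid is invalid or incompatible with the operation."""


class CoverageError(SpecLAIError, ValueError):
    """Fine spectrum does not cover the spectral response of a band."""


class AlignmentError(SpecLAIError, ValueError):
    """Row/column alignment between two data structures is violated."""


class SelectionError(SpecLAIError, RuntimeError):
    """A band selector could not produce a valid subset."""


class ChainingError(SelectionError):
    """The first stage of a chained selector returned too few bands."""


class SplitError(SpecLAIError, ValueError):
    """Calibration/validation split cannot be formed."""


class DegenerateTargetError(SpecLAIError, ValueError):
    """Regression target has no variance."""
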