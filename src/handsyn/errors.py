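"""Exception hierarchy for the handsyn pipeline."""


class HandsynError(Exception):
    """Base class for all handsyn errors."""


class FormatError(HandsynError):
    """Input file does not match the documented layout (missing/unparseable columns)."""


class ParameterError(HandsynError, ValueError):
    """A parameter is outside its documented range."""


class RecordingTooShortError(HandsynError):
    """Recording has too few frames for the requested operation."""


class NoMotionError(HandsynError):
    """Static-segment trimming found no motion anywhere in the recording."""


class DegenerateDoFError(HandsynError):
    """A degree of freedom has zero variance, breaking the 16-channel contract."""


class ThresholdUnreachableError(HandsynError):
    """Cumulative-variance threshold cannot be reached on the given input."""


class UnseparableMembersError(HandsynError):
    """A subject contributed two identical loading vectors; no cut can separate them."""


class DegenerateDesignError(HandsynError):
    """Representative-angle design matrix is (numerically) rank deficient."""


class ConsistencyError(HandsynError):
    """Internal contract violated (e.g. a DoF classified both independent and candidate)."""
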