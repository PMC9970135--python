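"""Exception hierarchy shared by all quatresp modules."""


class QuatRespError(Exception):
    """Base class for all quatresp errors."""


class AlignmentError(QuatRespError):
    """Two series that must share length/timestamps do not."""


class FormatError(QuatRespError):
    """A quaternion log file violates the documented CSV dialect."""


class GapError(QuatRespError):
    """A transmission gap is too long to interpolate through."""


class BoundsError(QuatRespError):
    """A requested time window lies outside the recording."""


class InsufficientDataError(QuatRespError):
    """A signal is too short for the requested operation."""


class DegenerateInputError(QuatRespError):
    """An input carries no usable variance (e.g. all-constant channels)."""


class BandError(QuatRespError):
    """A frequency band is empty, inverted or outside (0, fs/2)."""


class ConfigError(QuatRespError):
    """Invalid configuration (unknown preset, class too small, ...)."""


class EvaluationError(QuatRespError):
    """Model evaluation is impossible (e.g. unseen class in the test set)."""


class ValidationError(QuatRespError):
    """A simulation scenario carries out-of-range fields."""
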