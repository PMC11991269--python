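"""Exception hierarchy shared across sleepstream modules."""


class SleepstreamError(Exception):
    """Base class for all errors raised by sleepstream."""


class FormatError(SleepstreamError):
    """A file does not have the expected layout (e.g. a missing column)."""


class DataError(SleepstreamError):
    """Input values violate a physiological or structural invariant."""


class GapError(DataError):
    """A timestamp gap too large to impute was found in a recording."""


class AlignmentError(SleepstreamError):
    """Two time series cannot be brought onto a common time span."""


class ConfigError(SleepstreamError):
    """A configuration object or parameter grid is invalid."""


class ParameterError(SleepstreamError):
    """A sleep--wake summary parameter is undefined for the given input."""
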