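"""Exception hierarchy for the fTCD processing suite."""


class FtcdError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FtcdError):
    """A file does not conform to a supported input dialect."""


class CorruptFileError(FormatError):
    """Rows of unequal length or otherwise unreadable sample data."""


class ConfigError(FtcdError):
    """Invalid configuration value or combination of settings."""


class DegenerateSignalError(FtcdError):
    """A signal whose statistics make the requested operation undefined
    (e.g. normalization of a zero-mean channel)."""


class NoEpochsError(FtcdError):
    """No event markers / accepted epochs available for the operation."""


class NoDataError(FtcdError):
    """Zero accepted epochs where at least one is required."""


class InsufficientDataError(FtcdError):
    """Fewer observations than the statistic requires (e.g. n < 2)."""
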