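"""Exception hierarchy shared across the pipeline."""


class SsvepBfError(Exception):
    """Base class for package errors."""


class ConfigurationError(SsvepBfError):
    """Invalid parameter, filter cutoff, montage reference, or run config."""


class DataQualityError(SsvepBfError):
    """Data fails a safety rail (e.g. too many bad channels, all trials rejected)."""


class DegenerateDataError(SsvepBfError):
    """Input is degenerate for the requested statistic (zero medians, zero SD...)."""
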