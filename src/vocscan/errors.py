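"""Exception hierarchy for the vocscan pipeline."""


class VocscanError(Exception):
    """Base class for all vocscan errors."""


class FormatError(VocscanError, ValueError):
    """A file does not parse as the expected format (e.g. ragged matrix rows)."""


class ValidationError(VocscanError, ValueError):
    """A domain invariant is violated (e.g. negative intensity)."""


class MetadataError(VocscanError, KeyError):
    """A required metadata key is missing or malformed."""


class ConfigError(VocscanError, ValueError):
    """An invalid configuration value or combination."""


class ExtractionError(VocscanError, ValueError):
    """A data-point window cannot be extracted (out of matrix bounds)."""


class SamplingError(VocscanError, ValueError):
    """Not enough eligible positions to sample the requested count."""


class ScanError(VocscanError, ValueError):
    """A sample cannot be scanned (matrix shorter than the window)."""


class DataError(VocscanError, ValueError):
    """Training data violates its contract (label range, normalisation)."""


class UndefinedMetricError(VocscanError, ZeroDivisionError):
    """A metric denominator is zero."""
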