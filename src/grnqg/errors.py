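"""Exception hierarchy shared by all analysis stages.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError
(and subclasses) -> 3.
"""


class GrnqgError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GrnqgError):
    """Invalid parameter values, thresholds, or run configuration."""


class DataError(GrnqgError):
    """Input data violates a contract (dimensions, coverage, sparsity)."""


class FormatError(DataError):
    """A file does not conform to the expected on-disk format."""
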