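"""Exception hierarchy.

``DataError`` covers problems with input data (CLI exit code 1);
``ConfigError`` covers invalid configuration or usage (CLI exit code 2).
"""


class DeltagError(Exception):
    """Base class for all package errors."""


class DataError(DeltagError):
    """Invalid, inconsistent or unusable input data."""


class ValidationError(DataError):
    """A record violates a field-level invariant (bad label, negative age...)."""


class VcfParseError(DataError):
    """A VCF file could not be parsed."""


class UndefinedLdError(DataError):
    """LD is undefined: a constant genotype vector or too few complete pairs."""


class ConfigError(DeltagError):
    """Invalid configuration (e.g. a tag-SNP spec violating Lewontin bounds)."""
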