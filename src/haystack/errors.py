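"""Exception hierarchy shared across the package."""


class HaystackError(Exception):
    """Base class for all package-specific errors."""


class DataError(HaystackError):
    """Invalid or missing input data (maps to CLI exit code 1)."""


class ConfigurationError(HaystackError):
    """Invalid configuration, e.g. an expression table without a testis column."""


class UndefinedAlleleFraction(DataError):
    """Variant allele fraction requested for a call with zero read depth."""
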