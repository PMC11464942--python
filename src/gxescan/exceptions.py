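"""Exception hierarchy for gxescan."""


class GxescanError(Exception):
    """Base class for all package errors."""


class ConfigError(GxescanError):
    """Invalid simulation or pipeline configuration."""


class FormatError(GxescanError):
    """Malformed genotype file (bad magic bytes, truncated payload, ...)."""


class SchemaError(GxescanError):
    """Tabular input violates the expected schema."""


class QCError(GxescanError):
    """Quality control cannot proceed (e.g. everything filtered)."""


class ModelError(GxescanError):
    """A statistical model cannot be estimated on the given data."""
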