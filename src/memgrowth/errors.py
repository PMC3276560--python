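"""Exception hierarchy shared across memgrowth modules."""


class MemgrowthError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MemgrowthError):
    """A file dialect, column mapping, or run configuration is unusable."""


class ValidationError(MemgrowthError):
    """Input data violates a structural invariant (duplicates, range, consistency)."""


class ParseError(MemgrowthError):
    """A file could not be parsed; the message carries coordinates where possible."""


class EstimationError(MemgrowthError):
    """A model fit could not be carried out (rank deficiency, degenerate design)."""
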