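"""Exception hierarchy shared across the package."""


class PgatypeError(Exception):
    """Base class for all package errors."""


class ParseError(PgatypeError):
    """A file could not be parsed (message names the offending element)."""


class ValidationError(PgatypeError):
    """An object violates one of its invariants."""


class ConfigError(PgatypeError):
    """A rule-table or run configuration is malformed."""
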