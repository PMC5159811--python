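"""Exception hierarchy used across the package."""


class PancoexprError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PancoexprError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class DesignError(PancoexprError, ValueError):
    """Experimental design unsuitable for the requested operation
    (e.g. a replicate group with fewer than two samples)."""


class ParseError(PancoexprError, ValueError):
    """Malformed input file; the message carries the file path and, where
    possible, the offending line or identifier."""
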