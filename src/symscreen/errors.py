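"""Exception hierarchy shared across the package."""


class SymscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SymscreenError):
    """Malformed input file; parsers reject rather than repair."""


class InputError(SymscreenError):
    """Structurally valid input that violates an operation's preconditions."""


class ConfigurationError(SymscreenError):
    """Inconsistent run configuration (e.g. taxon missing from the genus map)."""


class BacktranslationError(SymscreenError):
    """Protein/CDS mismatch discovered while building a codon alignment."""


class NumericError(SymscreenError):
    """Non-finite quantity encountered in a likelihood computation."""
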