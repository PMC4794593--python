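"""Exception hierarchy shared across the package."""


class GlycoburdenError(Exception):
    """Base class for all package errors."""


class ConfigError(GlycoburdenError):
    """Invalid simulation or pipeline configuration."""


class FormatError(GlycoburdenError):
    """Malformed input file (MAF, expression/methylation/clinical TSV)."""


class StatError(GlycoburdenError):
    """A statistic's preconditions are violated (degenerate or undefined input)."""


class DataError(GlycoburdenError):
    """Inputs violate a domain invariant (missing genes, empty groups, ...)."""
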