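"""Exception types shared across the package."""


class OmicsBnError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(OmicsBnError):
    """Sample sets of the omics matrices cannot be aligned."""


class ParseError(OmicsBnError):
    """A file could not be parsed (non-numeric cell, malformed record)."""


class ConfigurationError(OmicsBnError):
    """Inconsistent or incomplete configuration of a run."""


class InsufficientDataError(OmicsBnError):
    """Too few samples for the requested computation."""


class DegenerateDataError(OmicsBnError):
    """Numerically degenerate input (singular posterior matrix)."""


class ContractError(OmicsBnError):
    """An internal contract between pipeline stages was violated."""


class SamplerStuckError(OmicsBnError):
    """The structure sampler has no legal move available."""
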