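"""Exception hierarchy shared across the package."""


class ConcordError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(ConcordError, ValueError):
    """Raised when a Newick string cannot be parsed."""


class ValidationError(ConcordError, ValueError):
    """Raised when inputs violate a documented contract (labels, shapes, ranges)."""


class PolytomyError(ValidationError):
    """Raised when an operation requires a fully bifurcating tree but finds a polytomy."""
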