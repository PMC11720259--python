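"""Exception types shared across the package."""


class RohscanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RohscanError, ValueError):
    """Malformed input file (message names the offending line or SNP)."""


class ValidationError(RohscanError, ValueError):
    """An in-memory object violates one of its invariants."""


class EmptyAfterQCError(RohscanError, ValueError):
    """Quality control removed every SNP or every individual."""


class StageError(RohscanError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
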