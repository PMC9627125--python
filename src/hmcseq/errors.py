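"""Exception types shared across the package."""


class HmcseqError(Exception):
    """Base class for all package errors."""


class FormatError(HmcseqError):
    """A file or table does not conform to the expected format."""


class ValidationError(HmcseqError):
    """Input is well-formed but violates a contract (coordinates, ranges, shapes)."""


class ConvergenceError(HmcseqError):
    """An iterative fit failed to converge; carries diagnostics in the message."""
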