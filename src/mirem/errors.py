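"""Exception hierarchy shared across the package."""


class MiremError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MiremError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(MiremError, ValueError):
    """Inputs violated a documented precondition or invariant."""


class NoGenesMappedError(MiremError):
    """None of the input gene identifiers could be recognized."""
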