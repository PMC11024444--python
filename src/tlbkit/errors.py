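"""Exception hierarchy used across tlbkit."""


class TLBError(Exception):
    """Base class for all tlbkit errors."""


class ScanParseError(TLBError):
    """A raw scan file could not be parsed; the message names the line."""


class ValidationError(TLBError, ValueError):
    """Input data violates a structural invariant (e.g. non-monotone grid)."""


class CoverageError(TLBError, ValueError):
    """A scan does not cover the temperature range an operation requires."""


class DomainError(TLBError, ValueError):
    """An argument is outside the operation's domain (empty window, k > n ...)."""


class PairingError(TLBError, ValueError):
    """Paired samples could not be matched by patient id."""


class ConfigurationError(TLBError, ValueError):
    """A configuration refers to something that does not exist."""
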