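"""Exception types raised by crossbeta."""


class CrossBetaError(Exception):
    """Base class for all package errors."""


class ParseError(CrossBetaError, ValueError):
    """A coordinate file could not be parsed; the message names the line."""


class StructureError(CrossBetaError, ValueError):
    """A structure violates a contract (missing atoms, inconsistent chains)."""


class GenerationError(CrossBetaError, RuntimeError):
    """The synthetic builder could not realise a requested geometry."""


class ConfigError(CrossBetaError, ValueError):
    """An analysis configuration violates its invariants."""
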