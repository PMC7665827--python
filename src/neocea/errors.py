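"""Exception hierarchy shared across the analysis stages."""


class NeoceaError(Exception):
    """Base class for all package errors."""


class DomainError(NeoceaError, ValueError):
    """An input violates a mathematical precondition (negative counts,
    rates outside [0, 1], ...)."""


class ConfigurationError(NeoceaError, ValueError):
    """The analysis configuration is inconsistent or incomplete
    (missing baseline year, unknown adjustment class, ...)."""


class UndefinedIcerError(NeoceaError, ArithmeticError):
    """The incremental effect is not positive, so the ICER has no
    interpretable value on the cost-effectiveness ratio scale."""
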