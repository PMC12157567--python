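"""Error classes raised across the package."""


class TypinferError(Exception):
    """Base class for all package errors."""


class InputDomainError(TypinferError, ValueError):
    """An argument lies outside the mathematical domain of the operation."""


class UnsupportedRequestError(TypinferError, ValueError):
    """The requested quantity is not defined for the given configuration."""


class ResourceGuardError(TypinferError, RuntimeError):
    """The requested exact computation would exceed the enumeration guard."""
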