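"""Exception hierarchy shared across modules."""


class PhenoswitchError(Exception):
    """Base class for all package errors."""


class DomainError(PhenoswitchError, ValueError):
    """An argument lies outside its mathematical domain."""


class NumericalError(PhenoswitchError, ArithmeticError):
    """A numerical procedure failed (non-convergence, inconsistent round-off)."""


class IdentifiabilityError(PhenoswitchError, ValueError):
    """The requested quantity is structurally non-identifiable from the inputs."""
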