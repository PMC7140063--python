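"""Exception hierarchy.

Exit-code mapping used by the CLI: ``InputError`` -> 1 (malformed or
insufficient input), ``ComputationUndefinedError`` -> 2 (the requested
quantity does not exist for these inputs, e.g. inverting a zero-slope
dose-response line).
"""


class FishdoseError(Exception):
    """Base class for all package errors."""


class InputError(FishdoseError, ValueError):
    """Malformed, inconsistent or insufficient input data."""


class DomainError(FishdoseError, ValueError):
    """A numeric argument outside its mathematical domain (e.g. dose <= 0)."""


class ComputationUndefinedError(FishdoseError, ArithmeticError):
    """The requested quantity is undefined for these inputs."""
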