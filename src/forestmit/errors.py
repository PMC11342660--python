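"""Exception hierarchy."""


class ForestMitError(Exception):
    """Base class for package errors."""


class ConfigurationError(ForestMitError, ValueError):
    """Invalid factor levels, labels, or parameter values."""


class InputError(ForestMitError, ValueError):
    """Input series or tables do not cover what an operation requires."""


class NumericalError(ForestMitError, ArithmeticError):
    """A numerical solve failed to converge."""
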