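"""Exception hierarchy shared across the package."""


class RagnmfError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RagnmfError, ValueError):
    """A file violates the format contract (bad cell, missing column, short line)."""


class ConfigurationError(RagnmfError, ValueError):
    """An invalid parameter combination was supplied."""


class NumericalError(RagnmfError, ArithmeticError):
    """The solver produced non-finite values.

    Carries the outer iteration at which divergence was detected.
    """

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
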