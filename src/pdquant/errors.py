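"""Exception hierarchy shared across pdquant modules."""


class PdquantError(Exception):
    """Base class for all pdquant errors."""


class InvalidArgumentError(PdquantError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedRatioError(PdquantError, ZeroDivisionError):
    """A ratio statistic has a zero denominator."""


class LowCountError(PdquantError, ValueError):
    """Too few photons/observations for the requested fit."""


class FitFailureError(PdquantError, RuntimeError):
    """Optimizer failed to converge from every starting point."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NormalizationError(PdquantError, ValueError):
    """FRAP normalization is undefined (reference/background degenerate)."""


class MissingBaselineError(PdquantError, ValueError):
    """A genotype lacks the mock rows needed as a normalization baseline."""


class InsufficientDataError(PdquantError, ValueError):
    """A statistical routine received fewer observations than it requires."""
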