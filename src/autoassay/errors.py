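"""Exception hierarchy shared across the package."""


class AutoAssayError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(AutoAssayError, ValueError):
    """An argument violates a precondition (e.g. n < 1, k < 0)."""


class OutOfRangeError(AutoAssayError, ValueError):
    """A value lies outside its axis bounds or calibrated range."""


class InsufficientDataError(AutoAssayError, ValueError):
    """Too few observations to fit or calibrate."""


class SingularDesignError(AutoAssayError, ValueError):
    """Degenerate design: all training points identical."""


class InfeasibleMixtureError(AutoAssayError, ValueError):
    """Requested component volumes exceed the well end volume or a stock limit."""


class PrecisionError(AutoAssayError, ValueError):
    """A nonzero component volume falls below the minimum pipettable volume."""


class WindowTooStrictError(AutoAssayError, ValueError):
    """Fewer than two trace points survive the slope-extraction window."""


class FitFailureError(AutoAssayError, RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class UnsupportedModelError(AutoAssayError, ValueError):
    """A closed form was requested outside its validity (e.g. alpha, beta != 0)."""


class InvalidConditionError(AutoAssayError, ValueError):
    """A condition lacks axes required by the virtual instrument."""


class CampaignAborted(AutoAssayError, RuntimeError):
    """The evaluator failed mid-campaign; the partial log is preserved on .state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state
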