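"""Exception hierarchy shared across the package."""


class FormudoeError(Exception):
    """Base class for all package-specific errors."""


class SingularDesignError(FormudoeError):
    """The model matrix is rank deficient; the quadratic fit is not identified."""


class DegenerateResponseError(FormudoeError):
    """The response is constant (zero total sum of squares); R^2 is undefined."""


class LeverageError(FormudoeError):
    """A leave-one-out leverage is (numerically) 1; PRESS is undefined."""


class FitFailureError(FormudoeError):
    """A nonlinear kinetic fit failed to converge.

    The best attempt found so far, if any, is attached as ``best_attempt``.
    """

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class AlignmentError(FormudoeError):
    """Two series that must share a timepoint grid do not."""
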