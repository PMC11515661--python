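"""Exception hierarchy for stochexpr."""


class StochExprError(Exception):
    """Base class for all stochexpr errors."""


class ParameterError(StochExprError, ValueError):
    """A supplied rate, order, or grid is out of its admissible range."""


class StructuralError(StochExprError):
    """The model topology admits no stationary distribution.

    Raised when some mRNA state with nonzero occupancy has no path to
    degradation, i.e. the decay-plus-transition matrix is singular.
    """


class ConvergenceError(StochExprError):
    """A truncated power series was evaluated outside its converged range."""

    def __init__(self, message: str, last_term: float | None = None):
        super().__init__(message)
        self.last_term = last_term


class PrecisionError(StochExprError):
    """An alternating sum could not be resolved at the working precision."""
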