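"""Exception hierarchy shared by all analysis stages."""


class SwimkitError(Exception):
    """Base class for all swimkit errors."""


class InvalidParameterError(SwimkitError, ValueError):
    """A parameter is outside its physically or statistically valid domain."""


class InsufficientDataError(SwimkitError, ValueError):
    """Too few observations to carry out the requested computation."""


class DegenerateInputError(SwimkitError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. zero variance)."""


class FitFailureError(SwimkitError, RuntimeError):
    """A numerical fit did not converge; diagnostics are attached to the message."""


class SaturationError(SwimkitError, ValueError):
    """Sequence divergence too large for the distance correction (log of a non-positive number)."""


class InestimableTermError(SwimkitError, ValueError):
    """A requested ANOVA term is not estimable under the observed cell structure."""
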