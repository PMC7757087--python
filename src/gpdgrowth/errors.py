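"""Exception types shared across the package."""


class GPDGrowthError(Exception):
    """Base class for all package errors."""


class ParameterError(GPDGrowthError, ValueError):
    """A model parameter violates its admissible region."""


class DomainError(GPDGrowthError, ValueError):
    """A time or size argument lies outside the curve's domain."""


class FeatureUndefinedError(GPDGrowthError, ValueError):
    """A requested analytic feature does not exist for these parameters
    (e.g. no inflection point when A*b <= a+1)."""


class NumericError(GPDGrowthError, ArithmeticError):
    """Quadrature or root finding failed to converge."""


class FitError(GPDGrowthError, RuntimeError):
    """No multi-start optimisation run converged."""
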