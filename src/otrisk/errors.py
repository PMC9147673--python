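"""Exception and warning types shared across the package."""


class OtriskError(Exception):
    """Base class for all package errors."""


class ValidationError(OtriskError, ValueError):
    """A domain object violates one of its invariants."""


class FormatError(OtriskError, ValueError):
    """An input file does not match the expected schema."""


class DomainError(OtriskError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class NumericalError(OtriskError, RuntimeError):
    """A numerical routine (ODE solver, sampler) failed.

    Carries the last good state where available.
    """

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class ConvergenceWarning(UserWarning):
    """An MCMC diagnostic indicates possible non-convergence."""


class ReproductionError(OtriskError, RuntimeError):
    """An exactly-reproducible report cell did not match its reference value."""
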