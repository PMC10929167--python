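"""Exception hierarchy shared across the toolkit."""


class MRScreenError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(MRScreenError):
    """Input violates a documented invariant (bad allele, se <= 0, ...)."""


class ConfigurationError(MRScreenError):
    """A column mapping or configuration file is unusable."""


class EmptySetError(MRScreenError):
    """No instruments survive a matching/harmonization step."""


class InsufficientInstrumentsError(MRScreenError):
    """An estimator's minimum instrument count is not met."""


class DegenerateInstrumentError(MRScreenError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class ConvergenceError(MRScreenError):
    """An iterative optimizer exhausted its iteration budget."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class CollinearityError(MRScreenError):
    """The multivariable design matrix is rank deficient."""

    def __init__(self, message: str, exposures=None):
        super().__init__(message)
        self.exposures = list(exposures) if exposures is not None else []
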