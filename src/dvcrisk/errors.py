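"""Exception hierarchy shared across the package."""


class DVCRiskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DVCRiskError):
    """Invalid configuration (grid dimensions, unknown covariates, bad parameters)."""


class ValidationError(DVCRiskError):
    """Invalid data passed to a fitting or transformation routine."""


class SingularityError(DVCRiskError):
    """A model coefficient is inestimable (e.g. an empty stratum)."""


class DegenerateInputError(DVCRiskError):
    """Too little variation in the input to build the requested basis."""


class DivergenceError(DVCRiskError):
    """Numerical divergence during iterative fitting."""
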