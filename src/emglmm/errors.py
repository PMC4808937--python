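"""Exception hierarchy."""


class EmglmmError(Exception):
    """Base class for all package errors."""


class SchemaError(EmglmmError):
    """A CSV/column-mapping problem: missing or duplicated required columns."""


class SpecError(EmglmmError):
    """A design specification names a covariate or group that cannot be resolved."""


class ParameterError(EmglmmError):
    """Covariance parameters outside their valid domain (|rho| >= 1, sigma2 <= 0, D not PSD)."""


class SingularDesignError(EmglmmError):
    """The stacked design is rank deficient; carries the suspect column labels."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class NestingError(EmglmmError):
    """Two fits passed to a likelihood-ratio test are not nested (or not comparable)."""
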