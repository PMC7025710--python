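"""Exception hierarchy shared across the package."""


class GadaDiscrimError(ValueError):
    """Base class for all package-specific errors."""


class DomainError(GadaDiscrimError):
    """Input violates a statistical or physiological precondition."""


class SchemaError(GadaDiscrimError):
    """A required CSV column is missing or the header is malformed."""


class EncodingError(GadaDiscrimError):
    """A record lacks a field needed for indicator encoding."""


class ConfigError(GadaDiscrimError):
    """A simulation or pipeline configuration is invalid."""


class SingularCovarianceError(GadaDiscrimError):
    """Pooled within-group covariance is not invertible.

    Carries the names of the offending (collinear or constant) columns in
    ``columns`` when they can be identified.
    """

    def __init__(self, message: str, columns: tuple = ()):
        super().__init__(message)
        self.columns = tuple(columns)
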