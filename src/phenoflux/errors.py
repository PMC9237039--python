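"""Typed errors shared across the pipeline stages."""


class PhenofluxError(Exception):
    """Base class for all package errors."""


class ConfigError(PhenofluxError):
    """Invalid configuration or generator parameters."""


class EmptyInputError(PhenofluxError):
    """An operation received no usable data."""


class NoSeasonalityError(PhenofluxError):
    """A seasonal curve is too flat to define phenological transitions."""


class GapError(PhenofluxError):
    """A daily series contains a gap too long to smooth across."""


class CollinearityError(PhenofluxError):
    """A design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class GraphError(PhenofluxError):
    """A causal graph specification is invalid (cyclic, wrong edge set)."""


class OutOfDomainError(PhenofluxError):
    """A query point lies outside the interpolation hull."""
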