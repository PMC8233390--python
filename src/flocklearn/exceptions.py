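"""Exception hierarchy shared across the pipeline stages."""


class FlocklearnError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(FlocklearnError):
    """A configuration value violates its declared invariant."""


class InvalidArgumentError(FlocklearnError):
    """An operation was called with an out-of-contract argument."""


class UnknownBirdError(FlocklearnError):
    """A bird id appears in the data but not in the roster/network."""


class SchemaError(FlocklearnError):
    """An input table is missing columns or contains malformed rows."""


class StalledDiffusionError(FlocklearnError):
    """All acquisition rates are zero while naive individuals remain."""


class TieError(FlocklearnError):
    """Two first-visit times coincide exactly; resolution must be explicit."""


class SpecificationError(FlocklearnError):
    """A model specification references coefficients or columns that do not exist."""


class ComparisonError(FlocklearnError):
    """Model fits being compared were not computed on identical response rows."""


class ReliabilityError(FlocklearnError):
    """Too many simulation replicates failed to converge for a trustworthy result."""


class FitError(FlocklearnError):
    """Numerical optimisation failed at every start."""
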