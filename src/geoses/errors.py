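"""Exception hierarchy.

Every failure mode in the pipeline raises a named subclass of
:class:`GeoSESError` so callers (and the CLI) can distinguish bad
configuration from bad data from degenerate numerics.
"""


class GeoSESError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GeoSESError):
    """Invalid configuration (simulation or pipeline parameters)."""


class SchemaError(GeoSESError):
    """A table's columns do not match the declared metadata."""


class DataError(GeoSESError):
    """Values violate a data contract (counts > totals, negatives, ...)."""


class RegistryError(GeoSESError):
    """A variable is missing from, or duplicated in, the dimension registry."""


class DegenerateInputError(GeoSESError):
    """Input admits no meaningful answer (constant column, all-equal scores)."""


class PipelineError(GeoSESError):
    """A pipeline stage cannot proceed (e.g. pruning leaves < 2 variables)."""


class WeightsError(GeoSESError):
    """Invalid spatial weights (asymmetry, islands, self-neighbors)."""
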