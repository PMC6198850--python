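"""Exception hierarchy."""


class AirForestError(Exception):
    """Base class for all package errors."""


class DataError(AirForestError):
    """Invalid or unsupported input data (missing values, too few rows)."""


class SchemaError(AirForestError):
    """Column schema problems: undeclared levels, bad kinds, mismatches."""


class ParameterError(AirForestError):
    """Invalid forest or study parameters (e.g. mtry exceeding the pool)."""


class DegenerateNodeError(AirForestError):
    """Impurity requested for an empty node."""


class UnsupportedConfigurationError(AirForestError):
    """A configuration the package deliberately refuses, e.g. multiclass
    nominal splitting with more levels than exhaustive enumeration allows."""


class WrongMethodError(AirForestError):
    """An importance/testing method applied to an incompatible forest,
    e.g. the plain impurity importance on an augmented-pool forest."""


class DegenerateNullError(AirForestError):
    """The mirror null cannot be built because no importance score is
    negative.  The mirror-null test relies on many uninformative
    variables producing negative scores; with few variables or mostly
    informative ones, fall back to a permutation-based test."""
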