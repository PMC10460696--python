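"""Exception hierarchy shared across the pipeline stages."""


class IsletGridError(Exception):
    """Base class for all package errors."""


class CoordinateError(IsletGridError, ValueError):
    """A voxel coordinate falls outside the sampling grid."""


class ConfigurationError(IsletGridError, ValueError):
    """A parameter value is outside its admissible range."""


class ValidationError(IsletGridError, ValueError):
    """Input data violate a structural invariant (listing the offenders)."""


class DesignError(IsletGridError, ValueError):
    """The linear-model design is confounded or rank deficient."""


class DimensionError(IsletGridError, ValueError):
    """A requested dimensionality exceeds what the data support."""


class InputError(IsletGridError, ValueError):
    """An operation received inputs violating its preconditions."""
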