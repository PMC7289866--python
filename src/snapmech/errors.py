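"""Exception hierarchy for snapmech."""


class SnapmechError(Exception):
    """Base class for all snapmech errors."""


class InvalidMorphometryError(SnapmechError):
    """Raised when mandible/body measurements violate their invariants."""


class InvalidGeometryError(SnapmechError):
    """Raised when a derived geometric quantity (e.g. centre of mass) is
    outside its feasible range."""


class InvalidDurationError(SnapmechError):
    """Raised for non-positive time intervals."""


class InsufficientDataError(SnapmechError):
    """Raised when a statistic requires more observations than supplied."""


class UndefinedRateError(SnapmechError):
    """Raised when a rate's denominator is zero."""


class SchemaError(SnapmechError):
    """Raised when an input table does not match the expected CSV schema."""


class ConfigError(SnapmechError):
    """Raised for infeasible or inconsistent simulation/pipeline configs."""
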