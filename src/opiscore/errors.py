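"""Exception hierarchy shared across the package."""


class OpiScoreError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(OpiScoreError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(OpiScoreError):
    """Too few samples/records to compute the requested quantity."""


class InvalidDataError(OpiScoreError):
    """Input data violate a structural invariant (e.g. non-unit quaternion)."""


class SchemaError(OpiScoreError):
    """A CSV file does not match its declared schema."""


class AlignmentError(OpiScoreError):
    """Subject identifiers do not align across input tables."""


class DegenerateDataError(OpiScoreError):
    """Response data carry no information for the requested model fit."""


class UndefinedStatisticError(OpiScoreError):
    """The requested statistic is undefined for these inputs."""
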