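"""Exception hierarchy shared across the toolkit."""


class ConnmetaError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(ConnmetaError):
    """A malformed domain value (bad URI, negative count, unknown enum member)."""


class UnknownClassError(SchemaError):
    """Entity class has no registered schema, community or user."""


class ValidationFailure(ConnmetaError):
    """Raised when an operation requires a valid record but validation failed."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class NotFoundError(ConnmetaError, KeyError):
    """An entity id was requested that the store does not contain.

    Deliberately distinct from an empty filter result, which is just ``[]``.
    """


class DuplicateIdError(ConnmetaError):
    """Insert attempted with an entity_id already present in its collection."""


class ConfigurationError(ConnmetaError):
    """Dataset or generator configuration is internally inconsistent."""


class FilterParseError(ConnmetaError):
    """A filter predicate used an unknown comparator or malformed clause."""
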