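"""Exception hierarchy shared across the package."""


class DmdWalkError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DmdWalkError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(DmdWalkError, ValueError):
    """Tabular input does not match the expected column schema."""


class DataIntegrityError(DmdWalkError, ValueError):
    """Input rows violate an internal consistency rule (e.g. able/time mismatch)."""


class SingularDesignError(DmdWalkError, ValueError):
    """The design matrix is rank deficient.

    ``dependent_columns`` lists the column indices involved in the linear
    dependence, when known.
    """

    def __init__(self, message: str, dependent_columns: list[int] | None = None):
        super().__init__(message)
        self.dependent_columns = dependent_columns or []


class DegreesOfFreedomError(DmdWalkError, ValueError):
    """Too few observations for the requested number of parameters."""


class DegenerateOutcomeError(DmdWalkError, ValueError):
    """The outcome vector carries no variance to explain."""
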