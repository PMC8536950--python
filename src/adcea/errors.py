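"""Exception hierarchy used across the package."""


class AdceaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AdceaError):
    """A configuration value is missing, malformed, or out of range."""


class ContractViolationError(AdceaError):
    """An operation was called outside its documented precondition."""


class CohortParseError(AdceaError):
    """A cohort file could not be parsed; carries row/field context."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if field is not None:
            loc.append(f"field '{field}'")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)
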