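"""Exception hierarchy for greenrank."""


class GreenrankError(Exception):
    """Base class for all greenrank errors."""


class SchemaError(GreenrankError):
    """A table's columns do not match the declared variable schema."""


class TableParseError(GreenrankError):
    """A cell could not be parsed as a number."""

    def __init__(self, row, column, value):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(
            f"non-numeric value {value!r} in row {row!r}, column {column!r}"
        )


class CompletenessError(GreenrankError):
    """Missing values where complete data is required."""


class NoCompleteProceduresError(CompletenessError):
    """Every procedure misses at least one required variable."""


class ValidationError(GreenrankError):
    """An input value violates a domain invariant."""


class PosetError(GreenrankError):
    """Internal inconsistency in an order relation."""


class ExactSizeError(GreenrankError):
    """Poset too large for exact linear-extension computation."""


class EmbeddingError(GreenrankError):
    """A poset cannot be embedded in the requested number of coordinates."""


class ConfigError(GreenrankError):
    """Invalid generator or pipeline configuration."""
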