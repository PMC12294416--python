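"""Exception hierarchy shared across the pipeline stages."""


class PeptimineError(Exception):
    """Base class for all package errors."""


class FastaParseError(PeptimineError):
    """Malformed FASTA input (missing header, empty record, ...)."""


class SequenceValidationError(PeptimineError):
    """A sequence contains a residue outside the accepted alphabet."""

    def __init__(self, record_id: str, position: int, residue: str):
        self.record_id = record_id
        self.position = position  # 1-based residue position
        self.residue = residue
        super().__init__(
            f"record {record_id!r}: invalid residue {residue!r} at position {position}"
        )


class RuleSyntaxError(PeptimineError):
    """Cleavage-rule text that does not follow the pattern grammar."""

    def __init__(self, message: str, column: int | None = None):
        self.column = column
        if column is not None:
            message = f"{message} (column {column})"
        super().__init__(message)


class SchemaError(PeptimineError):
    """A delimited input table is missing required columns."""


class ConsistencyError(PeptimineError):
    """Cross-table invariants violated (missing cells, orphan peptides, ...)."""


class PlacementError(PeptimineError):
    """A synthetic motif cannot be planted under the given rule set."""
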