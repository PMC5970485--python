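"""Exception hierarchy shared across the toolkit."""


class SCBoolNetError(Exception):
    """Base class for all toolkit errors."""


class FormatError(SCBoolNetError):
    """Structurally invalid input file (missing column, duplicate header...)."""


class BooleanParseError(SCBoolNetError):
    """A cell entry could not be parsed as Boolean; names row and column."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class ModelDocumentError(SCBoolNetError):
    """Malformed native JSON model document; carries the offending field."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class UnknownGeneError(SCBoolNetError, KeyError):
    """Lookup of a gene name that is not in the gene set."""


class InfeasibleError(SCBoolNetError):
    """Synthesis cannot proceed: some target state is unreachable from every
    initial state in the pruned directed state graph."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class IncompleteModelError(SCBoolNetError):
    """A combined model was requested but some gene has no compatible rule."""

    def __init__(self, message: str, genes=()):
        super().__init__(message)
        self.genes = tuple(genes)


class CapabilityError(SCBoolNetError):
    """Request exceeds a documented implementation bound."""
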