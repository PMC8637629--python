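"""Exception hierarchy shared across the pipeline stages."""


class GcmetaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GcmetaError):
    """Input file does not conform to the study-table schema."""


class ValidationError(GcmetaError):
    """Data are well-formed but violate a domain invariant."""


class DegenerateTableError(GcmetaError):
    """A 2x2 allele table has a zero cell and no continuity correction."""


class InsufficientStudiesError(GcmetaError):
    """An operation needs more studies than the table provides."""
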