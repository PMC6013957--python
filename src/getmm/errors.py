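"""Exception hierarchy.

Every error carries a short machine-readable ``category`` used by the CLI to
emit one-line diagnostics.
"""


class GetmmError(Exception):
    """Base class for all package errors."""

    category = "error"


class ValidationError(GetmmError):
    """Input data violates a structural invariant (negative count, bad cell...)."""

    category = "validation"


class ParseError(GetmmError):
    """A file could not be parsed; message names the offending line."""

    category = "parse"


class DuplicateKeyError(GetmmError):
    """Duplicate gene or sample identifier."""

    category = "duplicate-key"


class MissingLengthError(GetmmError):
    """Genes in the count matrix have no annotated length."""

    category = "missing-length"


class MissingGeneError(GetmmError):
    """A required signature gene is absent from the matrix."""

    category = "missing-gene"


class DegenerateSampleError(GetmmError):
    """A sample column is all zero, so no scaling factor can be defined."""

    category = "degenerate-sample"


class EstimationImpossibleError(GetmmError):
    """No gene satisfies the preconditions of the estimator (e.g. RLE with no
    gene positive in every sample)."""

    category = "estimation-impossible"


class UndefinedResultError(GetmmError):
    """The requested statistic is undefined on this input (e.g. pooled
    variance zero)."""

    category = "undefined-result"


class ContractError(GetmmError):
    """An operation was called outside its contract (wrong scale, too few
    samples...)."""

    category = "contract"
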