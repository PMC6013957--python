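"""In-memory containers for expression data.

Matrices are pandas DataFrames in the field's usual orientation: one row per
gene, one column per sample.  Missing values (genes set to NA after the
log2-at-zero rule) are ``NaN`` in memory and the literal token ``NA`` on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DuplicateKeyError, ValidationError

#: Normalization methods an ExpressionMatrix may be tagged with.
METHODS = ("raw", "rpk", "tpm", "tmm", "rle", "getmm")
SCALES = ("linear", "log2", "zscore")

#: Token used for missing values in text output.
NA_TOKEN = "NA"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise DuplicateKeyError(f"duplicate {what}: {dups[:5]}")


def validate_counts(counts: pd.DataFrame, min_samples: int = 1) -> pd.DataFrame:
    """Validate a raw count matrix (genes x samples, nonnegative integers).

    Returns the matrix with an integer dtype.  Raises ValidationError with the
    offending gene/sample coordinates on any bad cell.
    """
    _check_unique(counts.index, "gene IDs")
    _check_unique(counts.columns, "sample IDs")
    if counts.shape[1] < min_samples:
        raise ContractError(
            f"need at least {min_samples} samples, got {counts.shape[1]}"
        )
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = counts.map(lambda v: not isinstance(v, (int, float, np.number)))
        g, s = _first_true(bad)
        raise ValidationError(f"non-numeric count at gene {g!r}, sample {s!r}")
    if np.isnan(values.astype(float)).any():
        g, s = _first_true(counts.isna())
        raise ValidationError(f"missing count at gene {g!r}, sample {s!r}")
    if (values < 0).any():
        g, s = _first_true(counts < 0)
        raise ValidationError(f"negative count at gene {g!r}, sample {s!r}")
    if not np.array_equal(values, np.floor(values)):
        bad = counts != np.floor(counts)
        g, s = _first_true(bad)
        raise ValidationError(f"non-integer count at gene {g!r}, sample {s!r}")
    return counts.astype(np.int64)


def _first_true(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    g, s = stacked[stacked].index[0]
    return g, s


def validate_lengths(lengths: pd.Series) -> pd.Series:
    """Validate a gene-length table (gene ID -> length in base pairs)."""
    _check_unique(lengths.index, "gene IDs")
    lengths = lengths.astype(np.int64)
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1].tolist()
        raise ValidationError(f"gene length < 1 bp for {bad[:5]}")
    return lengths


@dataclass
class ExpressionMatrix:
    """A normalized gene x sample matrix tagged with its producing method.

    ``values`` is a float DataFrame; NaN marks missing entries, which may
    occur on the log2 scale only (a zero linear value has no logarithm).
    """

    values: pd.DataFrame
    method: str = "raw"
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown method tag {self.method!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "sample IDs")
        self.values = self.values.astype(float)
        if self.scale == "linear":
            arr = self.values.to_numpy()
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValidationError("linear-scale expression values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class NormFactors:
    """Per-sample multiplicative normalization factors.

    ``library_sizes`` are the quantities the factors modify: total read
    counts for TMM on raw counts, total RPK for the GeTMM variant.  For RLE
    the factor is applied to the counts directly and the library size is
    informational.
    """

    factors: pd.Series
    library_sizes: pd.Series
    method: str = "none"
    ref_sample: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.method not in ("tmm", "rle", "none"):
            raise ValidationError(f"unknown factor method {self.method!r}")
        f = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(f)) or (f <= 0).any():
            raise ValidationError("normalization factors must be positive and finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"factor": self.factors, "library_size": self.library_sizes}
        ).rename_axis("sample_id")


def as_values(m: "ExpressionMatrix | pd.DataFrame") -> pd.DataFrame:
    """Accept either an ExpressionMatrix or a bare DataFrame."""
    return m.values if isinstance(m, ExpressionMatrix) else m
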