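"""RNA-seq normalization: RPK, TPM, TMM, RLE and gene-length-corrected TMM.

The methods differ in two orthogonal choices:

* whether counts are first divided by gene length in kb (reads per
  kilobase, RPK), which makes expression levels comparable *within* a
  sample; and
* how the per-sample scaling constant is estimated — the plain column sum
  (TPM), a trimmed weighted mean of log ratios against a reference column
  (TMM), or the median ratio to the per-gene geometric mean (RLE) — which
  makes values comparable *between* samples.

GeTMM combines both: TMM factor estimation is run on the RPK matrix, with
the total RPK of a sample standing in for its library size, and the result
is scaled to per-million units.  When composition bias is absent (all TMM
factors 1) GeTMM reduces exactly to TPM.

Module-level functions implement the individual operations; the
``*Normalizer`` classes wrap them as scikit-learn transformers operating on
genes x samples DataFrames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix, NormFactors
from .errors import (
    ContractError,
    DegenerateSampleError,
    EstimationImpossibleError,
    MissingLengthError,
    ValidationError,
)

__all__ = [
    "rpk",
    "tpm",
    "cpm",
    "tmm_factors",
    "rle_factors",
    "scaled_expression",
    "getmm",
    "log2_with_missing",
    "TPMNormalizer",
    "TMMNormalizer",
    "RLENormalizer",
    "GeTMMNormalizer",
]


# ---------------------------------------------------------------------------
# functional core


def rpk(
    counts: pd.DataFrame,
    lengths: pd.Series,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Reads per kilobase: count / (gene length in kb).

    ``on_missing`` controls genes without an annotated length: ``"error"``
    (default) raises listing the offending IDs, ``"drop"`` removes them.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        if on_missing == "drop":
            counts = counts.drop(index=missing)
        elif on_missing == "error":
            ids = missing.tolist()
            shown = ", ".join(map(repr, ids[:5]))
            more = f" (+{len(ids) - 5} more)" if len(ids) > 5 else ""
            raise MissingLengthError(f"no length for gene(s) {shown}{more}")
        else:
            raise ValidationError(f"unknown on_missing policy {on_missing!r}")
    kb = lengths.loc[counts.index].astype(float) / 1000.0
    return counts.astype(float).div(kb, axis=0)


def _check_positive_columns(values: pd.DataFrame) -> pd.Series:
    colsums = values.sum(axis=0)
    zero = colsums.index[colsums <= 0].tolist()
    if zero:
        raise DegenerateSampleError(f"all-zero sample column(s): {zero[:5]}")
    return colsums


def tpm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    on_missing: str = "error",
) -> ExpressionMatrix:
    """Transcripts per kilobase million.

    Each gene's RPK is divided by the sample's total RPK over one million,
    so every column sums to 1e6.
    """
    r = rpk(counts, lengths, on_missing=on_missing)
    total = _check_positive_columns(r)
    values = r.div(total / 1e6, axis=1)
    return ExpressionMatrix(values, method="tpm", scale="linear")


def cpm(counts: pd.DataFrame, per: float = 1e6) -> ExpressionMatrix:
    """Counts per million over raw column sums (no length correction)."""
    total = _check_positive_columns(counts)
    return ExpressionMatrix(
        counts.astype(float).div(total / per, axis=1), method="raw", scale="linear"
    )


def tmm_factors(
    m: pd.DataFrame,
    ref_sample: str | None = None,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    weighted: bool = True,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample against a reference column, per-gene log2 expression
    ratios (M) and average log2 abundances (A) are computed over genes
    positive in both columns; genes in the extreme ``logratio_trim``
    fraction of M and ``abs_trim`` fraction of A are discarded, and the
    factor is 2 to the precision-weighted mean of the surviving M values.
    Factors are rescaled to geometric mean 1.

    ``m`` may hold raw counts or fractional RPK values; its column sums act
    as library sizes.  If ``ref_sample`` is unset, the column whose upper
    quartile (scaled by library size) is closest to the mean of those upper
    quartiles is used; ties break to the first column.
    """
    if m.shape[1] < 2:
        raise ContractError("TMM needs at least 2 samples")
    values = m.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("negative values in TMM input")
    lib = _check_positive_columns(m).to_numpy(dtype=float)
    samples = list(m.columns)

    if ref_sample is None:
        upper_q = np.quantile(values, 0.75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(upper_q - upper_q.mean())))
    else:
        if ref_sample not in m.columns:
            raise ValidationError(f"unknown reference sample {ref_sample!r}")
        ref_idx = samples.index(ref_sample)

    y_r = values[:, ref_idx]
    n_r = lib[ref_idx]
    factors = np.ones(len(samples))
    for k in range(len(samples)):
        factors[k] = _tmm_pair(
            values[:, k], lib[k], y_r, n_r, logratio_trim, abs_trim, weighted
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        factors=pd.Series(factors, index=m.columns, name="factor"),
        library_sizes=pd.Series(lib, index=m.columns, name="library_size"),
        method="tmm",
        ref_sample=samples[ref_idx],
    )


def _tmm_pair(
    y_k: np.ndarray,
    n_k: float,
    y_r: np.ndarray,
    n_r: float,
    logratio_trim: float,
    abs_trim: float,
    weighted: bool,
) -> float:
    """One sample's TMM factor against the reference column."""
    both = (y_k > 0) & (y_r > 0)
    yk, yr = y_k[both], y_r[both]
    if yk.size == 0:
        return 1.0
    pk, pr = yk / n_k, yr / n_r
    m_val = np.log2(pk / pr)
    a_val = 0.5 * np.log2(pk * pr)
    # asymptotic variance of M by the delta method; precision weight is 1/var
    var = (n_k - yk) / (n_k * yk) + (n_r - yr) / (n_r * yr)

    n = m_val.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(m_val)
    rank_a = rankdata(a_val)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any() or np.max(np.abs(m_val[keep])) < 1e-6:
        return 1.0
    if weighted:
        f = np.sum(m_val[keep] / var[keep]) / np.sum(1.0 / var[keep])
    else:
        f = np.mean(m_val[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def rle_factors(counts: pd.DataFrame) -> NormFactors:
    """Relative-log-expression (median-of-ratios) size factors.

    The per-gene geometric mean across samples is the pseudo-reference;
    each sample's factor is the median, over genes positive in every
    sample, of that sample's count over the reference.  Fractional input is
    rejected (the convention of median-of-ratios implementations, which
    take raw integer counts only).
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("negative values in RLE input")
    if not np.array_equal(values, np.floor(values)):
        raise ValidationError(
            "RLE requires integer read counts; fractional values "
            "(e.g. length-corrected RPK) are not accepted"
        )
    all_pos = (values > 0).all(axis=1)
    if not all_pos.any():
        raise EstimationImpossibleError(
            "no gene has strictly positive counts in every sample"
        )
    logs = np.log(values[all_pos])
    log_geomean = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return NormFactors(
        factors=pd.Series(factors, index=counts.columns, name="factor"),
        library_sizes=counts.sum(axis=0).astype(float).rename("library_size"),
        method="rle",
    )


def scaled_expression(
    m: pd.DataFrame,
    factors: NormFactors,
    per: float = 1e6,
) -> ExpressionMatrix:
    """Apply normalization factors to a matrix.

    TMM-style factors modify the effective library size:
    ``value = m / (library_size * factor) * per``.  RLE-style factors
    divide the counts directly (``per`` is ignored; pass
    ``rle_per_million=True`` via :class:`RLENormalizer` when cross-method
    comparability is needed).
    """
    missing = m.columns.difference(factors.factors.index)
    if len(missing):
        raise KeyError(f"sample(s) missing from factors: {missing.tolist()[:5]}")
    f = factors.factors.loc[m.columns]
    if factors.method == "rle":
        values = m.astype(float).div(f, axis=1)
        return ExpressionMatrix(values, method="rle", scale="linear")
    lib = factors.library_sizes.loc[m.columns]
    values = m.astype(float).div(lib * f / per, axis=1)
    return ExpressionMatrix(values, method="tmm", scale="linear")


def getmm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    on_missing: str = "error",
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    weighted: bool = True,
) -> ExpressionMatrix:
    """Gene-length corrected TMM.

    TMM factors are estimated on the RPK matrix itself, with the total RPK
    of each sample as its library size, and the RPK values are scaled to
    per-million units of the factor-adjusted total.  Equals TPM exactly
    when every factor is 1.
    """
    r = rpk(counts, lengths, on_missing=on_missing)
    nf = tmm_factors(
        r, logratio_trim=logratio_trim, abs_trim=abs_trim, weighted=weighted
    )
    out = scaled_expression(r, nf, per=1e6)
    return ExpressionMatrix(out.values, method="getmm", scale="linear")


def log2_with_missing(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform, marking zeros as missing (NA) rather than -inf."""
    if m.scale != "linear":
        raise ContractError("input is already on the log2 scale")
    values = m.values.to_numpy(dtype=float)
    out = np.full_like(values, np.nan)
    pos = values > 0
    out[pos] = np.log2(values[pos])
    out[np.isnan(values)] = np.nan
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        method=m.method,
        scale="log2",
    )


# ---------------------------------------------------------------------------
# scikit-learn style transformers


class _LengthsMixin:
    def _lengths(self) -> pd.Series:
        if self.gene_lengths is None:
            raise ContractError("gene_lengths must be provided")
        return pd.Series(self.gene_lengths)


class TPMNormalizer(TransformerMixin, BaseEstimator, _LengthsMixin):
    """Transcripts-per-million transformer (stateless across samples).

    Parameters
    ----------
    gene_lengths : mapping or Series
        Gene ID -> length in base pairs.
    on_missing : {"error", "drop"}
        Policy for genes lacking a length.
    log2 : bool
        Emit log2 values with zeros as NaN.
    """

    def __init__(self, gene_lengths=None, on_missing="error", log2=False):
        self.gene_lengths = gene_lengths
        self.on_missing = on_missing
        self.log2 = log2

    def fit(self, X: pd.DataFrame, y=None):
        self._lengths()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self)
        out = tpm(X, self._lengths(), on_missing=self.on_missing)
        if self.log2:
            out = log2_with_missing(out)
        return out.values


class TMMNormalizer(TransformerMixin, BaseEstimator):
    """TMM-normalized counts per million.

    ``fit`` estimates per-sample factors and library sizes (available as
    ``factors_``, ``library_sizes_``, ``ref_sample_``); ``transform``
    rescales a matrix with them.
    """

    def __init__(
        self,
        ref_sample=None,
        logratio_trim=0.30,
        abs_trim=0.05,
        weighted=True,
        per=1e6,
        log2=False,
    ):
        self.ref_sample = ref_sample
        self.logratio_trim = logratio_trim
        self.abs_trim = abs_trim
        self.weighted = weighted
        self.per = per
        self.log2 = log2

    def fit(self, X: pd.DataFrame, y=None):
        nf = tmm_factors(
            X,
            ref_sample=self.ref_sample,
            logratio_trim=self.logratio_trim,
            abs_trim=self.abs_trim,
            weighted=self.weighted,
        )
        self.norm_factors_ = nf
        self.factors_ = nf.factors
        self.library_sizes_ = nf.library_sizes
        self.ref_sample_ = nf.ref_sample
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self)
        out = scaled_expression(X, self.norm_factors_, per=self.per)
        if self.log2:
            out = log2_with_missing(out)
        return out.values


class RLENormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios size-factor normalization.

    By default the output is factor-divided counts; ``per_million=True``
    additionally rescales each column by the factor-adjusted library size
    for cross-method comparability.
    """

    def __init__(self, per_million=False, per=1e6, log2=False):
        self.per_million = per_million
        self.per = per
        self.log2 = log2

    def fit(self, X: pd.DataFrame, y=None):
        nf = rle_factors(X)
        self.norm_factors_ = nf
        self.factors_ = nf.factors
        self.library_sizes_ = nf.library_sizes
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self)
        out = scaled_expression(X, self.norm_factors_)
        values = out.values
        if self.per_million:
            eff = self.library_sizes_.loc[X.columns] / self.factors_.loc[X.columns]
            values = values.div(eff / self.per, axis=1)
        if self.log2:
            return log2_with_missing(
                ExpressionMatrix(values, method="rle", scale="linear")
            ).values
        return values


class GeTMMNormalizer(TransformerMixin, BaseEstimator, _LengthsMixin):
    """Gene-length corrected TMM transformer.

    ``fit`` converts counts to RPK and estimates TMM factors on total RPK;
    ``transform`` returns per-million scaled values comparable both within
    and between samples.
    """

    def __init__(
        self,
        gene_lengths=None,
        on_missing="error",
        logratio_trim=0.30,
        abs_trim=0.05,
        weighted=True,
        log2=False,
    ):
        self.gene_lengths = gene_lengths
        self.on_missing = on_missing
        self.logratio_trim = logratio_trim
        self.abs_trim = abs_trim
        self.weighted = weighted
        self.log2 = log2

    def fit(self, X: pd.DataFrame, y=None):
        r = rpk(X, self._lengths(), on_missing=self.on_missing)
        nf = tmm_factors(
            r,
            logratio_trim=self.logratio_trim,
            abs_trim=self.abs_trim,
            weighted=self.weighted,
        )
        self.norm_factors_ = nf
        self.factors_ = nf.factors
        self.library_sizes_ = nf.library_sizes  # total RPK per sample
        self.ref_sample_ = nf.ref_sample
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self)
        r = rpk(X, self._lengths(), on_missing=self.on_missing)
        out = scaled_expression(r, self.norm_factors_, per=1e6)
        if self.log2:
            return log2_with_missing(out).values
        return out.values
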