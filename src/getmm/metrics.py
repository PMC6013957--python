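"""Evaluation statistics for comparing normalization methods.

Implements gene-wise Z-normalization, RMSE on standardized data, the
signal-to-noise ratio with pooled variance, per-gene (intersample) and
per-sample (intrasample) correlation suites, Bland-Altman agreement, and
two-group differential tests with Benjamini-Hochberg FDR control.

Missing values (NaN) are excluded pairwise throughout; sample standard
deviations use the n-1 denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, as_values
from .errors import ContractError, UndefinedResultError, ValidationError

__all__ = [
    "z_normalize",
    "rmse",
    "snr",
    "correlate_per_gene",
    "correlate_per_sample",
    "bland_altman",
    "BlandAltmanResult",
    "two_group_tests",
    "bh_fdr",
]


def z_normalize(m: ExpressionMatrix | pd.DataFrame) -> ExpressionMatrix:
    """Standardize each gene row to mean 0 and standard deviation 1.

    Missing values are excluded from the moments and stay missing.  A gene
    with zero variance (or fewer than two observed values) cannot be
    standardized; its row is set to all-missing with a warning.
    """
    values = as_values(m)
    mean = values.mean(axis=1, skipna=True)
    sd = values.std(axis=1, ddof=1, skipna=True)
    n_obs = values.notna().sum(axis=1)
    bad = (n_obs < 2) | (sd == 0) | sd.isna()
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) with zero variance or <2 observations "
            "set to all-missing",
            stacklevel=2,
        )
    out = values.sub(mean, axis=0).div(sd, axis=0)
    out.loc[bad] = np.nan
    method = m.method if isinstance(m, ExpressionMatrix) else "raw"
    return ExpressionMatrix(out, method=method, scale="zscore")


def _complete_pairs(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ContractError(f"length mismatch: {a.shape} vs {b.shape}")
    ok = ~(np.isnan(a) | np.isnan(b))
    return a[ok], b[ok]


def rmse(a, b) -> float:
    """Root mean square error over complete (non-missing) pairs."""
    x, y = _complete_pairs(a, b)
    if x.size == 0:
        raise UndefinedResultError("no complete pairs for RMSE")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def snr(x1, x2) -> float:
    """Signal-to-noise ratio: group mean difference over the pooled SD.

    The pooled variance weights each group's sample variance by its
    degrees of freedom: Vp = [(n1-1)V1 + (n2-1)V2] / (n1+n2-2).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ContractError("SNR needs at least 2 observations per group")
    v1, v2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
    vp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if vp == 0:
        raise UndefinedResultError("pooled variance is zero")
    return float((np.mean(x1) - np.mean(x2)) / np.sqrt(vp))


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValidationError(f"unknown correlation method {method!r}")


def _correlate(a: pd.DataFrame, b: pd.DataFrame, method: str, min_pairs: int = 3):
    coefs, ns = {}, {}
    for key in a.index:
        x, y = _complete_pairs(a.loc[key], b.loc[key])
        ns[key] = x.size
        coefs[key] = _corr(x, y, method) if x.size >= min_pairs else np.nan
    return pd.DataFrame({"coefficient": pd.Series(coefs), "n_pairs": pd.Series(ns)})


def correlate_per_gene(
    rnaseq: ExpressionMatrix | pd.DataFrame,
    reference: ExpressionMatrix | pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Intersample correlation: one coefficient per shared gene, across
    the shared samples.  Genes with fewer than 3 complete pairs get a
    missing coefficient; ``n_pairs`` reports usable pair counts.
    """
    a, b = as_values(rnaseq), as_values(reference)
    genes = a.index.intersection(b.index)
    samples = a.columns.intersection(b.columns)
    return _correlate(a.loc[genes, samples], b.loc[genes, samples], method)


def correlate_per_sample(
    rnaseq: ExpressionMatrix | pd.DataFrame,
    reference: ExpressionMatrix | pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Intrasample correlation: one coefficient per shared sample, across
    the shared genes.  The rank statistic makes this the probe for gene
    length bias: within a sample, length-uncorrected values rank genes by
    count x length rather than abundance.
    """
    a, b = as_values(rnaseq), as_values(reference)
    genes = a.index.intersection(b.index)
    samples = a.columns.intersection(b.columns)
    return _correlate(a.loc[genes, samples].T, b.loc[genes, samples].T, method)


@dataclass
class BlandAltmanResult:
    bias: float
    limits: tuple[float, float]
    p_value: float
    n: int


def bland_altman(c_high, c_low) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired coefficient sets.

    Differences d = c_high - c_low give the bias (mean of d), the 95%
    limits of agreement (bias +/- 1.96 sd(d)) and a one-sample t-test of d
    against zero.
    """
    d_high, d_low = _complete_pairs(c_high, c_low)
    d = d_high - d_low
    if d.size < 2:
        raise ContractError("Bland-Altman needs at least 2 complete pairs")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    limits = (bias - 1.96 * sd, bias + 1.96 * sd)
    if sd == 0:
        if bias == 0:
            p = 1.0
        else:
            warnings.warn(
                "zero variance of differences with nonzero bias; "
                "p-value reported as smallest positive float",
                stacklevel=2,
            )
            p = float(np.nextafter(0.0, 1.0))
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return BlandAltmanResult(bias=bias, limits=limits, p_value=p, n=int(d.size))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_group_tests(
    m: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    test: str = "t_test",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sided two-group tests with BH-adjusted FDR.

    ``labels`` maps sample IDs to group 1 or 2.  ``t_test`` is the classic
    pooled-variance Student's t-test (``equal_var=False`` switches to
    Welch); ``mann_whitney`` the Mann-Whitney U test.  Genes with no
    observed value in a group are flagged untestable (NaN statistic and
    p-value, excluded from the FDR adjustment).
    """
    values = as_values(m)
    labels = pd.Series(labels)
    unknown = labels.index.difference(values.columns)
    if len(unknown):
        raise ValidationError(f"labeled sample(s) not in matrix: {unknown.tolist()[:5]}")
    groups = set(labels.unique())
    if groups != {1, 2}:
        raise ValidationError(f"labels must be 1 or 2 with both groups present, got {sorted(groups)}")
    g1 = labels.index[labels == 1]
    g2 = labels.index[labels == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise ContractError("both groups need at least 2 samples")

    records = []
    for gene in values.index:
        x1 = values.loc[gene, g1].dropna().to_numpy(dtype=float)
        x2 = values.loc[gene, g2].dropna().to_numpy(dtype=float)
        if x1.size < 2 or x2.size < 2:
            records.append((gene, np.nan, np.nan, False))
            continue
        if test == "t_test":
            res = stats.ttest_ind(x1, x2, equal_var=equal_var)
        elif test == "mann_whitney":
            res = stats.mannwhitneyu(x1, x2, alternative="two-sided")
        else:
            raise ValidationError(f"unknown test {test!r}")
        stat, p = float(res.statistic), float(res.pvalue)
        records.append((gene, stat, p, np.isfinite(p)))
    out = pd.DataFrame(
        records, columns=["gene_id", "statistic", "p_value", "testable"]
    ).set_index("gene_id")
    out["fdr"] = np.nan
    mask = out["testable"]
    if mask.any():
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p_value"].to_numpy())
    return out
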