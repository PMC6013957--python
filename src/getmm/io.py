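"""Reading and writing count/expression matrices and gene-length derivation.

Count and expression matrices are tab-delimited UTF-8 text: a header row
``gene_id<TAB>sample1<TAB>...`` followed by one gene per row.  Expression
matrices carry their method/scale tags in a leading ``#`` comment line so
they round-trip losslessly.  Gene lengths come from GTF annotation
(GENCODE dialect, 1-based end-inclusive coordinates).
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .containers import (
    NA_TOKEN,
    ExpressionMatrix,
    validate_counts,
    validate_lengths,
)
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "gene_lengths_from_gtf",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_expression_matrix",
    "write_expression_matrix",
]


def read_count_matrix(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a raw read-count matrix (first column gene IDs, header sample IDs).

    Returns an integer DataFrame (genes x samples).  Non-numeric, negative or
    fractional cells and duplicate gene IDs are rejected with the offending
    coordinates.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    except pd.errors.ParserError as exc:  # malformed row structure
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.index.name is None and df.shape[1] == 0:
        raise ParseError(f"{path}: missing sample header row")
    # Columns that failed numeric inference pinpoint the first bad cell.
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"non-numeric count at gene {bad[0]!r}, sample {col!r}"
                )
            df[col] = coerced
    return validate_counts(df)


def _iter_gtf_exons(path: str | Path):
    """Yield gffutils Feature objects for exon records, skipping comments."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"GTF line {lineno}: expected 9 fields, got {len(fields)}")
            if fields[2] != "exon":
                continue
            try:
                yield gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:
                raise ParseError(f"GTF line {lineno}: {exc}") from exc


def _merge_intervals(intervals: list[tuple[int, int]]) -> int:
    """Total covered length of 1-based inclusive intervals after union-merge."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def gene_lengths_from_gtf(
    path: str | Path,
    id_attribute: str = "gene_id",
    exon_id_attribute: str = "exon_id",
    mode: str = "unique_exon_sum",
) -> pd.Series:
    """Derive per-gene lengths (bp) from GTF exon records.

    ``unique_exon_sum`` (default): exon records sharing a gene are
    deduplicated by their exon-ID attribute and the lengths of the distinct
    exons are summed.  Exons that overlap but carry distinct IDs are counted
    in full, so overlapping bases may contribute more than once.

    ``merged_union``: overlapping exon intervals of a gene are merged
    (strand-agnostic) and the union length is summed, so every genomic base
    counts at most once.

    Exons lacking the gene-ID attribute are skipped with a logged warning.
    Records lacking the exon-ID attribute fall back to their
    (chrom, start, end, strand) tuple as deduplication key.
    """
    if mode not in ("unique_exon_sum", "merged_union"):
        raise ValidationError(f"unknown mode {mode!r}")
    exons: dict[str, dict] = {}
    skipped = 0
    for feat in _iter_gtf_exons(path):
        gene_ids = feat.attributes.get(id_attribute)
        if not gene_ids:
            skipped += 1
            continue
        gene = gene_ids[0]
        per_gene = exons.setdefault(gene, {})
        exon_ids = feat.attributes.get(exon_id_attribute)
        key = exon_ids[0] if exon_ids else (feat.seqid, feat.start, feat.end, feat.strand)
        # first record wins for a duplicated exon_id; GENCODE repeats
        # identical coordinates across transcripts
        per_gene.setdefault(key, (feat.start, feat.end))
    if skipped:
        logger.warning(
            "skipped %d exon record(s) lacking the %r attribute", skipped, id_attribute
        )
    lengths = {}
    for gene, table in exons.items():
        intervals = list(table.values())
        if mode == "unique_exon_sum":
            lengths[gene] = sum(end - start + 1 for start, end in intervals)
        else:
            lengths[gene] = _merge_intervals(intervals)
    out = pd.Series(lengths, name="length", dtype=np.int64).rename_axis("gene_id")
    return validate_lengths(out)


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read a two-column gene_id / length TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] != 1:
        raise ParseError(f"{path}: expected two columns (gene_id, length)")
    return validate_lengths(df.iloc[:, 0].rename("length"))


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length").rename_axis("gene_id").to_csv(path, sep="\t")


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV with its tags in a comment line.

    Missing values are serialized as the token ``NA``.
    """
    with open(path, "w") as fh:
        fh.write(f"# method={m.method} scale={m.scale}\n")
        m.values.rename_axis("gene_id").to_csv(fh, sep="\t", na_rep=NA_TOKEN)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix written by :func:`write_expression_matrix`.

    A missing tag line yields a matrix tagged raw/linear.
    """
    method, scale = "raw", "linear"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            tags = dict(
                tok.split("=", 1) for tok in first.lstrip("#").split() if "=" in tok
            )
            method = tags.get("method", method)
            scale = tags.get("scale", scale)
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0, na_values=[NA_TOKEN])
    return ExpressionMatrix(df.astype(float), method=method, scale=scale)
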