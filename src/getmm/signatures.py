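"""The 7-gene Oncotype DX-style recurrence score for colon cancer.

The score combines a stromal panel (BGN, FAP, INHBA), a cell-cycle panel
(MKI67, MYC, MYBL2) and GADD45B.  The unscaled score is a fixed linear
combination of panel means,

    Rsu = 0.1263 * mean(stromal) - 0.3158 * mean(cell cycle)
        + 0.3406 * GADD45B,

and the reported score is RS = 44.16 * (Rsu + 0.30), clipped below at
zero.  High stromal and GADD45B expression raise the risk score; high
proliferation (cell-cycle) expression lowers the unscaled score.

Expression input is expected on a log scale by default, matching the
delta-delta-Cq convention of the qPCR assay the score was designed for;
pass a linear matrix through :func:`getmm.normalize.log2_with_missing`
first (the CLI does this automatically).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, as_values
from .errors import MissingGeneError, ValidationError

__all__ = ["RecurrencePanel", "DEFAULT_PANEL", "recurrence_score"]

_VERSION_SUFFIX = re.compile(r"\.\d+$")


@dataclass(frozen=True)
class RecurrencePanel:
    """Gene sets and coefficients of the recurrence score."""

    stromal: tuple[str, ...] = ("BGN", "FAP", "INHBA")
    cell_cycle: tuple[str, ...] = ("MKI67", "MYC", "MYBL2")
    single: str = "GADD45B"
    stromal_coef: float = 0.1263
    cell_cycle_coef: float = -0.3158
    single_coef: float = 0.3406
    scale: float = 44.16
    offset: float = 0.30

    def __post_init__(self) -> None:
        genes = self.all_genes
        if len(set(genes)) != len(genes):
            raise ValidationError("panel genes must be distinct")

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.stromal + self.cell_cycle + (self.single,)


DEFAULT_PANEL = RecurrencePanel()


def _normalize_symbol(symbol: str) -> str:
    return _VERSION_SUFFIX.sub("", str(symbol)).upper()


def _locate(index: pd.Index, gene: str, id_map: dict | None) -> object:
    if id_map and gene in id_map:
        target = id_map[gene]
        if target not in index:
            raise MissingGeneError(f"mapped ID {target!r} for panel gene {gene!r} absent")
        return target
    wanted = _normalize_symbol(gene)
    hits = [ix for ix in index if _normalize_symbol(ix) == wanted]
    if not hits:
        raise MissingGeneError(f"panel gene {gene!r} absent from matrix")
    if len(hits) > 1:
        raise ValidationError(f"panel gene {gene!r} matches multiple rows: {hits}")
    return hits[0]


def recurrence_score(
    m: ExpressionMatrix | pd.DataFrame,
    panel: RecurrencePanel = DEFAULT_PANEL,
    id_map: dict | None = None,
) -> pd.DataFrame:
    """Score every sample of an expression matrix.

    Returns a DataFrame indexed by sample with columns ``rsu`` (unscaled
    score), ``rs_raw`` (scaled, unclipped), ``rs`` (clipped at zero) and
    ``scorable``.  Samples with a missing value in any panel gene are
    flagged unscorable (NaN scores).  Gene symbols are matched
    case-insensitively after stripping ``.N`` version suffixes; ``id_map``
    overrides matching per gene.
    """
    values = as_values(m)
    rows = {g: _locate(values.index, g, id_map) for g in panel.all_genes}
    sub = values.loc[[rows[g] for g in panel.all_genes]].astype(float)
    sub.index = list(panel.all_genes)

    stromal_mean = sub.loc[list(panel.stromal)].mean(axis=0, skipna=False)
    cc_mean = sub.loc[list(panel.cell_cycle)].mean(axis=0, skipna=False)
    single = sub.loc[panel.single]

    rsu = (
        panel.stromal_coef * stromal_mean
        + panel.cell_cycle_coef * cc_mean
        + panel.single_coef * single
    )
    rs_raw = panel.scale * (rsu + panel.offset)
    rs = rs_raw.clip(lower=0.0)
    scorable = ~sub.isna().any(axis=0)
    out = pd.DataFrame(
        {"rsu": rsu, "rs_raw": rs_raw, "rs": rs, "scorable": scorable}
    ).rename_axis("sample_id")
    out.loc[~scorable, ["rsu", "rs_raw", "rs"]] = np.nan
    return out
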