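"""Synthetic RNA-seq count generator with known ground truth.

The model: each gene g has a true transcript concentration c[g] (how many
molecules, per arbitrary unit) and a length L[g] in bp.  Sequencing reads
land on a gene proportionally to c * L — a long transcript yields more
fragments than a short one at equal molarity — so the expected count in
sample s is

    mu[g, s] = lib[s] * c[g, s] * L[g] / sum_g' c[g', s] * L[g'],

and observed counts are negative-binomial with mean mu and variance
mu + phi * mu^2 (phi = dispersion; phi -> 0 recovers Poisson).  Optional
composition bias multiplies a fraction of genes by a fold-change in chosen
samples before renormalization, and optional differential expression
shifts a fraction of genes between two sample groups.

This deliberately reproduces the confound the normalizations must undo:
raw counts mix abundance with gene length (intrasample bias), and a few
boosted genes shrink every other gene's share of the library
(intersample composition bias).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import validate_counts
from .errors import ValidationError
from .io import write_gene_lengths

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "make_fixture", "FIXTURES"]


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for the count generator.

    Defaults give the package's reference scenario: 1000 genes with
    lengths log-uniform over 0.2-20 kb, 50 samples, log-normal
    concentrations (sd 2 in natural log), library sizes log-uniform over
    0.5-2 million reads, and negative-binomial dispersion 0.4 (the common
    dispersion recommended for cohorts without replicates).
    """

    n_genes: int = 1000
    n_samples: int = 50
    length_range: tuple[float, float] = (200.0, 20_000.0)
    log_conc_mean: float = 0.0
    log_conc_sd: float = 2.0
    library_sizes: tuple[float, ...] | None = None
    library_size_range: tuple[float, float] = (5e5, 2e6)
    dispersion: float = 0.4
    #: (fraction of genes, fold-change, affected sample indices)
    composition_bias: tuple[float, float, tuple[int, ...]] | None = None
    #: (fraction of genes, log2 fold-change) applied to group-2 samples
    de_genes: tuple[float, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2 or self.n_samples < 1:
            raise ValidationError("need n_genes >= 2 and n_samples >= 1")
        if self.length_range[0] < 1 or self.length_range[1] < self.length_range[0]:
            raise ValidationError("length_range must satisfy 1 <= min <= max")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.library_sizes is not None and len(self.library_sizes) != self.n_samples:
            raise ValidationError("library_sizes must have one entry per sample")
        if self.composition_bias is not None:
            frac, fold, samples = self.composition_bias
            if not 0 <= frac <= 1:
                raise ValidationError("composition fraction must be in [0, 1]")
            if fold <= 0:
                raise ValidationError("composition fold-change must be > 0")
            if any(s < 0 or s >= self.n_samples for s in samples):
                raise ValidationError("composition sample index out of range")
        if self.de_genes is not None and not 0 <= self.de_genes[0] <= 1:
            raise ValidationError("DE fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth behind a simulated count matrix.

    ``concentration`` holds the per-sample true concentrations after any
    composition-bias or DE multipliers, so Spearman against it measures
    how faithfully a normalization recovers relative abundance.
    """

    concentration: pd.DataFrame  # genes x samples, post-modifier
    base_concentration: pd.Series  # per-gene, pre-modifier
    lengths: pd.Series  # bp
    library_sizes: pd.Series  # expected reads per sample
    groups: pd.Series  # sample -> 1 or 2
    composition_genes: pd.Index = field(default_factory=lambda: pd.Index([]))
    de_gene_ids: pd.Index = field(default_factory=lambda: pd.Index([]))


def _gene_sample_ids(cfg: SimConfig) -> tuple[list[str], list[str]]:
    width = len(str(cfg.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    samples = [f"S{j + 1:02d}" for j in range(cfg.n_samples)]
    return genes, samples


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Draw a (counts, lengths, truth) triple, bit-reproducible from cfg.

    Gene-level quantities come from one child random stream; each sample's
    counts from its own child stream (spawn-key seeded), so regenerating a
    subset of columns is stable.
    """
    cfg.validate()
    genes, samples = _gene_sample_ids(cfg)
    root = np.random.SeedSequence(cfg.seed)
    gene_stream = np.random.default_rng(root.spawn(1)[0])

    log_min, log_max = np.log(cfg.length_range[0]), np.log(cfg.length_range[1])
    lengths = np.exp(gene_stream.uniform(log_min, log_max, cfg.n_genes))
    lengths = np.maximum(np.round(lengths), 1.0)
    base_conc = gene_stream.lognormal(cfg.log_conc_mean, cfg.log_conc_sd, cfg.n_genes)

    if cfg.library_sizes is not None:
        lib = np.asarray(cfg.library_sizes, dtype=float)
    else:
        lib = np.exp(
            gene_stream.uniform(
                np.log(cfg.library_size_range[0]),
                np.log(cfg.library_size_range[1]),
                cfg.n_samples,
            )
        )

    groups = np.ones(cfg.n_samples, dtype=int)
    groups[cfg.n_samples // 2 :] = 2

    conc = np.tile(base_conc[:, None], (1, cfg.n_samples))
    de_ids = pd.Index([])
    if cfg.de_genes is not None and cfg.de_genes[0] > 0:
        frac, lfc = cfg.de_genes
        n_de = int(round(frac * cfg.n_genes))
        de_idx = gene_stream.choice(cfg.n_genes, size=n_de, replace=False)
        conc[np.ix_(de_idx, np.flatnonzero(groups == 2))] *= 2.0**lfc
        de_ids = pd.Index([genes[i] for i in sorted(de_idx)])

    comp_ids = pd.Index([])
    if cfg.composition_bias is not None and cfg.composition_bias[0] > 0:
        frac, fold, affected = cfg.composition_bias
        n_comp = int(round(frac * cfg.n_genes))
        comp_idx = gene_stream.choice(cfg.n_genes, size=n_comp, replace=False)
        conc[np.ix_(comp_idx, list(affected))] *= fold
        comp_ids = pd.Index([genes[i] for i in sorted(comp_idx)])

    weight = conc * lengths[:, None]
    prob = weight / weight.sum(axis=0, keepdims=True)
    mu = prob * lib[None, :]

    counts = np.empty((cfg.n_genes, cfg.n_samples), dtype=np.int64)
    sample_streams = root.spawn(1 + cfg.n_samples)[1:]
    for j, ss in enumerate(sample_streams):
        rng = np.random.default_rng(ss)
        m = mu[:, j]
        if cfg.dispersion < 1e-12:
            counts[:, j] = rng.poisson(m)
        else:
            r = 1.0 / cfg.dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + m))

    counts_df = validate_counts(pd.DataFrame(counts, index=genes, columns=samples))
    lengths_s = pd.Series(lengths.astype(np.int64), index=genes, name="length")
    truth = SimTruth(
        concentration=pd.DataFrame(conc, index=genes, columns=samples),
        base_concentration=pd.Series(base_conc, index=genes, name="concentration"),
        lengths=lengths_s,
        library_sizes=pd.Series(lib, index=samples, name="library_size"),
        groups=pd.Series(groups, index=samples, name="group"),
        composition_genes=comp_ids,
        de_gene_ids=de_ids,
    )
    return counts_df, lengths_s, truth


def write_gtf(lengths: pd.Series, path: str | Path, max_exons: int = 3) -> None:
    """Write a GENCODE-dialect GTF whose unique-exon lengths reproduce
    ``lengths``.  Genes are laid end to end on one contig; each gene is
    split into up to ``max_exons`` non-overlapping exons with distinct
    exon_ids, and each exon record is repeated for two transcripts to
    exercise exon_id deduplication.
    """
    pos = 1
    with open(path, "w") as fh:
        fh.write("##provider: synthetic\n")
        for i, (gene, length) in enumerate(lengths.items()):
            n_exons = min(max_exons, int(length)) or 1
            cuts = np.linspace(0, int(length), n_exons + 1).astype(int)
            attrs_gene = f'gene_id "{gene}"; gene_name "{gene}";'
            fh.write(
                f"chr1\tsynthetic\tgene\t{pos}\t{pos + int(length) - 1}\t.\t+\t.\t{attrs_gene}\n"
            )
            for t in (1, 2):  # duplicate transcript records share exon_ids
                for e in range(n_exons):
                    start = pos + cuts[e]
                    end = pos + cuts[e + 1] - 1
                    if end < start:
                        continue
                    attrs = (
                        f'gene_id "{gene}"; transcript_id "{gene}.t{t}"; '
                        f'exon_id "{gene}.e{e + 1}"; gene_name "{gene}";'
                    )
                    fh.write(f"chr1\tsynthetic\texon\t{start}\t{end}\t.\t+\t.\t{attrs}\n")
            pos += int(length) + 100
        fh.flush()


def _fixture_tiny() -> SimConfig:
    return SimConfig(n_genes=8, n_samples=4, library_size_range=(2e3, 4e3), seed=101)


def _fixture_composition() -> SimConfig:
    return SimConfig(
        n_genes=500,
        n_samples=4,
        composition_bias=(0.05, 20.0, (3,)),
        seed=202,
    )


def _fixture_intrasample() -> SimConfig:
    return SimConfig(n_genes=200, n_samples=10, seed=303)


FIXTURES = {
    "tiny": _fixture_tiny,
    "composition": _fixture_composition,
    "intrasample": _fixture_intrasample,
    "rs_panel": None,  # handled specially: named panel genes
}


def make_fixture(name: str, out_dir: str | Path) -> dict[str, Path]:
    """Write a seeded fixture (counts TSV, GTF, lengths TSV, labels TSV).

    ``tiny`` is an 8-gene x 4-sample hand-checkable matrix; ``composition``
    carries 5% of genes 20-fold up in the last sample; ``intrasample`` is a
    small version of the reference scenario; ``rs_panel`` contains the 7
    recurrence-score genes plus fillers.
    """
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; valid: {sorted(FIXTURES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if name == "rs_panel":
        cfg = SimConfig(n_genes=12, n_samples=6, library_size_range=(5e4, 1e5), seed=404)
        counts, lengths, truth = simulate_counts(cfg)
        panel = ["BGN", "FAP", "INHBA", "MKI67", "MYC", "MYBL2", "GADD45B"]
        new_ids = panel + [f"FILLER{i}" for i in range(1, cfg.n_genes - len(panel) + 1)]
        counts.index = new_ids
        lengths.index = new_ids
        truth.groups.index = counts.columns
    else:
        cfg = FIXTURES[name]()
        counts, lengths, truth = simulate_counts(cfg)
    paths = {
        "counts": out_dir / f"{name}.counts.tsv",
        "gtf": out_dir / f"{name}.annotation.gtf",
        "lengths": out_dir / f"{name}.lengths.tsv",
        "labels": out_dir / f"{name}.labels.tsv",
    }
    counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    write_gtf(lengths, paths["gtf"])
    write_gene_lengths(lengths, paths["lengths"])
    truth.groups.rename_axis("sample_id").to_csv(paths["labels"], sep="\t")
    return paths
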