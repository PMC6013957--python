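# Methods

## Normalization model

All methods operate on a genes × samples matrix of nonnegative integer
read counts and differ in the per-sample scaling constant and in whether
counts are first corrected for gene length.

**RPK.** `RPK[g,s] = count[g,s] / (L_g / 1000)` with `L_g` the exonic
length in base pairs. Length correction makes values comparable across
genes within a sample; it changes nothing between samples.

**TPM.** RPK scaled so each column sums to 10⁶:
`TPM[g,s] = RPK[g,s] / Σ_g RPK[g,s] · 10⁶`. Scale-invariant per sample,
but the denominator is the plain column total, so a few dominant genes in
one sample deflate every other gene's value there (composition bias).

**TMM.** A robust estimate of the relative scaling between a sample k and
a reference column r. Over genes positive in both columns,

    M_g = log2((y_gk/N_k)/(y_gr/N_r)),  A_g = ½ log2((y_gk/N_k)(y_gr/N_r)),
    var_g = (N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr),

genes in the extreme 30% of M and 5% of A (rank-based, bounds
`floor(n·trim)+1 … n+1−floor(n·trim)`) are discarded, and
`f_k = 2^(Σ M_g/var_g / Σ 1/var_g)` over the survivors (arithmetic mean if
`weighted=False`). Factors are rescaled to geometric mean 1. The reference
column, when not given, is the one whose library-size-scaled 75th
percentile is closest to the mean of those percentiles; ties break to the
first column in order (so automatic reference selection is not
permutation-invariant under exact ties — pass `ref_sample` when that
matters). Degenerate cases: if no gene is positive in both columns, the
trimmed set is empty, or max|M| < 1e-6 over survivors, the factor is 1.
These choices reproduce the de-facto reference implementation (edgeR's
`calcNormFactors`); the test suite pins factors to edgeR and DESeq2
outputs frozen from direct runs of those packages.

**RLE.** Median-of-ratios size factors: over genes positive in every
sample, `f_s = exp(median_g(log y_gs − mean_s log y_gs))`. Applied by
dividing counts directly. Fractional input is refused (median-of-ratios
conventions expect raw integer counts); TMM accepts fractional values,
which is what makes the GeTMM construction possible.

**GeTMM.** TMM run on the RPK matrix with total RPK as the library size,
then per-million scaling:
`GeTMM[g,s] = RPK[g,s] / (N_s f_s) · 10⁶` with `N_s = Σ_g RPK[g,s]`.
Within a sample GeTMM is a monotone rescaling of RPK (ranks preserved);
across samples the trimmed factor absorbs composition bias. When all
factors are 1 it equals TPM exactly. Only this single code path is
offered (factors estimated on RPK and applied to RPK); estimating factors
on raw counts and applying them to RPK is a different estimator and is
deliberately not implemented.

**log2 policy.** Linear values are log2-transformed with zeros set to the
missing marker (NaN in memory, the token `NA` on disk). Missing values
are excluded pairwise from all downstream statistics.

## Evaluation statistics

- **Z-normalization**: per-gene standardization to mean 0, SD 1 (n−1
  denominator throughout the package). Zero-variance genes become
  all-missing with a warning.
- **RMSE** on standardized data over complete pairs.
- **SNR**: `(mean₁ − mean₂)/√Vp` with pooled variance
  `Vp = [(n₁−1)V₁ + (n₂−1)V₂]/(n₁+n₂−2)`.
- **Correlation suites**: per-gene (one coefficient per gene across
  samples; the intersample benchmark) and per-sample (one coefficient per
  sample across genes; the intrasample benchmark, where gene length bias
  shows up). Spearman uses average ranks; coefficients with fewer than 3
  complete pairs are reported missing together with the usable pair count.
  Correlation p-values are not computed; coefficient sets are compared
  directly.
- **Bland-Altman**: bias = mean difference, 95% limits of agreement =
  bias ± 1.96·SD (normal approximation), one-sample t-test of the
  differences against zero. A zero-variance difference vector with
  nonzero bias reports the smallest positive float as p with a warning.
- **Two-group tests**: pooled-variance Student's t by default (Welch by
  flag), Mann-Whitney U as the nonparametric option, two-sided, with
  Benjamini-Hochberg adjustment (statsmodels) attached per gene; genes
  lacking two observations in a group are flagged untestable and excluded
  from the adjustment.

## Recurrence score

`Rsu = 0.1263·mean(BGN, FAP, INHBA) − 0.3158·mean(MKI67, MYC, MYBL2)
+ 0.3406·GADD45B`, `RS = 44.16·(Rsu + 0.30)` clipped below at zero, no
upper cap. Input defaults to the log2 expression matrix (the CLI
transforms linear input automatically), matching the logarithmic
delta-delta-Cq scale of the qPCR assay the score was designed for; a
`--linear` flag scores linear values as-is. The seven genes are matched
case-insensitively after stripping `.N` version suffixes, with an
optional explicit ID map. Genes are used on their incoming scale without
per-gene rescaling to a fixed range (the commercial assay's 0–15
rescaling is not part of the published formula and is not applied).

## Gene lengths from annotation

GTF coordinates are 1-based end-inclusive; an exon's length is
`end − start + 1`. Default mode `unique_exon_sum`: exon records of a gene
are deduplicated by their `exon_id` attribute (records lacking it fall
back to the (chrom, start, end, strand) tuple) and the distinct exons'
lengths are summed. Under this rule exons that overlap but carry distinct
IDs double-count the shared bases; mode `merged_union` (union of merged
intervals, strand-agnostic) is offered for that case and is never smaller.
Genes present in the count matrix but absent from the annotation raise by
default; a `drop` policy is available.

## Synthetic data generator

The simulator emulates the sampling structure of bulk RNA-seq: gene g has
a base concentration `c_g ~ LogNormal(0, 2)` (natural-log SD 2 spans the
~4 orders of magnitude seen in expression data) and a length drawn
log-uniformly over 0.2–20 kb (so length and abundance are independent by
construction, and length-uncorrected values are confounded by the full
100-fold length range). Reads land on genes proportionally to `c_g · L_g`;
expected counts are `μ[g,s] = lib_s · c_gs L_g / Σ c_gs L_g` with
`lib_s` log-uniform over 0.5–2 million reads (a desk-scale stand-in that
preserves per-gene mean counts of a few hundred), and observed counts are
negative-binomial with variance `μ + φμ²`, `φ = 0.4` by default (the
common-dispersion value recommended for cohorts without replicates);
`φ = 0` falls back to Poisson. Optional modifiers multiply a fraction of
genes by a fold-change in selected samples (composition bias, default
scenario 5% of genes ×20 in the last sample) or shift a fraction of genes
between two half-cohort groups (differential expression). Randomness is
split into one child stream for gene-level draws and one per sample
(SeedSequence spawn keys), so output is bit-reproducible per
(config, seed) and column subsets regenerate stably.

What the generator does **not** emulate: isoform structure and effective
lengths, positional/GC bias, RNA degradation, batch effects, or
correlated gene modules. Tests that pass on it therefore demonstrate the
estimators' algebraic and sampling behavior, not robustness to those
artifacts.

## Test scenarios and noise regimes

Two distinct noise regimes are used deliberately:

- **Ordering claims** (median per-sample Spearman to truth is higher for
  length-corrected methods) are tested at the full default scenario
  (1000 genes, 50 samples, φ = 0.4): the ordering is robust to biological
  noise.
- **Quantitative recovery claims** (scale estimators within 5% of the
  analytic composition inflation; Spearman to truth ≥ 0.99) are tested in
  the Poisson limit (φ = 0), where the analytic expectation is an exact
  oracle up to counting noise. At φ = 0.4 the precision-weighted TMM mean
  is dominated by a few heavy-tailed genes whose realized library share
  wanders 15–20% around the analytic value, and per-sample Spearman
  saturates near 0.93 — a noise floor of the data, not an estimator
  error. The ≥ 0.99 bound additionally uses 10⁷-read libraries because
  rank resolution of low-abundance genes is depth-limited.
- **Depth-scaling invariance** (rescaling one sample's counts leaves its
  TPM/GeTMM/TMM-CPM values unchanged) is an exact identity for TPM and
  for the unweighted TMM estimator, and is asserted at 1e-9 there. The
  default precision weights depend on absolute counts, so the weighted
  factors move by ~1% under a 5× depth change; the weighted path is
  asserted at 2%.

## Numerical and interface choices

- Matrices keep the field's genes × samples orientation. The sklearn-style
  transformers (`fit`/`transform`, `get_params`, trailing-underscore
  fitted attributes) operate on DataFrames in that orientation rather than
  sklearn's samples × features arrays.
- Column quantiles use linear interpolation (R type 7), matching the
  reference TMM implementation's upper-quartile reference selection.
- Expression files serialize missing values as the literal token `NA` and
  carry `method`/`scale` tags in a leading `#` comment line so matrices
  round-trip losslessly (values at full float precision).
- The CLI writes data only to `--out`/`--out-dir` files and logs to
  stderr; every run emits a `<out>.manifest.json` with the command line,
  SHA-256 input checksums, seed and version.
- Plotting helpers are intentionally not included; all figures the
  statistics support can be drawn from the emitted TSVs.

## Known limitations

- Transcript-isoform quantification and effective-length models are out
  of scope; lengths are exonic sums per gene.
- The recurrence-score input scale (log2 default) is a documented
  convention, not a published prescription; results on linear input
  differ.
- Automatic TMM reference selection is order-dependent under exact
  upper-quartile ties.
- The unique-exon-sum length rule double-counts bases shared by
  overlapping exons with distinct IDs; use `merged_union` when annotation
  contains many such exons.
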