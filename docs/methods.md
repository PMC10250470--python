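# Methods

This note documents the models and procedures `trapdecon` implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic data does and does not emulate, and the numerical conventions that
matter for reproducing results exactly.

## Contamination model

**Setting.** TRAP-seq purifies the translatome of one cell type; each sample
carries an unknown admixture of background mRNA from other cell types. The
model assumes (i) a panel of *negative marker* genes exists whose true
expression in the target cell type is zero, so their measured signal is
entirely background; and (ii) a contamination-driven gene's measured
expression scales, in expectation, linearly with the amount of background in
the sample.

**Procedure.** With expression E (FPKM) over samples s:

* per-marker fractions c(g, s) = E(g, s) / max_s′ E(g, s′) ∈ [0, 1]; a marker
  whose maximum is attained in several samples scores 1.0 in each of them
  (the formula is total, no tie-breaking);
* contamination measure C(s) = mean over retained markers of c(g, s).
  Markers entirely absent from the matrix, or with all-zero expression, are
  dropped with a warning and listed in the profile;
* per-gene statistic R(g) = Pearson correlation of E(g, ·) with C across
  samples (Spearman available via `method="spearman"` for robustness to
  single-sample spikes; Pearson is the default because it is the literal
  published procedure);
* scrambled null: each scored gene's values are independently permuted
  between samples and R recomputed; the resulting values are pooled across
  genes into an empirical null. The default is one scramble per gene
  (`n_scrambles=1`), matching the single scrambled dataset of the original
  procedure; raising it smooths the null at linear cost;
* Z(g) = (R(g) − null mean) / null sd, with the null sd computed as the
  sample standard deviation (ddof = 1);
* exclusion: Z > `z_threshold` (default 2), strict and one-sided.
  Contamination can only inflate *positive* correlation with C, so strongly
  negative Z is left alone. A gene with Z exactly 2 is retained.

**Reproducibility contract.** The permutation stream is part of the public
interface: one `numpy.random.default_rng(seed)`, scored genes visited in
matrix row order, degenerate genes skipped (they consume no draws),
`n_scrambles` consecutive `rng.permutation(n_samples)` calls per gene. An
independent implementation following this contract reproduces the null — and
hence Z — bit for bit; the test suite and the acceptance script hold the
package to that at 1e-12.

**Degenerate cases.** A gene with zero variance across samples has no defined
correlation: it is flagged `degenerate`, given R = 0 and Z = NaN, and is
never excluded (silently dropping such genes would change the DE universe).
A constant C, a null with zero spread, an empty marker panel, or fewer than
3 samples are hard errors — each of these means the contamination signal is
undefined rather than merely weak.

**Markers.** Marker genes are never scored ("every other gene") and are
retained in the filtered matrix but listed in the filter report; the pipeline
can drop them before DE via `drop_markers_before_de`. The marker panel is a
required input: the package ships no default panel because marker validity is
a biological claim about the tissue at hand, not a software constant.

**What the Z filter does not do.** It does not estimate the absolute
contamination percentage, deconvolve mixtures, or regress out contamination;
genes are either kept or excluded.

## Null calibration: what to expect

Z thresholds the gene's R against the mean ± sd of a *pooled empirical* null.
When C is well-behaved the null is roughly Gaussian and the expected
no-contamination exclusion rate at Z > 2 is near the Gaussian tail (~2.3%);
measured over seeded replicates the mean is ~2%. But the null given an
awkward C shape (e.g. one sample dominating every marker) is visibly
non-Gaussian, and mean + 2 sd of a heavy-tailed distribution can capture
more than the nominal tail: individual no-contamination replicates
occasionally exclude 6–9% of genes. This is a property of the published
procedure itself, not of this implementation; raising `n_scrambles` smooths
the null but does not change its shape. Analyses for which the exclusion
budget matters should inspect the run report's null mean/sd and the score
distribution.

## Normalizations

* FPKM: value(g, s) = counts(g, s) × 10⁹ / (length(g) × libsize(s)). When
  library sizes are not supplied, each sample's column sum of counts is used,
  which makes the conversion self-contained and gives the exact mass balance
  Σ_g FPKM(g, s)·length(g)/10⁹·libsize(s) = column total. Supplied mapped-read
  totals override the default and are treated as opaque.
* Proteomics: each protein's intensity divided by the summed intensity of all
  proteins in its sample; columns sum to 1; idempotent by construction. An
  all-zero sample is an error.
* log2 fold change on group means, computed as log2(mean_a + ε) −
  log2(mean_b + ε) (difference of logs, so swapping groups negates values to
  the bit). The pseudocount ε defaults to 0 with a loud error on zero means:
  fold changes are normally computed on floor-passing genes where zeros do
  not arise, and a silent pseudocount would change results invisibly.

## Statistics

* **Ratio paired t-test**: a one-sample two-sided t-test of log(a_i/b_i)
  against 0; t = mean/(sd/√n), df = n − 1. Natural log internally; the
  statistic is invariant to the log base since base change rescales mean and
  sd identically. Nonpositive values are errors (a ratio test needs positive
  measurements); zero variance of the log-ratios is a degenerate-data error.
* **BH adjustment** delegates to `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`); tests verify exact agreement with a brute-force step-up
  implementation up to length 10⁴.
* **Differential expression** is an explicitly labelled stand-in, not a
  negative-binomial GLM: per-gene Welch t on log2(FPKM + pseudocount),
  BH across testable genes, calls `up`/`down` when |log2FC| ≥ log2(1.3)
  (inclusive) and q < 0.05 (strict). Default pseudocount 1.0 on the FPKM
  scale. Genes with zero variance in both groups get NaN p/q and call `ns`.
  The fold/q thresholds and the >5-FPKM expression floor (strict) are the
  conventions of the emulated analysis; the per-gene test is interchangeable
  plumbing around them.
* **Gene-set summaries**: per-member log2 fold change on group means, the
  panel mean over found members only, missing members always listed, and a
  ratio paired t-test pairing each found gene's group-A mean with its group-B
  mean. Panels with fewer than two found members, or identical group means,
  carry no t-test (with a warning) rather than a degenerate one.

### Power of the stand-in at small n

With 3 replicates per group the per-gene Welch test has df ≈ 4; after BH
across ~2000 genes its genome-wide power is essentially zero (measured: ~0.1
discoveries per replicate at 10% planted 2-fold effects). The published
analyses obtain power at n = 3 from DESeq2's shared-variance NB model, which
is deliberately out of scope here. The package's calibration experiments
(FDR control, filter utility) therefore use 6 replicates per condition —
enough for ~94% power at 2-fold effects — while the contamination-recovery
and null-calibration experiments keep the emulated design of 3 replicates ×
4 conditions × 2000 genes.

## Imaging metrics

Channels are binarized by strict `value > threshold`, with per-channel Otsu
as the default (reproducible without hand-picked constants) or fixed
thresholds in native intensity units; the thresholds used are recorded in the
result. The remyelination index is |myelin ∧ axon| / |axon|: normalizing the
colocalized volume to the axon channel makes the index robust to axonal
density differences, and it is 1.0 when the myelin mask covers every axon
voxel. Voxel counts are additive, so per-plane indices pooled by summing
counts equal the whole-volume index exactly. No filtering or background
subtraction is applied by default; a 3-voxel median filter sits behind a
flag. An empty axon mask (index undefined) and shape mismatches are errors.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
transcriptome realism:

* design: 3 replicates × (control, 3dpi, 7dpi, 10dpi); per-sample
  contamination fraction f_s = Beta(2, 5) draw × a per-condition weight
  (defaults 0.5 / 1.5 / 1.0 / 0.75), reflecting that background mRNA load
  tracks lesion state and peaks at demyelination. Condition-dependent
  contamination is what makes contamination confound DE — with iid
  contamination the filter would have nothing downstream to rescue;
* gene classes (disjoint, recorded in the truth object): 6 negative markers
  and 100 contaminant-driven genes with expected expression
  baseline(g) × (0.05 + 3·f_s) — the 0.05 leak floor models imperfect
  cell-type specificity and keeps markers measurable when the contamination
  scale is set to 0; 200 condition-responsive genes shifted ±1 log2 unit in
  all lesion conditions; the rest clean baseline;
* baselines log-normal (median 10 FPKM, sd 0.6 dex); mean-one log-normal
  multiplicative noise (σ = 0.2); counts Poisson around the FPKM-implied mean
  given uniform gene lengths (0.5–5 kb) and library sizes (15–25 M reads).
  Log-normal × Poisson already yields overdispersed counts; a
  gamma-Poisson (NB) option exists in the config;
* random streams split per purpose (structure / contamination / noise /
  counts) from one seed, so changing one field does not reshuffle unrelated
  draws; identical config + seed is bit-identical.

Not emulated: realistic gene-length/expression covariation, isoforms,
batch effects, sample-to-sample library-preparation artefacts, nonlinear
contamination (e.g. saturation), and correlated marker panels. Passing the
recovery tests therefore shows the procedure works when its own linearity
assumption holds — the same assumption the R statistic encodes — not that
real contamination is linear.

The two-channel volume generator plants a Bernoulli axon mask
(density 0.1), a conditional myelin overlap, a small off-axon false-positive
rate (0.005), and Gaussian intensity noise around levels 30/200, giving a
known ground-truth index against which recovery is asserted at ±0.02 on
128³ voxels.

## Pipeline

Stage order is fixed: (counts → FPKM) → contamination profile → gene scores →
Z filter → expression floor → DE per contrast → gene-set summaries. The
filter runs *before* DE — excluded genes never enter testing or BH — which is
the conservative reading of a procedure whose published description does not
pin the order. Contrast labels are validated against the sample metadata
before any computation. The run report echoes the config, the seeds, and
per-stage gene counts, and its internal consistency (input = excluded +
retained, floor ≤ DE universe ≤ retained) is asserted on every run.

## Known limitations

* C is a *relative* measure: each marker is normalized to its own maximum,
  so C ranks samples within a dataset but is not comparable across datasets.
* With few samples (the method operates on as few as 3–12), chance
  correlation between contamination and condition is common; condition-
  responsive genes can then be excluded as contamination-like. This is
  inherent to the correlation statistic, visible in the synthetic recovery
  experiments, and is the price of a filter that needs no reference profiles.
* The DE stage is a stand-in by design; its numbers are not comparable to
  NB-GLM results at small n (see the power note above).
* The scrambled null's Z > 2 tail is only approximately 2% (see the
  calibration section).
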