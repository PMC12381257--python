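# Methods

This note documents the models, parameter choices and numerical conventions
behind clonescope, and what the synthetic validation does and does not show.

## Synthetic cohort model

Counts for cell *c*, gene *g* are negative binomial with mean

    μ_cg = ℓ_c · λ_g · dosage_{clone(c),g} · fold_{type(c),g}

and shared dispersion θ (`nb_dispersion`, NB variance μ + μ²/θ). Components:

- **Gene baselines** λ_g ~ LogNormal(`baseline_log_mean` = 1.5,
  `baseline_log_sd` = 1.5). The simulated genome is compact (720 genes in the
  default cohort), so it stands for the *expressed* panel of a real cell:
  per-gene depth matches the top-expressed fraction of a cell with a few
  thousand UMIs, and baselines span orders of magnitude as real
  transcriptomes do.
- **Library size** ℓ_c ~ LogNormal(0, 0.25).
- **Dispersion** θ = 10, i.e. a biological-coefficient-of-variation of
  ~0.32, in the range standard scRNA simulators fit to 10x data. (Much
  smaller θ imposes a per-gene CV floor above 70%, which no amount of depth
  can overcome; that is noisier than observed data.)
- **Clones.** Each malignant cell draws a clone from per-condition
  prevalence weights; a clone's segments multiply μ by `copy_ratio`
  (1 neutral, 1.5 single-copy gain on diploid, 0.5 single-copy loss).
  Segments are 0-based inclusive gene-index intervals per chromosome and may
  not overlap within a clone. Default clones carry 3–4 segments including
  losses, matching the multi-arm alteration load of real tumors.
- **Lineages.** Each cell type boosts a disjoint random marker set
  (default 30–60 genes) by `marker_fold` (default 3).
- **Mitochondrial genes.** A flagged random subset (3%) with a 4× expression
  boost (MT transcripts are abundant); they carry no CNV dosage and feed the
  QC mito fraction.
- **Determinism.** One RNG stream per patient is keyed as
  `(seed, 1000 + patient_index)`, so adding patients never perturbs earlier
  patients' data; a gene-level stream `(seed, 0)` draws baselines, marker
  assignments and mito flags. Identical config + seed reproduces outputs
  byte for byte.

`make_null_config` averages clone weights, cell-type proportions and
malignant fractions across conditions, making condition labels exchangeable:
the planted `differential_regions` list is empty and every downstream test
statistic is null-distributed.

**What the simulator does not emulate:** doublets, ambient RNA, batch/sample
integration effects, per-gene dispersion variation, transcriptional bursting
and cell-cycle structure, allele-specific signal, and per-site (liver/bone)
metastatic differences — condition is a binary label. Passing validation
here shows the estimators are correct under the stated generative model, not
that they are robust to every artifact of real data.

## QC and normalization

Cells are kept iff mito fraction ≤ 0.20 AND total UMIs in [400, 100000] AND
detected genes in [200, 10000]; all bounds inclusive, computed on raw
counts, with per-criterion exclusion counts reported. An external exclusion
list (e.g. doublet calls) can be ANDed in via `apply_exclusions`; doublet
detection itself is out of scope. Normalization scales each cell to
`target_sum` (default 10,000 — the common convention) and applies log1p.

## CNV inference

Pipeline order: drop genes with mean normalized expression < 0.1 or without
positions → subtract per-gene reference means (T cells by default) → sort
genes by (chromosome, start; chromosomes lexicographic) → per cell and
chromosome, centered moving average of width `window_genes` (default 101,
the external tool's convention; the window shrinks symmetrically at
chromosome ends, half-width min(w//2, i, n−1−i)) → subtract the smoothed
reference average → clamp to ±1 → subtract the per-cell median. Benchmarks
on the compact synthetic genomes use window 21 so that a window does not
span a sixth of a chromosome.

Numerical notes: smoothing uses cumulative sums and is verified elementwise
(≤1e-10) against a direct-summation oracle; the reference-cell mean profile
is 0 to 1e-8 before clamping by construction. Because the spec'd order
clamps *before* the median recentring, profile values can exceed the clamp
by up to the median magnitude; in practice medians are near 0.

Per-cell median recentring also absorbs the library-composition artifact of
CNVs: a large gain inflates a cell's total counts, and total-count
normalization then depresses every other gene by a roughly constant
log-shift.

**CNV burden** is the mean of squared profile values — the deviation energy
from copy-neutrality. The upstream publication defers its score formula to
methods that do not state one; mean-of-squares is this package's documented
choice (flagged in output metadata).

## Malignant calling

Candidates (epithelial, never reference cells) are embedded in two
features: burden score and Pearson correlation with the mean profile of the
top-decile-burden candidates (the putative tumor consensus). A 2-means
split on standardized features defines the groups; the higher-burden group
is malignant. Separation must clear silhouette ≥ 0.25 **and** exceed the
95th percentile of silhouettes obtained by 2-means on standard-normal data
of the same size plus 0.1. The second check matters: a 2-means split of
pure 2-D noise reaches silhouette ≈ 0.30–0.34, so an absolute cutoff alone
cannot recognize a CNV-free cohort. On planted cohorts the observed
silhouette is ≈ 0.75; on null cohorts ≈ 0.32 against a reference cut of
≈ 0.43, so calls collapse to all-normal exactly when they should.

## Subclones

Ward-linkage agglomerative clustering on Euclidean profile distances;
k ∈ 2..k_max (default 6) chosen by maximum mean silhouette, with k = 1
declared when the best silhouette is below 0.25. Unlike the 2-D calling
features, profile space is high-dimensional and noise silhouettes stay
low, so the absolute cutoff suffices here (50/50 single-clone cohorts
select k = 1).

## Heterogeneity (ITHGEX)

On the top `n_hvg` (default 2000, i.e. all genes of the compact simulated
genomes) most variable genes among a tumor's malignant cells, each cell
vector is centered across genes (u_i = x_i − mean(x_i)) and

    ITHGEX = mean_i ‖u_i − c‖² / mean_i ‖u_i‖²,   c = mean_i u_i

— the fraction of cell-level variation not captured by the tumor's mean
malignant profile. It is 0 for identical cells, bounded by 1 (within the
nominal [0, 2] interval of correlation-based scores), and strictly
increasing in between-clone divergence whenever structured expression
variance exceeds noise. Two simpler forms were evaluated and rejected on
planted cohorts: 1 − corr(cell, centroid) *decreases* with divergence
because the centroid contains each cell's own clone, and mean pairwise
1 − corr cancels for balanced clones. The published heterogeneity score is
defined in an external reference; this form is an interpretation and is
flagged as such in output metadata. Divergence ladders used in validation
pair each gain (1 + ℓ) with a reciprocal loss 1/(1 + ℓ) so that planted
divergence is not confounded with library-size artifacts.

## Region permutation test

Genes are partitioned into consecutive fixed-size windows per chromosome
(default 25 genes; trailing windows may be shorter). Gap-based splitting
was considered and not implemented — the grouping granularity is the
window-size knob. Per window, a cell's region-CNV is its mean profile over
member genes; the observed statistic is |mean(condition A) − mean(B)| over
malignant cells. The null shuffles condition labels over cells (or over
patients, `permutation_unit="patient"`, for cohorts where within-patient
correlation matters; cell-level is the default to mirror the cited tools).
p = (1 + #{T* ≥ T}) / (1 + n_perm) with n_perm = 10,000 by default, so p is
never 0 and has resolution 1/(n_perm+1). Raw p < 0.05 defines significance
(mirroring the source convention); BH q values are reported alongside.

Because the smoother spreads signal ±(w−1)/2 genes, windows adjacent to a
true segment carry genuine leaked signal; in power analyses they are
excluded from the "clean null" side, and rankings are by (p ascending,
statistic descending) since many true windows sit at the p floor.

Cross-cohort overlap of significant windows is reported as
|sig(A) ∩ sig(B)| / |sig(A)| by default (the denominator convention is
ambiguous in the source; Jaccard is available), as a percent with two
decimals. Arm-level summaries rank arms by |between-group mean difference|
and return the top 25 by default.

## Signatures

- **Markers:** one-vs-rest Welch t (default) or Wilcoxon rank-sum per gene,
  log2 fold change on the expm1 scale with a 1e-9 floor, BH within group;
  deterministic ordering (p, then effect, then gene id).
- **Derivation:** top-N (default 200) by that ordering, restricted to the
  requested direction; insufficient genes raise an error stating the count.
- **Recovery-AUC:** genes ranked per cell by decreasing expression, ties
  broken by a per-cell seeded shuffle; the score is the area under the
  cumulative hit curve within the top ⌈0.05·G⌉ ranks, normalized so a set
  occupying the very top ranks scores 1.
- **Weighted activity:** per cell, the t-statistic of the slope of
  expression ~ weight across all genes (weight 0 outside the set), computed
  in closed form from the correlation; r² is capped at 1 − 1e-15 so
  perfect fits give large finite values.
- **Classification:** argmax per cell with column-order tie-break, margin,
  and tie flag. The pipeline standardizes each signature's scores across
  cells first: derived top-N sets differ in how many constitutively
  high-expression genes they contain, which shifts raw AUC baselines per
  signature and can let one set dominate every cell. The mean-scaled
  expression scorer (`mean_scaled_score`) is the documented alternative
  when the AUC path is disabled; the cited classifier's internals are not
  public, so both scorers are labeled as this package's own forms.
- **Pseudobulk:** counts summed per sample, log2-CPM(+1), Welch t across
  samples per gene, BH; ≥ 2 samples per condition required. Ordering: q,
  then |log2FC|, then gene id.
- **State coordinates:** raw score pairs for 2 signatures, (A−B, C−D) for 4.

## Composition test

log2FC of per-type proportions with a one-cell pseudocount for empty types
(flagged in output), computed as a difference of logs so swapping
conditions negates it exactly. Two-sided permutation p on |log2FC| over
cell labels (patient-level permutation available but off by default, to
mirror the cited tool); 95% percentile bootstrap CI from resampling cells
with replacement within condition (multinomial over observed type
frequencies, which is equivalent); significance = p < alpha AND |log2FC| >
threshold (default 2) on the point estimate, with the CI reported so users
can apply a CI-bound rule instead.

## Pipeline

TOML-configured stages (simulate/load → qc → cnv → regions → signatures →
composition); one master seed derives per-stage seeds through a seeded
generator; each stage reads prior outputs from the working directory, so
any stage reruns standalone with identical results; the manifest records a
sha256 per output file and contains no timestamps, making reruns
hash-identical. The CLI (`clonescope`) is a thin wrapper over these stage
functions.

## Validation scales

Benchmarks simulate cohorts of roughly 300–2,400 cells over 480–2,000
genes: calibration uses 20 null cohorts × ~200 windows × 2,000
permutations; power uses ~450 malignant cells per condition with 40-gene
planted segments; calling uses ~200 malignant vs ~200 normal epithelial
cells; coverage uses 200 cohorts × 500 bootstrap draws. These sizes give
tight Monte-Carlo intervals for the properties tested while keeping the
full suite fast on a single CPU.

## Known limitations

- No HMM segmentation, no allele/BAF integration; profiles are smoothed
  log-ratios only, so focal events smaller than the window blur.
- Expression-based CNV inference assumes dosage acts multiplicatively on
  expression; compensated genes violate this.
- The ITHGEX and CNV-burden formulas are documented interpretations of
  scores whose exact published forms are unavailable.
- The region test treats windows independently; spatial correlation from
  smoothing is handled by design (buffer zones) rather than modeled.
- Binary conditions only; no per-site metastatic structure.
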