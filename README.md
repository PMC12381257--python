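# clonescope

Comparative single-cell copy-number and signature analysis for two-condition
tumor cohorts (e.g. primary vs. metastatic breast cancer), built around a
seeded synthetic-cohort generator with planted ground truth.

Single-cell RNA-seq of matched tumor cohorts raises a chain of questions this
package answers end to end: which epithelial cells are malignant, what clonal
copy-number structure they carry, how transcriptionally heterogeneous each
tumor is, which genomic regions differ between conditions, which expression
programs distinguish the conditions, and which cell types shift in abundance.
It is aimed at computational biologists who want these stages as a tested,
reproducible Python library rather than a collection of ad hoc notebooks.

## What it computes

**CNV profiles from expression.** For cell *i* and genomically ordered gene
*g*, the profile is a centered moving average of reference-centered
log-expression:

    c_ig = clamp( MA_w( x_ig − x̄_g^ref ) − MA_w(ref avg) , ±1 ) − median_g(c_ig)

with window *w* = 101 genes by default (shrinking symmetrically at chromosome
ends) and T cells as the copy-neutral reference. The per-cell **CNV burden**
is the mean of squared profile values, `score_i = mean_g c_ig²`.

**Malignant calling.** Epithelial candidates are split by 2-means on
(burden, correlation with the top-decile mean profile); the split must beat
both an absolute silhouette cutoff and a Gaussian-reference noise
calibration, otherwise everything is called normal.

**Subclones and heterogeneity.** Ward clustering on profiles with
silhouette-based model selection; the heterogeneity score ITHGEX is the
fraction of malignant-cell expression variation not explained by the tumor's
mean malignant profile, `mean_i ‖u_i − c‖² / mean_i ‖u_i‖²` on highly
variable genes.

**Region permutation test.** Genes are grouped into consecutive windows;
per window the statistic is `T = |mean CNV(condition A) − mean CNV(B)|`
over malignant cells, with a label-permutation null and
`p = (1 + #{T* ≥ T}) / (1 + n_perm)` (10,000 permutations by default),
BH-adjusted q alongside, plus cross-cohort overlap of significant windows
and top-25 arm-level summaries.

**Signatures.** One-vs-rest marker tests (Welch t or rank-sum, BH), top-200
upregulated genes per group as signatures, per-cell recovery-curve AUC
scoring within the top 5% of each cell's expression ranking (seeded tie
break), univariate-linear-model activities (t-statistic of expression ~
weight) for weighted sets, argmax classification with optional per-signature
standardization, pseudobulk differential expression on log2-CPM, and 2-/4-axis
cellular-state coordinates.

**Composition.** Per cell type, `log2FC = log2(p_A / p_B)` of proportions
(pseudocount of one cell for empty types), permutation p on |log2FC|,
95% bootstrap CI, and the joint significance rule p < 0.05 AND |log2FC| > 2.

**Synthetic cohorts.** Negative-binomial counts with per-patient RNG
streams; clone-specific segments act multiplicatively on expected
expression; lineage marker programs, mitochondrial flags, library-size
variation, and condition-dependent composition are all planted and recorded
in a `Truth` object.

## Worked example

`examples/02_qc_and_cnv_calling.py` simulates an epithelial compartment in
which half the cells carry a three-segment clone, QC-filters, infers CNV
against the T-cell reference and calls malignant cells:

```
QC: kept 580/580 cells; exclusions: {'mito_fraction': 0, 'umi_below_min': 0,
    'umi_above_max': 0, 'genes_below_min': 0, 'genes_above_max': 0}

CNV burden (mean of squared log-ratios): malignant 0.0431,
    normal epithelial 0.0197, T-cell reference 0.0153
malignant calling accuracy vs truth: 99.8% (413 candidate epithelial cells)
```

All 580 simulated cells pass the standard QC gates; malignant cells carry
roughly twice the CNV burden of copy-neutral cells (whose residual burden is
smoothing noise), and the two-feature split recovers the planted labels for
412 of 413 candidates. The other scripts in `examples/` walk through cohort
simulation, subclones and heterogeneity, the window permutation test,
signature classification, composition testing, and the config-driven
pipeline (also available as the `clonescope` command-line tool).

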