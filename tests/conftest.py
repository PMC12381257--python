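import numpy as np
import pandas as pd
import pytest
import anndata as ad

from clonescope import cnv, io as csio, simulate as cssim


def brute_force_cnv_oracle(expr, reference_mask, params):
    """Direct-summation re-implementation of the CNV profile pipeline.

    Every step is written as explicit loops / naive sums, independent of the
    cumulative-sum path used by the package. Returns (values, genes,
    ref_mean_pre_clamp) where the last is the per-gene mean over reference
    cells just before clamping (expected ~0).
    """
    import scipy.sparse as sp

    X = expr.X.toarray() if sp.issparse(expr.X) else np.asarray(expr.X, float)
    var = expr.var
    has_pos = var["chromosome"].notna().to_numpy() & var["start"].notna().to_numpy()
    mean_norm = np.expm1(X).mean(axis=0)
    keep = has_pos & (mean_norm >= params.min_mean_expression)
    X = X[:, keep]
    genes = var.loc[keep, ["chromosome", "start"]].copy()
    ref = np.asarray(reference_mask, bool)
    X = X - X[ref].mean(axis=0, keepdims=True)
    order = np.lexsort((genes["start"].to_numpy(), genes["chromosome"].to_numpy()))
    X = X[:, order]
    genes = genes.iloc[order]
    chroms = genes["chromosome"].to_numpy()
    half = params.window_genes // 2
    sm = np.empty_like(X)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n = len(idx)
        for j, gi in enumerate(idx):
            h = min(half, j, n - 1 - j)
            window = idx[j - h : j + h + 1]
            for c in range(X.shape[0]):
                sm[c, gi] = sum(X[c, g] for g in window) / len(window)
    ref_avg = sm[ref].mean(axis=0)
    sm = sm - ref_avg[None, :]
    ref_mean_pre_clamp = sm[ref].mean(axis=0)
    sm = np.clip(sm, -params.clamp, params.clamp)
    sm = sm - np.median(sm, axis=1, keepdims=True)
    return sm, genes, ref_mean_pre_clamp


def make_expr_adata(X, chromosomes=None, starts=None, cell_ids=None, gene_ids=None):
    """Wrap a dense matrix as a log-expression AnnData with gene positions."""
    X = np.asarray(X, float)
    n, g = X.shape
    gene_ids = gene_ids or [f"g{i:04d}" for i in range(g)]
    var = pd.DataFrame(
        {
            "chromosome": chromosomes if chromosomes is not None else ["chr1"] * g,
            "start": starts if starts is not None else np.arange(g) * 1000,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    obs = pd.DataFrame(index=pd.Index(cell_ids or [f"c{i:04d}" for i in range(n)], name="cell_id"))
    return ad.AnnData(X=X, obs=obs, var=var)


def analyzed_cohort(config, window_genes=21):
    """simulate -> normalize -> CNV profiles, as the benchmarks use them."""
    adata, truth = cssim.simulate_cohort(config)
    expr = csio.normalize_log(adata)
    ref = (expr.obs["cell_type"] == "T cells").to_numpy()
    P = cnv.infer_cnv_profiles(expr, ref, cnv.CNVParams(window_genes=window_genes))
    return adata, expr, truth, P


def planted_window_masks(P, segments, regions, buffer_genes):
    """Boolean masks (planted, buffer) over region rows.

    A region is planted when it overlaps a segment; it is buffer when it
    lies within ``buffer_genes`` of one (the moving average leaks real
    signal that far), so only regions outside the buffer are clean nulls.
    """
    g = P.genes.reset_index()
    g["within"] = g.groupby("chromosome").cumcount()
    planted = np.zeros(len(g), bool)
    buffered = np.zeros(len(g), bool)
    for s in segments:
        on = (g["chromosome"] == s.chromosome).to_numpy()
        w = g["within"].to_numpy()
        planted |= on & (w >= s.start_gene_index) & (w <= s.end_gene_index)
        buffered |= on & (w >= s.start_gene_index - buffer_genes) & (
            w <= s.end_gene_index + buffer_genes
        )
    reg_planted = np.array(
        [planted[r.start_idx : r.end_idx].any() for r in regions.itertuples()]
    )
    reg_buffer = np.array(
        [buffered[r.start_idx : r.end_idx].any() for r in regions.itertuples()]
    )
    return reg_planted, reg_buffer


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-shaped cohort reused across read-only tests."""
    cfg = cssim.default_config(seed=3)
    cfg.n_patients_per_condition = 2
    cfg.cells_per_patient = 150
    adata, truth = cssim.simulate_cohort(cfg)
    return cfg, adata, truth
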