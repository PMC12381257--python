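"""Expression-based copy-number inference and downstream tumor analyses.

Profiles are inferred by centering each gene on its mean in a reference
lineage (T cells by default), smoothing along genomic order with a centered
moving average per chromosome, clamping, and recentring each cell on its
median — the standard expression-CNV heuristic. On top of the profiles this
module provides a per-cell CNV burden score, malignant-cell calling,
subclone detection, an intratumoral-heterogeneity score, proximity-grouped
permutation testing of gene windows between conditions, cross-cohort overlap
of significant windows, and arm-level summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad
from sklearn.cluster import KMeans, AgglomerativeClustering
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CNVParams:
    """Parameters of the profile-inference pipeline.

    min_mean_expression: gene inclusion cutoff on the normalized-count scale
        (mean of expm1 of the log-normalized values).
    window_genes: odd width of the centered moving average; the window
        shrinks symmetrically at chromosome ends.
    clamp: profiles are clamped to +/- this value before median recentring.
    reference_label: lineage used as the copy-neutral reference.
    """

    min_mean_expression: float = 0.1
    window_genes: int = 101
    clamp: float = 1.0
    reference_label: str = "T cells"

    def validate(self) -> None:
        if self.window_genes < 1 or self.window_genes % 2 == 0:
            raise ValueError("window_genes must be an odd positive integer")
        if self.clamp <= 0:
            raise ValueError("clamp must be positive")


@dataclass
class CNVProfileMatrix:
    """Smoothed log-ratio CNV estimates, cells x genes in genomic order."""

    values: np.ndarray
    genes: pd.DataFrame  # index: gene id; columns: chromosome, start
    cell_ids: pd.Index
    is_reference: np.ndarray
    params: CNVParams = field(default_factory=CNVParams)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class RegionTestParams:
    n_perm: int = 10_000
    alpha: float = 0.05
    permutation_unit: str = "cell"  # or "patient"
    seed: int = 0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.permutation_unit not in ("cell", "patient"):
            raise ValueError("permutation_unit must be 'cell' or 'patient'")


def moving_average_smooth(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with symmetric edge shrinkage.

    At position i the half-width is min(window // 2, i, n-1-i), so the
    window stays centered and shrinks near the edges. Implemented with
    cumulative sums; a brute-force direct-summation version lives in the
    test suite as an independent oracle.
    """
    n = X.shape[1]
    half = window // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h
    cs = np.concatenate(
        [np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1
    )
    return (cs[:, hi + 1] - cs[:, lo]) / (hi - lo + 1)


def infer_cnv_profiles(
    expr: ad.AnnData,
    reference_mask: np.ndarray,
    params: CNVParams | None = None,
) -> CNVProfileMatrix:
    """Infer per-cell CNV profiles from log-normalized expression.

    Pipeline: drop genes with mean normalized expression below the cutoff or
    without positions; subtract per-gene reference means; sort genes by
    (chromosome, start); smooth each cell chromosome-wise with the centered
    moving average; subtract the smoothed reference average; clamp to
    +/- params.clamp; subtract each cell's median. Reference cells are
    processed identically and flagged in the output.
    """
    p = params or CNVParams()
    p.validate()
    reference_mask = np.asarray(reference_mask, bool)
    if reference_mask.sum() < 30:
        raise ValueError(
            f"need >= 30 reference cells, got {int(reference_mask.sum())}"
        )
    var = expr.var
    if "chromosome" not in var or "start" not in var:
        raise ValueError("expr.var must carry 'chromosome' and 'start' gene positions")
    has_pos = var["chromosome"].notna().to_numpy() & var["start"].notna().to_numpy()
    if has_pos.mean() < 0.5:
        raise ValueError("gene positions available for fewer than 50% of genes")

    X = expr.X.toarray() if sp.issparse(expr.X) else np.asarray(expr.X, float)
    mean_norm = np.expm1(X).mean(axis=0)
    keep = has_pos & (mean_norm >= p.min_mean_expression)
    if not keep.any():
        raise ValueError("no genes pass the expression/position filters")
    X = X[:, keep]
    genes = var.loc[keep, ["chromosome", "start"]].copy()

    X = X - X[reference_mask].mean(axis=0, keepdims=True)

    order = np.lexsort((genes["start"].to_numpy(), genes["chromosome"].to_numpy()))
    X = X[:, order]
    genes = genes.iloc[order]

    chroms = genes["chromosome"].to_numpy()
    smoothed = np.empty_like(X)
    start = 0
    for chrom in pd.unique(chroms):
        end = start + int((chroms == chrom).sum())
        smoothed[:, start:end] = moving_average_smooth(X[:, start:end], p.window_genes)
        start = end

    ref_avg = smoothed[reference_mask].mean(axis=0, keepdims=True)
    smoothed = smoothed - ref_avg
    smoothed = np.clip(smoothed, -p.clamp, p.clamp)
    smoothed = smoothed - np.median(smoothed, axis=1, keepdims=True)

    return CNVProfileMatrix(
        values=smoothed,
        genes=genes,
        cell_ids=expr.obs_names.copy(),
        is_reference=reference_mask.copy(),
        params=p,
    )


def cnv_score(P: CNVProfileMatrix) -> np.ndarray:
    """Per-cell CNV burden: mean of squared profile values (>= 0).

    This is a documented interpretation — the quantity summarizes how far a
    cell's inferred profile deviates from copy-neutral.
    """
    return np.mean(P.values**2, axis=1)


def call_malignant(
    P: CNVProfileMatrix,
    scores: np.ndarray,
    candidate_mask: np.ndarray,
    min_silhouette: float = 0.25,
    seed: int = 0,
) -> np.ndarray:
    """Label candidate (epithelial) cells malignant or normal from CNV evidence.

    Candidates (never reference cells) are embedded in two features: CNV
    score and Pearson correlation with the mean profile of the top-decile
    scoring candidates. A 2-means split on the standardized features defines
    the groups; the group with the higher mean score is malignant. The split
    must be well separated: its silhouette has to clear ``min_silhouette``
    AND the 95th percentile of silhouettes of 2-means splits of structure-
    free Gaussian data of the same size plus a 0.1 margin (a 2-means split
    of pure noise already reaches silhouettes near 0.32, so an absolute
    cutoff alone cannot detect the no-CNV case). Otherwise everything is
    called normal and a warning is logged.
    """
    candidate_mask = np.asarray(candidate_mask, bool) & ~P.is_reference
    n_cand = int(candidate_mask.sum())
    if n_cand < 10:
        raise ValueError(f"need >= 10 candidate cells, got {n_cand}")
    cand_idx = np.flatnonzero(candidate_mask)
    s = scores[cand_idx]
    top = cand_idx[s >= np.quantile(s, 0.9)]
    anchor = P.values[top].mean(axis=0)
    prof = P.values[cand_idx]
    pc = prof - prof.mean(axis=1, keepdims=True)
    ac = anchor - anchor.mean()
    denom = np.linalg.norm(pc, axis=1) * np.linalg.norm(ac)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, pc @ ac / np.maximum(denom, 1e-300), 0.0)
    F = np.column_stack([s, corr])
    F = (F - F.mean(axis=0)) / np.maximum(F.std(axis=0), 1e-12)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(F)
    labels = np.full(P.n_cells, "normal", dtype=object)
    if len(np.unique(km.labels_)) < 2:
        logger.warning("malignant calling: degenerate split; all candidates normal")
        return labels
    sil = silhouette_score(F, km.labels_)
    rng = np.random.default_rng(seed)
    ref_sils = []
    for b in range(30):
        G = rng.standard_normal((n_cand, 2))
        ref_km = KMeans(n_clusters=2, n_init=3, random_state=b).fit(G)
        ref_sils.append(silhouette_score(G, ref_km.labels_))
    noise_cut = float(np.quantile(ref_sils, 0.95)) + 0.1
    if sil < min_silhouette or sil <= noise_cut:
        logger.warning(
            "malignant calling: groups not separated (silhouette %.3f, needs "
            ">= %.2f and > %.3f noise reference); all candidates called normal",
            sil,
            min_silhouette,
            noise_cut,
        )
        return labels
    mal_cluster = int(np.argmax([s[km.labels_ == k].mean() for k in (0, 1)]))
    labels[cand_idx[km.labels_ == mal_cluster]] = "malignant"
    return labels


def detect_subclones(
    P: CNVProfileMatrix,
    malignant_mask: np.ndarray,
    k_max: int = 6,
    min_silhouette: float = 0.25,
) -> np.ndarray:
    """Cluster malignant CNV profiles into subclones.

    Ward-linkage agglomerative clustering on Euclidean profile distances;
    k in 2..k_max is chosen by maximum mean silhouette, with k=1 declared
    when even the best silhouette falls below ``min_silhouette``. Returns
    integer labels for the malignant cells (in mask order).
    """
    malignant_mask = np.asarray(malignant_mask, bool)
    n = int(malignant_mask.sum())
    if n < 20:
        raise ValueError(f"need >= 20 malignant cells, got {n}")
    V = P.values[malignant_mask]
    if np.allclose(V, V[0]):
        return np.zeros(n, int)
    best_k, best_sil, best_labels = 1, -1.0, np.zeros(n, int)
    for k in range(2, min(k_max, n - 1) + 1):
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(V)
        sil = silhouette_score(V, labels)
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if best_sil < min_silhouette:
        return np.zeros(n, int)
    logger.info("detect_subclones: k=%d (silhouette %.3f)", best_k, best_sil)
    return best_labels


def ithgex_score(
    expr: ad.AnnData,
    malignant_mask: np.ndarray,
    n_hvg: int = 2000,
) -> float:
    """Intratumoral heterogeneity of gene expression for one tumor.

    On the top ``n_hvg`` most variable genes among the tumor's malignant
    cells, each cell vector is centered across genes (u_i = x_i - mean(x_i))
    and the score is the fraction of cell-level variation not captured by
    the tumor's mean malignant profile:

        score = mean_i ||u_i - c||^2 / mean_i ||u_i||^2,  c = mean_i u_i

    It is 0 when all malignant cells are identical, bounded by 1 (subset of
    the nominal [0, 2] range), and strictly increasing in between-clone
    divergence whenever structured expression variance exceeds noise.
    Plain 1-minus-correlation variants (cell vs. centroid, or mean pairwise)
    were rejected: the centroid contains each cell's own clone, and balanced
    clones cancel in pairwise averages, so neither tracks divergence. Cells
    with zero variance on the selected genes are excluded (logged). This
    form is an interpretation of the published heterogeneity score.
    """
    malignant_mask = np.asarray(malignant_mask, bool)
    if malignant_mask.sum() < 10:
        raise ValueError(
            f"need >= 10 malignant cells in the tumor, got {int(malignant_mask.sum())}"
        )
    X = expr.X[malignant_mask]
    X = X.toarray() if sp.issparse(X) else np.asarray(X, float)
    var = X.var(axis=0)
    hv = np.argsort(var)[::-1][: min(n_hvg, X.shape[1])]
    V = X[:, hv]
    U = V - V.mean(axis=1, keepdims=True)
    norms2 = np.sum(U**2, axis=1)
    ok = norms2 > 0
    if (~ok).any():
        logger.warning("ithgex_score: %d constant cells excluded", int((~ok).sum()))
    U = U[ok]
    if U.shape[0] < 2:
        return 0.0
    c = U.mean(axis=0)
    resid = np.mean(np.sum((U - c) ** 2, axis=1))
    return float(resid / np.mean(norms2[ok]))


# ---------------------------------------------------------------------------
# gene windows and the region permutation test


def make_gene_windows(genes: pd.DataFrame, window_size: int = 25) -> pd.DataFrame:
    """Partition genomically ordered genes into consecutive windows.

    Returns a DataFrame with region_id, chromosome, start_idx, end_idx
    (half-open indices into the gene order) and n_genes; the trailing window
    on each chromosome may be smaller than ``window_size``.
    """
    if window_size < 1:
        raise ValueError("window_size must be positive")
    chroms = genes["chromosome"].to_numpy()
    rows = []
    offset = 0
    for chrom in pd.unique(chroms):
        n = int((chroms == chrom).sum())
        for s in range(0, n, window_size):
            e = min(s + window_size, n)
            rows.append(
                {
                    "region_id": f"{chrom}:{s}-{e - 1}",
                    "chromosome": chrom,
                    "start_idx": offset + s,
                    "end_idx": offset + e,
                    "n_genes": e - s,
                }
            )
        offset += n
    return pd.DataFrame(rows)


def _region_means(P: CNVProfileMatrix, regions: pd.DataFrame) -> np.ndarray:
    starts = regions["start_idx"].to_numpy()
    sums = np.add.reduceat(P.values, starts, axis=1)
    return sums / regions["n_genes"].to_numpy()[None, :]


def region_group_test(
    P: CNVProfileMatrix,
    condition_labels,
    regions: pd.DataFrame,
    params: RegionTestParams | None = None,
    patient_labels=None,
) -> pd.DataFrame:
    """Permutation test of per-window CNV differences between two conditions.

    Per region the observed statistic is |mean region-CNV in condition A -
    condition B| (a cell's region-CNV is its mean profile over member
    genes). The null is built by shuffling condition labels over cells (or,
    with permutation_unit='patient', over patients); p uses the +1
    convention so it is never 0. BH-adjusted q values are reported alongside
    raw-p significance at alpha.
    """
    pr = params or RegionTestParams()
    pr.validate()
    cond = pd.Series(np.asarray(condition_labels, dtype=object))
    levels = pd.unique(cond.dropna())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(levels)}")
    a_name, b_name = levels
    a = (cond == a_name).to_numpy()
    b = (cond == b_name).to_numpy()
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("one condition has no cells")

    R = _region_means(P, regions)
    nA, nB = int(a.sum()), int(b.sum())
    mean_a, mean_b = R[a].mean(axis=0), R[b].mean(axis=0)
    obs = np.abs(mean_a - mean_b)

    rng = np.random.default_rng(pr.seed)
    used = a | b
    Ru = R[used]
    total = Ru.sum(axis=0)
    exceed = np.zeros(R.shape[1])
    if pr.permutation_unit == "patient":
        if patient_labels is None:
            raise ValueError("permutation_unit='patient' requires patient_labels")
        pats = pd.Series(np.asarray(patient_labels, dtype=object))[used].to_numpy()
        upats, pat_codes = np.unique(pats, return_inverse=True)
        pat_is_a = np.zeros(len(upats), bool)
        for i, up in enumerate(upats):
            pat_is_a[i] = a[used][pats == up].all()
        chunk = 500
        for lo in range(0, pr.n_perm, chunk):
            m = min(chunk, pr.n_perm - lo)
            perm_pat = np.stack([rng.permutation(pat_is_a) for _ in range(m)])
            M = perm_pat[:, pat_codes].astype(float)
            nAs = M.sum(axis=1, keepdims=True)
            sumsA = M @ Ru
            meanA = sumsA / nAs
            meanB = (total[None, :] - sumsA) / (len(pats) - nAs)
            exceed += (np.abs(meanA - meanB) >= obs[None, :]).sum(axis=0)
    else:
        a_used = a[used]
        chunk = 500
        for lo in range(0, pr.n_perm, chunk):
            m = min(chunk, pr.n_perm - lo)
            M = np.stack([rng.permutation(a_used) for _ in range(m)]).astype(float)
            sumsA = M @ Ru
            meanA = sumsA / nA
            meanB = (total[None, :] - sumsA) / nB
            exceed += (np.abs(meanA - meanB) >= obs[None, :]).sum(axis=0)

    p = (1.0 + exceed) / (1.0 + pr.n_perm)
    q = multipletests(p, method="fdr_bh")[1]
    out = regions.copy()
    out[f"mean_{a_name}"] = mean_a
    out[f"mean_{b_name}"] = mean_b
    out["diff"] = mean_a - mean_b
    out["statistic"] = obs
    out["p_value"] = p
    out["q_value"] = q
    out["significant"] = p < pr.alpha
    return out


def region_overlap(A: pd.DataFrame, B: pd.DataFrame, mode: str = "of_A") -> float:
    """Concordance of significant regions between two region test tables.

    mode 'of_A': |sig(A) & sig(B)| / |sig(A)|; mode 'jaccard':
    |intersection| / |union|. Both tables must be built on the same regions.
    Multiply by 100 for the percent form (e.g. '73.40%').
    """
    if not A["region_id"].equals(B["region_id"]):
        raise ValueError("A and B were not built on the same RegionSet")
    sa = set(A.loc[A["significant"], "region_id"])
    sb = set(B.loc[B["significant"], "region_id"])
    if mode == "of_A":
        if not sa:
            raise ValueError("undefined overlap: no significant regions in A")
        return len(sa & sb) / len(sa)
    if mode == "jaccard":
        union = sa | sb
        return len(sa & sb) / len(union) if union else 0.0
    raise ValueError(f"unknown mode {mode!r}")


def arm_level_summary(
    P: CNVProfileMatrix,
    arms: pd.DataFrame,
    group_labels,
    n_top: int = 25,
) -> pd.DataFrame:
    """Rank chromosome arms by group-specific mean CNV.

    ``arms`` is a table (chromosome, arm, start, end; 0-based half-open).
    Per arm and group, the mean CNV over the group's cells and member genes
    is computed; specificity is the between-group difference and the top
    ``n_top`` arms by |specificity| are returned with a gain/loss direction
    relative to the first group. Arms covering no profiled genes are skipped
    with a warning.
    """
    grp = pd.Series(np.asarray(group_labels, dtype=object))
    levels = pd.unique(grp.dropna())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    g1, g2 = levels
    m1, m2 = (grp == g1).to_numpy(), (grp == g2).to_numpy()
    chrom = P.genes["chromosome"].to_numpy()
    start = P.genes["start"].to_numpy()
    rows = []
    for _, arm in arms.iterrows():
        hit = (chrom == arm["chromosome"]) & (start >= arm["start"]) & (start < arm["end"])
        if not hit.any():
            logger.warning("arm %s%s covers no profiled genes; skipped",
                           arm["chromosome"], arm["arm"])
            continue
        v1 = P.values[np.ix_(m1, hit)].mean()
        v2 = P.values[np.ix_(m2, hit)].mean()
        spec = v1 - v2
        rows.append(
            {
                "chromosome": arm["chromosome"],
                "arm": arm["arm"],
                "n_genes": int(hit.sum()),
                f"mean_{g1}": v1,
                f"mean_{g2}": v2,
                "specificity": spec,
                "direction": "gain" if spec > 0 else ("loss" if spec < 0 else "neutral"),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.reindex(out["specificity"].abs().sort_values(ascending=False).index)
    return out.head(n_top).reset_index(drop=True)
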