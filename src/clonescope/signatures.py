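"""Gene-signature derivation, per-cell scoring and classification.

Signatures are top-N differentially expressed gene lists (e.g. a metastatic
program, or one list per integrative subtype). Cells are scored either by a
recovery-curve AUC over their expression ranking (AUCell-style, for
unweighted sets) or by a univariate linear model whose t-statistic is the
activity (for weighted sets); the classifier assigns each cell to its
highest-scoring signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
import anndata as ad
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """A named gene list, optionally with per-gene weights."""

    name: str
    genes: list[str]
    weights: list[float] | None = None

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")
        if self.weights is not None and len(self.weights) != len(self.genes):
            raise ValueError(
                f"gene set {self.name!r}: {len(self.weights)} weights for "
                f"{len(self.genes)} genes"
            )


@dataclass
class SignatureParams:
    n_top: int = 200
    auc_top_fraction: float = 0.05
    de_method: str = "ttest"  # or "ranksum"

    def validate(self) -> None:
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")
        if not 0 < self.auc_top_fraction <= 1:
            raise ValueError("auc_top_fraction must lie in (0, 1]")
        if self.de_method not in ("ttest", "ranksum"):
            raise ValueError("de_method must be 'ttest' or 'ranksum'")


@dataclass
class SignatureScores:
    """Cells x signatures score matrix with the per-cell argmax assignment."""

    scores: pd.DataFrame
    labels: pd.Series
    margin: pd.Series
    tie: pd.Series = field(default=None)


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X, float)


def rank_markers(
    expr: ad.AnnData, labels, method: str = "ttest"
) -> dict[str, pd.DataFrame]:
    """One-vs-rest marker test per group on log-normalized expression.

    Per group and gene: Welch t (or Wilcoxon rank-sum), log2 fold change on
    the expm1 (normalized count) scale, and BH-adjusted q across genes
    within the group. Groups with fewer than 3 cells are skipped with a
    warning. Tables are sorted by (p, -log2fc, gene) so ordering is
    deterministic.
    """
    lab = pd.Series(np.asarray(labels, dtype=object), index=expr.obs_names)
    groups = pd.unique(lab.dropna())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    X = _dense(expr.X)
    genes = expr.var_names.to_numpy()
    eps = 1e-9
    out: dict[str, pd.DataFrame] = {}
    for g in groups:
        mask = (lab == g).to_numpy()
        if mask.sum() < 3 or (~mask).sum() < 2:
            logger.warning("rank_markers: group %r below minimum size; skipped", g)
            continue
        A, B = X[mask], X[~mask]
        if method == "ttest":
            stat, p = st.ttest_ind(A, B, axis=0, equal_var=False)
        elif method == "ranksum":
            stat, p = st.ranksums(A, B, axis=0)
        else:
            raise ValueError("method must be 'ttest' or 'ranksum'")
        p = np.where(np.isfinite(p), p, 1.0)
        stat = np.where(np.isfinite(stat), stat, 0.0)
        lfc = np.log2(np.expm1(A).mean(axis=0) + eps) - np.log2(
            np.expm1(B).mean(axis=0) + eps
        )
        q = multipletests(p, method="fdr_bh")[1]
        tab = pd.DataFrame(
            {"gene": genes, "log2fc": lfc, "statistic": stat, "p_value": p, "q_value": q}
        )
        tab = tab.sort_values(
            ["p_value", "log2fc", "gene"], ascending=[True, False, True]
        ).reset_index(drop=True)
        out[str(g)] = tab
    return out


def derive_signature(
    marker_table: pd.DataFrame, n_top: int = 200, direction: str = "up",
    name: str = "signature",
) -> GeneSet:
    """Top-``n_top`` genes of a marker table in one direction.

    Genes are restricted to the requested direction (up: log2fc > 0, down:
    log2fc < 0) and ranked by significance then effect size, with gene id
    as the final tie-break so the selection is stable across runs.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sub = marker_table[
        marker_table["log2fc"] > 0 if direction == "up" else marker_table["log2fc"] < 0
    ].copy()
    if len(sub) < n_top:
        raise ValueError(
            f"cannot take top {n_top} {direction}-regulated genes: "
            f"{len(sub)} available"
        )
    asc = [True, direction == "down", True]
    sub = sub.sort_values(["p_value", "log2fc", "gene"], ascending=asc)
    return GeneSet(name=f"{name}_top{n_top}_{direction}", genes=sub["gene"].head(n_top).tolist())


def auc_score(
    expr: ad.AnnData,
    gene_set: GeneSet,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Recovery-curve AUC of a gene set within each cell's top-ranked genes.

    Genes are ranked per cell by decreasing expression, with ties broken by
    a per-cell seeded shuffle (logged); the score is the area under the
    cumulative hit curve within the top ceil(top_fraction * G) ranks,
    normalized to [0, 1] (1 when the set occupies the very top ranks).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    member = expr.var_names.isin(gene_set.genes)
    if not member.any():
        raise ValueError(
            f"no gene of set {gene_set.name!r} present in the matrix; "
            f"missing e.g. {gene_set.genes[:5]}"
        )
    logger.debug("auc_score: tie-break shuffles seeded from %d", seed)
    X = _dense(expr.X)
    n, G = X.shape
    k = math.ceil(top_fraction * G)
    m = int(member.sum())
    m_eff = min(m, k)
    max_auc = m_eff * (2 * k - m_eff + 1) / 2  # set genes at the very top
    rng = np.random.default_rng(seed)
    scores = np.empty(n)
    member = np.asarray(member)
    for c in range(n):
        tie_key = rng.permutation(G)
        order = np.lexsort((tie_key, -X[c]))
        ranks_in_top = np.flatnonzero(member[order][:k]) + 1  # 1-based
        scores[c] = np.sum(k - ranks_in_top + 1) / max_auc
    return scores


def mean_scaled_score(expr: ad.AnnData, gene_set: GeneSet) -> np.ndarray:
    """Per-cell mean of z-scaled expression over the set's present genes.

    The simple alternative scorer used when the AUC path is disabled; its
    form (mean of gene-standardized expression) is this package's own
    documented choice.
    """
    member = expr.var_names.isin(gene_set.genes)
    if not member.any():
        raise ValueError(f"no gene of set {gene_set.name!r} present in the matrix")
    X = _dense(expr.X)[:, np.asarray(member)]
    Z = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    return Z.mean(axis=1)


def weighted_activity(expr: ad.AnnData, gene_set: GeneSet) -> np.ndarray:
    """Pathway activity from a weighted gene set via a univariate linear model.

    Per cell, expression is regressed on the weight vector (weight 0 for
    genes outside the set, across all matrix genes); the activity is the
    t-statistic of the slope. Requires >= 3 member genes present and
    non-constant weights.
    """
    if gene_set.weights is None:
        raise ValueError(f"gene set {gene_set.name!r} carries no weights")
    w = np.zeros(expr.n_vars)
    pos = pd.Index(expr.var_names).get_indexer(gene_set.genes)
    present = pos >= 0
    if present.sum() < 3:
        raise ValueError(
            f"gene set {gene_set.name!r}: only {int(present.sum())} member genes "
            "present (need >= 3)"
        )
    w[pos[present]] = np.asarray(gene_set.weights)[present]
    if np.ptp(w) == 0:
        raise ValueError("weight vector has zero variance")
    X = _dense(expr.X)
    G = X.shape[1]
    wc = w - w.mean()
    xc = X - X.mean(axis=1, keepdims=True)
    sw = np.sqrt(np.sum(wc**2))
    sx = np.sqrt(np.sum(xc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sx > 0, xc @ wc / np.maximum(sx * sw, 1e-300), 0.0)
    r2 = np.minimum(r**2, 1 - 1e-15)
    return r * np.sqrt((G - 2) / (1 - r2))


def classify_by_signatures(
    scores: pd.DataFrame, standardize: bool = False
) -> SignatureScores:
    """Assign each cell to its highest-scoring signature.

    With ``standardize=True`` each signature's scores are z-scaled across
    cells first and the scaled matrix is stored; signatures differ in
    baseline (e.g. sets enriched in constitutively high genes score high in
    every cell), so cross-signature argmax on raw scores can be dominated
    by one set. Ties are broken by signature (column) order; tied cells get
    margin 0 and a raised tie flag.
    """
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 signatures to classify")
    if standardize:
        scores = (scores - scores.mean(axis=0)) / scores.std(axis=0).clip(lower=1e-12)
    V = scores.to_numpy(float)
    best = V.argmax(axis=1)
    part = np.sort(V, axis=1)
    margin = part[:, -1] - part[:, -2]
    tie = margin == 0
    labels = pd.Series(scores.columns.to_numpy()[best], index=scores.index, name="label")
    return SignatureScores(
        scores=scores,
        labels=labels,
        margin=pd.Series(margin, index=scores.index, name="margin"),
        tie=pd.Series(tie, index=scores.index, name="tie"),
    )


def pseudobulk_de(
    counts: ad.AnnData, sample_labels, condition_labels
) -> pd.DataFrame:
    """Sample-level differential expression on summed (pseudobulk) counts.

    Counts are summed per sample, converted to log2-CPM (+1), and each gene
    is tested between conditions with a Welch t-test across samples, BH
    corrected. Both conditions need >= 2 samples. logFC is the mean
    log2-CPM difference (first condition minus second).
    """
    samp = pd.Series(np.asarray(sample_labels, dtype=object))
    cond = pd.Series(np.asarray(condition_labels, dtype=object))
    pairs = pd.DataFrame({"sample": samp, "condition": cond}).drop_duplicates()
    if pairs["sample"].duplicated().any():
        raise ValueError("a sample maps to more than one condition")
    levels = pd.unique(pairs["condition"])
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(levels)}")
    counts_by = {}
    X = counts.X
    for s in pairs["sample"]:
        mask = (samp == s).to_numpy()
        counts_by[s] = np.asarray(X[mask].sum(axis=0)).ravel()
    for lv in levels:
        if (pairs["condition"] == lv).sum() < 2:
            raise ValueError(
                f"condition {lv!r} has a single sample; between-sample variance "
                "is undefined"
            )
    mat = np.stack([counts_by[s] for s in pairs["sample"]])
    cpm = np.log2(mat / mat.sum(axis=1, keepdims=True) * 1e6 + 1)
    is_a = (pairs["condition"] == levels[0]).to_numpy()
    A, B = cpm[is_a], cpm[~is_a]
    stat, p = st.ttest_ind(A, B, axis=0, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": counts.var_names.to_numpy(),
            "log2fc": A.mean(axis=0) - B.mean(axis=0),
            "p_value": p,
            "q_value": q,
        }
    )
    out["_abs_lfc"] = out["log2fc"].abs()
    out = out.sort_values(
        ["q_value", "_abs_lfc", "gene"], ascending=[True, False, True]
    ).drop(columns="_abs_lfc")
    return out.reset_index(drop=True)


def state_coordinates(scores: pd.DataFrame, axis_sets: list[str]) -> pd.DataFrame:
    """Cellular-state plot coordinates from 2 or 4 signature scores.

    With 2 signatures the coordinates are the raw scores; with 4 (A, B, C,
    D) they are (A - B, C - D), placing each cell on two opposing program
    axes.
    """
    missing = [s for s in axis_sets if s not in scores.columns]
    if missing:
        raise ValueError(f"unknown signature name(s): {missing}")
    if len(axis_sets) == 2:
        x, y = scores[axis_sets[0]], scores[axis_sets[1]]
    elif len(axis_sets) == 4:
        a, b, c, d = (scores[s] for s in axis_sets)
        x, y = a - b, c - d
    else:
        raise ValueError("axis_sets must name 2 or 4 signatures")
    return pd.DataFrame({"x": x.to_numpy(), "y": y.to_numpy()}, index=scores.index)


# ---------------------------------------------------------------------------
# gene-set file formats


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read unweighted gene sets from a GMT file (name, description, genes...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs name, description, >=1 gene")
        sets.append(GeneSet(name=parts[0], genes=parts[2:]))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, "clonescope"] + list(s.genes)) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def read_weighted_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a weighted gene set from a two-column TSV (gene, weight)."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["gene", "weight"], comment="#")
    return GeneSet(
        name=name or Path(path).stem,
        genes=tab["gene"].astype(str).tolist(),
        weights=tab["weight"].astype(float).tolist(),
    )


def write_weighted_set(s: GeneSet, path: str | Path) -> None:
    if s.weights is None:
        raise ValueError("gene set carries no weights")
    pd.DataFrame({"gene": s.genes, "weight": s.weights}).to_csv(
        path, sep="\t", header=False, index=False
    )
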