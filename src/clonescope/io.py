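"""Reading 10x-style inputs, quality-control filtering and log-normalization.

QC follows the conventional three-criterion cell filter: mitochondrial count
fraction, total UMI count and number of detected genes, all with inclusive
bounds computed on raw counts. Normalization scales each cell to a fixed
target sum and applies log1p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io
import anndata as ad
import scanpy as sc

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file (dimension mismatch, non-integer counts, ...)."""


@dataclass
class QCThresholds:
    """Cell-level QC bounds; all bounds inclusive.

    Defaults: mitochondrial fraction <= 0.20, total UMIs in [400, 100000],
    detected genes in [200, 10000].
    """

    mito_max: float = 0.20
    umi_min: int = 400
    umi_max: int = 100_000
    genes_min: int = 200
    genes_max: int = 10_000

    def validate(self) -> None:
        if not 0 <= self.mito_max <= 1:
            raise ValueError("mito_max must lie in [0, 1]")
        if self.umi_min >= self.umi_max or self.genes_min >= self.genes_max:
            raise ValueError("QC min bounds must be below max bounds")


def read_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path | None = None,
    positions_path: str | Path | None = None,
) -> ad.AnnData:
    """Read a 10x-style triplet into an AnnData (cells x genes).

    On disk the matrix is genes x cells (Matrix Market, 1-based); it is
    transposed on load. ``metadata_path`` (TSV with a cell_id column) is
    joined onto ``.obs``; ``positions_path`` (BED-like TSV: chromosome,
    start, end, gene_id; 0-based half-open) onto ``.var``. Duplicate gene
    symbols are disambiguated with a numeric suffix and logged.
    """
    for p in (mtx_path, features_path, barcodes_path):
        if not Path(p).exists():
            raise FormatError(f"input file not found: {p}")
    try:
        M = scipy.io.mmread(str(mtx_path))
    except Exception as e:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"{mtx_path}: not a readable Matrix Market file ({e})")
    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0]
    if M.shape[0] != len(feats):
        raise FormatError(
            f"{mtx_path} declares {M.shape[0]} genes but {features_path} has "
            f"{len(feats)} rows"
        )
    if M.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path} declares {M.shape[1]} cells but {barcodes_path} has "
            f"{len(barcodes)} rows"
        )
    data = M.data if sp.issparse(M) else np.asarray(M).ravel()
    if not np.allclose(data, np.round(data)) or (data < 0).any():
        raise FormatError(f"{mtx_path}: counts must be non-negative integers")
    X = sp.csr_matrix(M.T).astype(np.int64)
    if barcodes.duplicated().any():
        dups = barcodes[barcodes.duplicated()].unique().tolist()
        raise FormatError(f"{barcodes_path}: duplicate cell ids {dups[:5]}")
    symbols = feats[1] if feats.shape[1] > 1 else feats[0]
    var = pd.DataFrame({"gene_id": feats[0].to_numpy()}, index=symbols.to_numpy())
    var.index.name = "gene_symbol"
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=barcodes.to_numpy()), var=var)
    adata.obs_names.name = "cell_id"
    if adata.var_names.duplicated().any():
        dups = adata.var_names[adata.var_names.duplicated()].unique().tolist()
        logger.warning("duplicate gene symbols disambiguated with suffixes: %s", dups)
        adata.var_names_make_unique(join="-")
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t").set_index("cell_id")
        missing = adata.obs_names.difference(meta.index)
        if len(missing):
            raise FormatError(
                f"{metadata_path}: {len(missing)} barcodes lack metadata rows "
                f"(first: {missing[0]})"
            )
        adata.obs = adata.obs.join(meta, how="left")
    if positions_path is not None:
        bed = pd.read_csv(
            positions_path,
            sep="\t",
            header=None,
            names=["chromosome", "start", "end", "gene_id"],
        ).set_index("gene_id")
        joined = (
            adata.var.reset_index().merge(
                bed, left_on="gene_id", right_index=True, how="left"
            )
        ).set_index("gene_symbol")
        adata.var = joined
    if "is_mito" not in adata.var:
        adata.var["is_mito"] = adata.var_names.str.upper().str.startswith("MT-")
    return adata


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[np.ndarray, dict]:
    """Per-cell QC mask plus a report of per-criterion exclusion counts.

    A cell is kept iff its mitochondrial fraction is <= mito_max AND its
    total counts lie in [umi_min, umi_max] AND its detected-gene count lies
    in [genes_min, genes_max] (all inclusive, computed on raw counts).
    """
    t = thresholds or QCThresholds()
    t.validate()
    if "is_mito" not in adata.var:
        raise ValueError("adata.var lacks an 'is_mito' flag; annotate genes first")
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito = np.asarray(X[:, adata.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)
    fail_mito = mito_frac > t.mito_max
    fail_umi_low = totals < t.umi_min
    fail_umi_high = totals > t.umi_max
    fail_genes_low = n_genes < t.genes_min
    fail_genes_high = n_genes > t.genes_max
    keep = ~(fail_mito | fail_umi_low | fail_umi_high | fail_genes_low | fail_genes_high)
    if not keep.any():
        raise ValueError("empty after QC: every cell failed at least one criterion")
    report = {
        "n_cells_input": int(adata.n_obs),
        "n_cells_kept": int(keep.sum()),
        "n_cells_excluded": int((~keep).sum()),
        "excluded_by": {
            "mito_fraction": int(fail_mito.sum()),
            "umi_below_min": int(fail_umi_low.sum()),
            "umi_above_max": int(fail_umi_high.sum()),
            "genes_below_min": int(fail_genes_low.sum()),
            "genes_above_max": int(fail_genes_high.sum()),
        },
        "thresholds": asdict(t),
    }
    return keep, report


def apply_exclusions(keep: np.ndarray, adata: ad.AnnData, excluded_cells) -> np.ndarray:
    """AND an external exclusion list (e.g. doublet calls) into a QC mask."""
    out = keep.copy()
    out[adata.obs_names.isin(pd.Index(excluded_cells))] = False
    return out


def normalize_log(adata: ad.AnnData, target_sum: float = 10_000.0) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Returns a new AnnData whose ``.X`` holds the log-normalized values;
    sparsity is preserved and per-cell sums of expm1(X) equal target_sum.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise ValueError(
            f"{int((totals <= 0).sum())} cells have zero counts; run qc_filter first"
        )
    out = adata.copy()
    out.X = out.X.astype(np.float64)
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    out.uns["target_sum"] = float(target_sum)
    return out
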