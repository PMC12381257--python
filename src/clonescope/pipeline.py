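"""Configuration-driven orchestration of the full analysis chain.

Stages: simulate (or load) -> qc -> cnv (profiles, scores, malignant calls,
subclones, heterogeneity) -> regions (window permutation test, arm summary)
-> signatures (derive, score, classify) -> composition. Each stage reads
its inputs from the working directory and writes text outputs there, so any
stage can be rerun standalone with identical results; ``run_pipeline``
chains them and writes a manifest with a content hash per output file.

One master seed deterministically derives per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad

from . import __version__
from . import io as csio
from . import cnv as cscnv
from . import composition as cscomp
from . import signatures as cssig
from . import simulate as cssim

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "cnv", "regions", "signatures", "composition")

_FLOAT_FMT = "%.10g"


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one sub-2^31 seed per stage from the master seed."""
    rng = np.random.default_rng(master_seed)
    vals = rng.integers(0, 2**31 - 1, size=len(STAGES))
    return {s: int(v) for s, v in zip(STAGES, vals)}


def load_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    if ("simulate" in cfg) == ("input" in cfg):
        raise ValueError("config must contain exactly one of [simulate] / [input]")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages (each reads prior outputs from `outdir` and writes its own)


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    sim = dict(cfg.get("simulate", {}))
    sim.setdefault("seed", seed)
    config = cssim.SimConfig(**sim) if sim.get("cell_types") else cssim.default_config(
        seed=sim["seed"]
    )
    adata, truth = cssim.simulate_cohort(config)
    raw = outdir / "raw"
    paths = cssim.write_cohort(adata, truth, config, raw)
    return list(paths.values())


def _load_raw(cfg: dict, outdir: Path) -> ad.AnnData:
    if "input" in cfg:
        paths = cfg["input"]
        base = Path(paths.get("dir", "."))
        return csio.read_matrix(
            base / paths["matrix"],
            base / paths["features"],
            base / paths["barcodes"],
            metadata_path=base / paths["metadata"] if "metadata" in paths else None,
            positions_path=base / paths["positions"] if "positions" in paths else None,
        )
    raw = outdir / "raw"
    return csio.read_matrix(
        raw / "matrix.mtx",
        raw / "features.tsv",
        raw / "barcodes.tsv",
        metadata_path=raw / "metadata.tsv",
        positions_path=raw / "genes.bed",
    )


def stage_qc(cfg: dict, outdir: Path) -> list[Path]:
    adata = _load_raw(cfg, outdir)
    thresholds = csio.QCThresholds(**cfg.get("qc", {}))
    keep, report = csio.qc_filter(adata, thresholds)
    qcdir = outdir / "qc"
    qcdir.mkdir(parents=True, exist_ok=True)
    (qcdir / "qc_report.json").write_text(json.dumps(report, indent=2))
    kept = pd.Series(adata.obs_names[keep])
    kept.to_csv(qcdir / "kept_barcodes.tsv", sep="\t", header=False, index=False)
    return [qcdir / "qc_report.json", qcdir / "kept_barcodes.tsv"]


def _load_filtered_expr(cfg: dict, outdir: Path) -> ad.AnnData:
    adata = _load_raw(cfg, outdir)
    kept = pd.read_csv(
        outdir / "qc" / "kept_barcodes.tsv", sep="\t", header=None, dtype=str
    )[0]
    adata = adata[adata.obs_names.isin(set(kept))].copy()
    target = float(cfg.get("normalize", {}).get("target_sum", 10_000.0))
    return csio.normalize_log(adata, target_sum=target)


def stage_cnv(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    expr = _load_filtered_expr(cfg, outdir)
    params = cscnv.CNVParams(**cfg.get("cnv", {}))
    ref_mask = (expr.obs["cell_type"] == params.reference_label).to_numpy()
    P = cscnv.infer_cnv_profiles(expr, ref_mask, params)
    scores = cscnv.cnv_score(P)
    candidates = (
        expr.obs["cell_type"].to_numpy() == cfg.get("cnv", {}).get(
            "candidate_cell_type", "epithelial"
        )
    )
    calls = cscnv.call_malignant(P, scores, candidates, seed=seed)
    mal = calls == "malignant"
    subclone = np.full(P.n_cells, "", dtype=object)
    if mal.sum() >= 20:
        subclone[mal] = [
            f"clone{c}" for c in cscnv.detect_subclones(P, mal)
        ]
    ith_rows = []
    for patient, sub in expr.obs.groupby("patient", observed=True):
        pm = mal & np.asarray(expr.obs_names.isin(sub.index))
        if pm.sum() >= 10:
            ith_rows.append(
                {"patient": patient, "ithgex": cscnv.ithgex_score(expr, pm)}
            )
    cnvdir = outdir / "cnv"
    cnvdir.mkdir(parents=True, exist_ok=True)
    prof = pd.DataFrame(P.values, index=P.cell_ids, columns=P.genes.index)
    _write_tsv(prof, cnvdir / "profiles.tsv", index=True)
    _write_tsv(P.genes.reset_index(), cnvdir / "gene_order.tsv")
    cells = pd.DataFrame(
        {
            "cell_id": P.cell_ids,
            "cnv_score": scores,
            "is_reference": P.is_reference,
            "call": calls,
            "subclone": subclone,
        }
    )
    _write_tsv(cells, cnvdir / "cells.tsv")
    _write_tsv(pd.DataFrame(ith_rows), cnvdir / "ithgex.tsv")
    return [
        cnvdir / "profiles.tsv",
        cnvdir / "gene_order.tsv",
        cnvdir / "cells.tsv",
        cnvdir / "ithgex.tsv",
    ]


def _load_profiles(outdir: Path) -> tuple[cscnv.CNVProfileMatrix, pd.DataFrame]:
    cnvdir = outdir / "cnv"
    prof = pd.read_csv(cnvdir / "profiles.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(cnvdir / "gene_order.tsv", sep="\t", index_col=0)
    cells = pd.read_csv(cnvdir / "cells.tsv", sep="\t")
    P = cscnv.CNVProfileMatrix(
        values=prof.to_numpy(),
        genes=genes,
        cell_ids=prof.index,
        is_reference=cells["is_reference"].to_numpy(),
    )
    return P, cells


def stage_regions(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    P, cells = _load_profiles(outdir)
    adata = _load_raw(cfg, outdir)
    meta = adata.obs.loc[P.cell_ids]
    rcfg = dict(cfg.get("regions", {}))
    window = int(rcfg.pop("window_size", 25))
    n_top = int(rcfg.pop("n_top_arms", 25))
    params = cscnv.RegionTestParams(**rcfg)
    params.seed = seed
    regions = cscnv.make_gene_windows(P.genes, window)
    mal = (cells["call"] == "malignant").to_numpy()
    cond = meta["condition"].to_numpy(dtype=object)
    cond_mal = np.where(mal, cond, None)
    table = cscnv.region_group_test(
        P, cond_mal, regions, params, patient_labels=meta["patient"].to_numpy()
    )
    # whole chromosomes stand in for arms when no arm table is supplied
    arm_rows = []
    for chrom in pd.unique(P.genes["chromosome"]):
        s = P.genes.loc[P.genes["chromosome"] == chrom, "start"]
        half = (s.min() + s.max()) / 2
        arm_rows.append({"chromosome": chrom, "arm": "p", "start": 0, "end": half})
        arm_rows.append({"chromosome": chrom, "arm": "q", "start": half, "end": s.max() + 1})
    arms = pd.DataFrame(arm_rows)
    grp = np.where(mal, cond, None)
    arm_tab = cscnv.arm_level_summary(P, arms, grp, n_top=n_top)
    regdir = outdir / "regions"
    regdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(table, regdir / "region_test.tsv")
    _write_tsv(arm_tab, regdir / "arm_summary.tsv")
    return [regdir / "region_test.tsv", regdir / "arm_summary.tsv"]


def stage_signatures(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    expr = _load_filtered_expr(cfg, outdir)
    _, cells = _load_profiles(outdir)
    scfg = cfg.get("signatures", {})
    params = cssig.SignatureParams(
        n_top=int(scfg.get("n_top", 200)),
        auc_top_fraction=float(scfg.get("auc_top_fraction", 0.05)),
        de_method=scfg.get("de_method", "ttest"),
    )
    params.validate()
    mal_ids = set(cells.loc[cells["call"] == "malignant", "cell_id"])
    mal_mask = expr.obs_names.isin(mal_ids)
    target = expr[mal_mask].copy() if mal_mask.sum() >= 6 else expr
    labels = target.obs["condition"]
    markers = cssig.rank_markers(target, labels, method=params.de_method)
    sets = []
    for grp, tab in markers.items():
        n_avail = int((tab["log2fc"] > 0).sum())
        sets.append(
            cssig.derive_signature(
                tab, n_top=min(params.n_top, n_avail), direction="up", name=grp
            )
        )
    sigdir = outdir / "signatures"
    sigdir.mkdir(parents=True, exist_ok=True)
    cssig.write_gmt(sets, sigdir / "signatures.gmt")
    scores = pd.DataFrame(
        {s.name: cssig.auc_score(target, s, params.auc_top_fraction, seed=seed) for s in sets},
        index=target.obs_names,
    )
    assign = cssig.classify_by_signatures(scores, standardize=True)
    _write_tsv(scores, sigdir / "scores.tsv", index=True)
    cls = pd.DataFrame(
        {"label": assign.labels, "margin": assign.margin, "tie": assign.tie}
    )
    _write_tsv(cls, sigdir / "classification.tsv", index=True)
    (sigdir / "params.json").write_text(json.dumps(asdict(params), indent=2))
    return [
        sigdir / "signatures.gmt",
        sigdir / "scores.tsv",
        sigdir / "classification.tsv",
        sigdir / "params.json",
    ]


def stage_composition(cfg: dict, outdir: Path, seed: int) -> list[Path]:
    adata = _load_raw(cfg, outdir)
    kept = pd.read_csv(
        outdir / "qc" / "kept_barcodes.tsv", sep="\t", header=None, dtype=str
    )[0]
    obs = adata.obs.loc[adata.obs_names.isin(set(kept))]
    ccfg = cfg.get("composition", {})
    tab = cscomp.proportion_test(
        obs["cell_type"],
        obs["condition"],
        n_perm=int(ccfg.get("n_perm", 1000)),
        n_boot=int(ccfg.get("n_boot", 1000)),
        alpha=float(ccfg.get("alpha", 0.05)),
        fc_threshold=float(ccfg.get("fc_threshold", 2.0)),
        seed=seed,
    )
    compdir = outdir / "composition"
    compdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(tab, compdir / "proportions.tsv")
    (compdir / "params.json").write_text(
        json.dumps({k: ccfg.get(k) for k in ccfg}, indent=2)
    )
    return [compdir / "proportions.tsv", compdir / "params.json"]


# ---------------------------------------------------------------------------


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run all stages in dependency order and write a manifest.

    The manifest echoes the config and seed, lists every output file with a
    sha256 content hash, and is itself written to ``outdir/manifest.json``.
    Rerunning with the same config and seed reproduces the hashes. On stage
    failure the error names the stage; outputs of completed stages remain
    on disk and are listed in the partial manifest.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    if ("simulate" in cfg) == ("input" in cfg):
        raise ValueError("config must contain exactly one of [simulate] / [input]")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(seed if seed is not None else cfg.get("seed", 0))
    seeds = stage_seeds(master)
    manifest: dict = {
        "package": "clonescope",
        "version": __version__,
        "seed": master,
        "config": _jsonable(cfg),
        "stages": [],
    }
    plan = [
        ("simulate", lambda: stage_simulate(cfg, outdir, seeds["simulate"]))
        if "simulate" in cfg
        else ("simulate", lambda: []),
        ("qc", lambda: stage_qc(cfg, outdir)),
        ("cnv", lambda: stage_cnv(cfg, outdir, seeds["cnv"])),
        ("regions", lambda: stage_regions(cfg, outdir, seeds["regions"])),
        ("signatures", lambda: stage_signatures(cfg, outdir, seeds["signatures"])),
        ("composition", lambda: stage_composition(cfg, outdir, seeds["composition"])),
    ]
    for name, fn in plan:
        try:
            outputs = fn()
        except Exception as e:
            manifest["failed_stage"] = name
            manifest["error"] = str(e)
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
        manifest["stages"].append(
            {
                "name": name,
                "seed": seeds[name],
                "outputs": {
                    str(p.relative_to(outdir)): _sha256(p) for p in outputs
                },
            }
        )
        logger.info("stage %s: %d outputs", name, len(outputs))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
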