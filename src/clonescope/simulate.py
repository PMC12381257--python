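"""Synthetic multi-patient, two-condition scRNA-seq cohorts with planted truth.

The generator emulates the structure of a primary-vs-metastatic breast cancer
cohort: several patients per condition, a handful of cell lineages with marker
programs, malignant epithelial cells carrying clone-specific copy-number
segments that act multiplicatively on expected expression, mitochondrial
genes contributing to the QC fraction, and condition-dependent cell-type
composition. Counts are negative binomial with a shared dispersion.

Every random draw is keyed to the config seed; one RNG stream per patient is
derived from the master seed so adding patients never perturbs the data of
earlier patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io
import anndata as ad


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass
class Segment:
    """One copy-number segment: 0-based inclusive gene indices on a chromosome.

    copy_ratio multiplies expected expression of member genes: 1 is neutral,
    1.5 a single-copy gain on a diploid background, 0.5 a single-copy loss.
    """

    chromosome: str
    start_gene_index: int
    end_gene_index: int
    copy_ratio: float


@dataclass
class CloneSpec:
    """A malignant clone: its segments and per-condition prevalence weights."""

    clone_id: str
    condition_weights: dict[str, float]
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self):
        self.segments = [
            Segment(**s) if isinstance(s, dict) else s for s in self.segments
        ]


@dataclass
class CellTypeSpec:
    name: str
    proportion_by_condition: dict[str, float]
    marker_genes_count: int = 0
    marker_fold: float = 1.0


@dataclass
class SimConfig:
    """All knobs of the cohort generator; see module docstring for the model."""

    n_patients_per_condition: int = 4
    cells_per_patient: int = 300
    n_chromosomes: int = 6
    genes_per_chromosome: int = 120
    baseline_log_mean: float = 1.5
    baseline_log_sd: float = 1.5
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.25
    nb_dispersion: float = 10.0
    mito_gene_fraction: float = 0.03
    mito_expression_boost: float = 4.0
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    clones: list[CloneSpec] = field(default_factory=list)
    malignant_fraction_by_condition: dict[str, float] = field(default_factory=dict)
    malignant_cell_type: str = "epithelial"
    conditions: tuple[str, str] = ("primary", "metastatic")
    seed: int = 0

    def __post_init__(self):
        self.cell_types = [
            CellTypeSpec(**c) if isinstance(c, dict) else c for c in self.cell_types
        ]
        self.clones = [
            CloneSpec(**c) if isinstance(c, dict) else c for c in self.clones
        ]
        self.conditions = tuple(self.conditions)

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome

    def validate(self) -> None:
        if self.n_patients_per_condition < 1 or self.cells_per_patient < 1:
            raise ConfigError("n_patients_per_condition and cells_per_patient must be positive")
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ConfigError("n_chromosomes and genes_per_chromosome must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0 <= self.mito_gene_fraction <= 1:
            raise ConfigError("mito_gene_fraction must lie in [0, 1]")
        if not self.cell_types:
            raise ConfigError("cell_types must not be empty")
        for cond in self.conditions:
            total = sum(ct.proportion_by_condition.get(cond, 0.0) for ct in self.cell_types)
            if not np.isclose(total, 1.0):
                raise ConfigError(
                    f"cell_types proportions for condition {cond!r} sum to {total}, not 1"
                )
            frac = self.malignant_fraction_by_condition.get(cond, 0.0)
            if not 0 <= frac <= 1:
                raise ConfigError(f"malignant_fraction_by_condition[{cond!r}] outside [0, 1]")
        for ct in self.cell_types:
            if ct.marker_genes_count < 0 or ct.marker_fold <= 0:
                raise ConfigError(f"cell_types[{ct.name!r}]: marker count/fold must be positive")
        seen = set()
        for clone in self.clones:
            if clone.clone_id in seen:
                raise ConfigError(f"duplicate clone_id {clone.clone_id!r}")
            seen.add(clone.clone_id)
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for seg in clone.segments:
                if seg.copy_ratio <= 0:
                    raise ConfigError(f"clones[{clone.clone_id!r}]: copy_ratio must be > 0")
                if seg.end_gene_index < seg.start_gene_index or seg.start_gene_index < 0:
                    raise ConfigError(
                        f"clones[{clone.clone_id!r}]: segment end < start on {seg.chromosome}"
                    )
                if seg.end_gene_index >= self.genes_per_chromosome:
                    raise ConfigError(
                        f"clones[{clone.clone_id!r}]: segment exceeds genes_per_chromosome"
                    )
                by_chrom.setdefault(seg.chromosome, []).append(
                    (seg.start_gene_index, seg.end_gene_index)
                )
            for chrom, ivals in by_chrom.items():
                ivals.sort()
                for (s0, e0), (s1, _e1) in zip(ivals, ivals[1:]):
                    if s1 <= e0:
                        raise ConfigError(
                            f"clones[{clone.clone_id!r}]: overlapping segments on {chrom}"
                        )
        names = [ct.name for ct in self.cell_types]
        if self.malignant_cell_type not in names and any(
            self.malignant_fraction_by_condition.get(c, 0) > 0 for c in self.conditions
        ):
            raise ConfigError(
                f"malignant_cell_type {self.malignant_cell_type!r} not among cell_types"
            )
        if self.clones:
            for cond in self.conditions:
                if self.malignant_fraction_by_condition.get(cond, 0) > 0:
                    w = sum(c.condition_weights.get(cond, 0.0) for c in self.clones)
                    if w <= 0:
                        raise ConfigError(
                            f"condition_weights sum to 0 for condition {cond!r} "
                            "but malignant cells are requested there"
                        )


@dataclass
class Truth:
    """Ground truth of a simulated cohort.

    cells: per-cell patient, condition, cell_type, clone_id, is_malignant
    clones: clone_id -> list of planted segments
    genes: per-gene chromosome, start, end, is_mito (mirrors AnnData.var)
    differential_regions: segments of clones whose prevalence differs between
        conditions, i.e. the windows planted to differ in the region test.
    """

    cells: pd.DataFrame
    clones: dict[str, list[Segment]]
    genes: pd.DataFrame
    differential_regions: list[dict]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cells": self.cells.reset_index().to_dict(orient="list"),
            "clones": {k: [asdict(s) for s in v] for k, v in self.clones.items()},
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "differential_regions": self.differential_regions,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Truth":
        d = json.loads(Path(path).read_text())
        cells = pd.DataFrame(d["cells"]).set_index("cell_id")
        genes = pd.DataFrame(d["genes"]).set_index("gene_id")
        clones = {
            k: [Segment(**s) for s in v] for k, v in d["clones"].items()
        }
        return cls(cells, clones, genes, d["differential_regions"])


# ---------------------------------------------------------------------------


def _gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    chrom = np.repeat(
        [f"chr{i + 1}" for i in range(cfg.n_chromosomes)], cfg.genes_per_chromosome
    )
    within = np.tile(np.arange(cfg.genes_per_chromosome), cfg.n_chromosomes)
    start = within * 100_000
    n_mito = int(round(cfg.mito_gene_fraction * n))
    mito_idx = rng.choice(n, size=n_mito, replace=False) if n_mito else np.array([], int)
    is_mito = np.zeros(n, bool)
    is_mito[mito_idx] = True
    gene_id = np.array(
        [
            (f"MT-G{i + 1:05d}" if is_mito[i] else f"G{i + 1:05d}")
            for i in range(n)
        ]
    )
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "start": start,
            "end": start + 1_000,
            "within_chrom_index": within,
            "is_mito": is_mito,
        },
        index=pd.Index(gene_id, name="gene_id"),
    )


def _dosage_vectors(cfg: SimConfig, genes: pd.DataFrame) -> np.ndarray:
    """(n_clones, n_genes) multiplicative dosage; mito genes stay neutral."""
    dos = np.ones((len(cfg.clones), len(genes)))
    chrom = genes["chromosome"].to_numpy()
    within = genes["within_chrom_index"].to_numpy()
    mito = genes["is_mito"].to_numpy()
    for i, clone in enumerate(cfg.clones):
        for seg in clone.segments:
            hit = (
                (chrom == seg.chromosome)
                & (within >= seg.start_gene_index)
                & (within <= seg.end_gene_index)
                & ~mito
            )
            dos[i, hit] = seg.copy_ratio
    return dos


def _marker_assignments(
    cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """(n_types, n_genes) multiplicative marker fold; disjoint marker sets."""
    fold = np.ones((len(cfg.cell_types), len(genes)))
    eligible = np.flatnonzero(~genes["is_mito"].to_numpy())
    order = rng.permutation(eligible)
    cursor = 0
    for i, ct in enumerate(cfg.cell_types):
        k = ct.marker_genes_count
        if cursor + k > len(order):
            raise ConfigError("not enough non-mitochondrial genes for all marker programs")
        fold[i, order[cursor : cursor + k]] = ct.marker_fold
        cursor += k
    return fold


def simulate_cohort(config: SimConfig) -> tuple[ad.AnnData, Truth]:
    """Generate a cohort as an AnnData (counts, obs=cells, var=genes) plus Truth.

    Counts for cell c, gene g are NB with mean
    ``libsize_c * lambda_g * dosage_{clone(c),g} * marker_fold_{type(c),g}``
    and shared dispersion; non-malignant cells have dosage 1 everywhere.
    Identical config and seed give byte-identical output.
    """
    config.validate()
    master = np.random.default_rng([config.seed, 0])
    genes = _gene_table(config, master)
    lam = master.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    lam[genes["is_mito"].to_numpy()] *= config.mito_expression_boost
    fold = _marker_assignments(config, genes, master)
    dosage = _dosage_vectors(config, genes)

    theta = config.nb_dispersion
    type_names = [ct.name for ct in config.cell_types]
    mal_type = (
        type_names.index(config.malignant_cell_type)
        if config.malignant_cell_type in type_names
        else -1
    )

    blocks, obs_frames = [], []
    patient_no = 0
    for cond in config.conditions:
        props = np.array(
            [ct.proportion_by_condition.get(cond, 0.0) for ct in config.cell_types]
        )
        mal_frac = config.malignant_fraction_by_condition.get(cond, 0.0)
        if config.clones:
            w = np.array([c.condition_weights.get(cond, 0.0) for c in config.clones])
            w = w / w.sum() if w.sum() > 0 else w
        for p in range(config.n_patients_per_condition):
            patient_no += 1
            patient = f"{cond[:1].upper()}{p + 1:02d}"
            rng = np.random.default_rng([config.seed, 1000 + patient_no])
            n = config.cells_per_patient
            types = rng.choice(len(config.cell_types), size=n, p=props)
            is_mal = np.zeros(n, bool)
            if mal_type >= 0 and mal_frac > 0:
                cand = types == mal_type
                is_mal[cand] = rng.random(cand.sum()) < mal_frac
            clone_of = np.full(n, -1)
            if config.clones and is_mal.any():
                clone_of[is_mal] = rng.choice(len(config.clones), size=is_mal.sum(), p=w)
            lib = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, n)
            mu = lib[:, None] * lam[None, :]
            mu *= fold[types]
            carriers = clone_of >= 0
            if carriers.any():
                mu[carriers] *= dosage[clone_of[carriers]]
            counts = rng.negative_binomial(theta, theta / (theta + mu))
            blocks.append(sp.csr_matrix(counts))
            obs_frames.append(
                pd.DataFrame(
                    {
                        "patient": patient,
                        "condition": cond,
                        "cell_type": [type_names[t] for t in types],
                        "clone_id": [
                            config.clones[c].clone_id if c >= 0 else "normal"
                            for c in clone_of
                        ],
                        "is_malignant": is_mal,
                        "cell_id": [f"{patient}-C{i + 1:04d}" for i in range(n)],
                    }
                ).set_index("cell_id")
            )

    obs = pd.concat(obs_frames)
    X = sp.vstack(blocks).tocsr()
    adata = ad.AnnData(X=X, obs=obs, var=genes.copy())

    diff_regions = []
    for clone in config.clones:
        ws = [clone.condition_weights.get(c, 0.0) for c in config.conditions]
        if not np.isclose(min(ws), max(ws)):
            for seg in clone.segments:
                diff_regions.append({"clone_id": clone.clone_id, **asdict(seg)})
    truth_genes = genes[["chromosome", "start", "end", "is_mito"]].copy()
    truth_genes["baseline_mean"] = lam  # planted per-gene rate, for validation
    truth = Truth(
        cells=obs.copy(),
        clones={c.clone_id: list(c.segments) for c in config.clones},
        genes=truth_genes,
        differential_regions=diff_regions,
    )
    return adata, truth


def make_null_config(config: SimConfig) -> SimConfig:
    """Copy of ``config`` with all condition-dependent effects equalized.

    Clone prevalences, cell-type compositions and malignant fractions are
    averaged across conditions, so no region or composition differs in
    expectation and condition labels are exchangeable downstream.
    """
    config.validate()
    conds = config.conditions
    cell_types = []
    for ct in config.cell_types:
        mean_p = float(np.mean([ct.proportion_by_condition.get(c, 0.0) for c in conds]))
        cell_types.append(
            CellTypeSpec(
                name=ct.name,
                proportion_by_condition={c: mean_p for c in conds},
                marker_genes_count=ct.marker_genes_count,
                marker_fold=ct.marker_fold,
            )
        )
    clones = []
    for clone in config.clones:
        mean_w = float(np.mean([clone.condition_weights.get(c, 0.0) for c in conds]))
        clones.append(
            CloneSpec(
                clone_id=clone.clone_id,
                condition_weights={c: mean_w for c in conds},
                segments=[Segment(**asdict(s)) for s in clone.segments],
            )
        )
    mean_mal = float(
        np.mean([config.malignant_fraction_by_condition.get(c, 0.0) for c in conds])
    )
    out = SimConfig(**{**asdict(config), "cell_types": [], "clones": []})
    out.cell_types = cell_types
    out.clones = clones
    out.malignant_fraction_by_condition = {c: mean_mal for c in conds}
    return out


def default_config(seed: int = 0) -> SimConfig:
    """A small cohort shaped like the study: epithelial (partly malignant),
    T cells (CNV reference), myeloid, B cells and fibroblasts, two clones with
    gains and losses, and a composition shift between conditions."""
    return SimConfig(
        n_patients_per_condition=4,
        cells_per_patient=300,
        n_chromosomes=6,
        genes_per_chromosome=120,
        cell_types=[
            CellTypeSpec("epithelial", {"primary": 0.35, "metastatic": 0.40}, 40, 3.0),
            CellTypeSpec("T cells", {"primary": 0.30, "metastatic": 0.22}, 40, 3.0),
            CellTypeSpec("myeloid", {"primary": 0.15, "metastatic": 0.08}, 40, 3.0),
            CellTypeSpec("B cells", {"primary": 0.10, "metastatic": 0.10}, 40, 3.0),
            CellTypeSpec("fibroblasts", {"primary": 0.10, "metastatic": 0.20}, 40, 3.0),
        ],
        clones=[
            CloneSpec(
                "cloneA",
                {"primary": 1.0, "metastatic": 0.2},
                [
                    Segment("chr1", 20, 69, 1.5),
                    Segment("chr3", 40, 89, 0.5),
                    Segment("chr6", 0, 49, 1.5),
                ],
            ),
            CloneSpec(
                "cloneB",
                {"primary": 0.2, "metastatic": 1.0},
                [
                    Segment("chr2", 10, 59, 2.0),
                    Segment("chr4", 60, 109, 1.5),
                    Segment("chr5", 30, 79, 0.5),
                ],
            ),
        ],
        malignant_fraction_by_condition={"primary": 0.8, "metastatic": 0.8},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# disk round trip (10x-style outputs)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def config_to_toml(config: SimConfig) -> str:
    """Serialize a SimConfig to TOML (readable back with tomllib)."""
    d = asdict(config)
    cell_types = d.pop("cell_types")
    clones = d.pop("clones")
    mal = d.pop("malignant_fraction_by_condition")
    lines = [f"{k} = {_toml_value(v)}" for k, v in d.items()]
    lines.append("")
    lines.append("[malignant_fraction_by_condition]")
    lines += [f"{json.dumps(k)} = {_toml_value(v)}" for k, v in mal.items()]
    for ct in cell_types:
        lines += ["", "[[cell_types]]"]
        for k, v in ct.items():
            if k == "proportion_by_condition":
                continue
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("[cell_types.proportion_by_condition]")
        lines += [f"{json.dumps(k)} = {_toml_value(v)}" for k, v in v_items(ct["proportion_by_condition"])]
    for cl in clones:
        lines += ["", "[[clones]]"]
        lines.append(f"clone_id = {_toml_value(cl['clone_id'])}")
        lines.append("[clones.condition_weights]")
        lines += [f"{json.dumps(k)} = {_toml_value(v)}" for k, v in v_items(cl["condition_weights"])]
        for seg in cl["segments"]:
            lines.append("[[clones.segments]]")
            lines += [f"{k} = {_toml_value(v)}" for k, v in seg.items()]
    return "\n".join(lines) + "\n"


def v_items(d: dict):
    return d.items()


def config_from_toml(path: str | Path) -> SimConfig:
    import tomllib

    with open(path, "rb") as fh:
        d = tomllib.load(fh)
    return SimConfig(**d)


def write_cohort(
    adata: ad.AnnData, truth: Truth, config: SimConfig, outdir: str | Path
) -> dict[str, Path]:
    """Write 10x-style text outputs: matrix.mtx (genes x cells, 1-based),
    features.tsv, barcodes.tsv, genes.bed (0-based half-open), metadata.tsv,
    truth.json and config.toml. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    X = sp.coo_matrix(adata.X.T)  # genes as rows on disk
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X, field="integer")
    paths["matrix"] = outdir / "matrix.mtx"
    feats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    paths["features"] = outdir / "features.tsv"
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    paths["barcodes"] = outdir / "barcodes.tsv"
    bed = adata.var.reset_index()[["chromosome", "start", "end", "gene_id"]]
    bed.to_csv(outdir / "genes.bed", sep="\t", header=False, index=False)
    paths["positions"] = outdir / "genes.bed"
    meta = adata.obs.reset_index()[
        ["cell_id", "patient", "condition", "cell_type", "clone_id", "is_malignant"]
    ]
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    paths["metadata"] = outdir / "metadata.tsv"
    truth.to_json(outdir / "truth.json")
    paths["truth"] = outdir / "truth.json"
    (outdir / "config.toml").write_text(config_to_toml(config))
    paths["config"] = outdir / "config.toml"
    return paths
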