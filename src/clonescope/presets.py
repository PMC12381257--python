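"""Benchmark cohort configurations with planted ground truth.

Each function returns a :class:`~clonescope.simulate.SimConfig` describing a
named validation scenario: cohorts whose planted clones, marker programs or
composition shifts exercise one capability of the package (malignant
calling, subclone recovery, region testing, heterogeneity scoring,
signature classification). The parameter values are the package's fixed
study conditions; tests and the reproduction script build on them.
"""

from __future__ import annotations

from .simulate import CellTypeSpec, CloneSpec, Segment, SimConfig, default_config  # noqa: F401

_BOTH = {"primary": 1.0, "metastatic": 1.0}


def _tumor_cohort(
    seed: int,
    clones: list[CloneSpec],
    cells_per_patient: int = 150,
    n_patients_per_condition: int = 1,
    epithelial: float = 0.6,
    malignant_fraction: float = 0.8,
    n_chromosomes: int = 6,
    genes_per_chromosome: int = 120,
) -> SimConfig:
    return SimConfig(
        n_patients_per_condition=n_patients_per_condition,
        cells_per_patient=cells_per_patient,
        n_chromosomes=n_chromosomes,
        genes_per_chromosome=genes_per_chromosome,
        cell_types=[
            CellTypeSpec("epithelial", {"primary": epithelial, "metastatic": epithelial}, 30, 3.0),
            CellTypeSpec("T cells", {"primary": 1 - epithelial, "metastatic": 1 - epithelial}, 30, 3.0),
        ],
        clones=clones,
        malignant_fraction_by_condition={
            "primary": malignant_fraction,
            "metastatic": malignant_fraction,
        },
        seed=seed,
    )


def malignant_calling_config(seed: int = 1) -> SimConfig:
    """~200 malignant / ~200 normal epithelial cells; one clone with three
    segments (two 1.5x gains, one 0.5x loss) on a two-lineage background."""
    clone = CloneSpec(
        "c1",
        dict(_BOTH),
        [Segment("chr1", 20, 69, 1.5), Segment("chr3", 40, 89, 0.5), Segment("chr5", 10, 59, 1.5)],
    )
    return _tumor_cohort(
        seed, [clone], cells_per_patient=290, epithelial=0.72, malignant_fraction=0.5
    )


def burden_contrast_config(seed: int = 1) -> SimConfig:
    """Four-segment clone (gains and losses) for CNV-burden contrasts."""
    clone = CloneSpec(
        "c1",
        dict(_BOTH),
        [
            Segment("chr1", 20, 69, 1.5),
            Segment("chr3", 40, 89, 0.5),
            Segment("chr5", 10, 59, 1.5),
            Segment("chr6", 50, 99, 0.5),
        ],
    )
    return _tumor_cohort(
        seed, [clone], cells_per_patient=290, epithelial=0.72, malignant_fraction=0.5
    )


def region_test_config(seed: int = 1, null: bool = False) -> SimConfig:
    """Two-condition cohort for the window permutation test.

    Condition "primary" carries a clone with three 40-gene 1.5x gains;
    "metastatic" carries a segment-free clone, so the planted windows
    differ between conditions. ``null=True`` is shorthand for running
    :func:`~clonescope.simulate.make_null_config` on the same cohort.
    """
    from .simulate import make_null_config

    clones = [
        CloneSpec(
            "cA",
            {"primary": 1.0, "metastatic": 0.0},
            [
                Segment("chr1", 40, 79, 1.5),
                Segment("chr5", 100, 139, 1.5),
                Segment("chr8", 0, 39, 1.5),
            ],
        ),
        CloneSpec("cB", {"primary": 0.0, "metastatic": 1.0}, []),
    ]
    cfg = _tumor_cohort(
        seed,
        clones,
        cells_per_patient=120,
        n_patients_per_condition=2,
        epithelial=0.7,
        malignant_fraction=0.9,
        n_chromosomes=10,
        genes_per_chromosome=200,
    )
    return make_null_config(cfg) if null else cfg


def subclone_config(seed: int = 1, n_clones: int = 2, cells_per_patient: int = 150) -> SimConfig:
    """One or two clones with disjoint gain+loss segments, one tumor."""
    clones = [
        CloneSpec("c1", dict(_BOTH), [Segment("chr1", 20, 69, 1.5), Segment("chr3", 40, 89, 0.5)]),
        CloneSpec("c2", dict(_BOTH), [Segment("chr2", 10, 59, 1.5), Segment("chr5", 30, 79, 0.5)]),
    ][:n_clones]
    return _tumor_cohort(seed, clones, cells_per_patient=cells_per_patient)


def ithgex_ladder_config(level: float, seed: int = 1) -> SimConfig:
    """Two clones whose divergence scales with ``level``.

    Each clone carries three disjoint segments at reciprocal copy ratios
    (1 + level and 1 / (1 + level)), keeping total counts balanced so the
    planted divergence is not confounded with library-size effects.
    """
    g, l = 1.0 + level, 1.0 / (1.0 + level)
    clones = [
        CloneSpec(
            "c1",
            dict(_BOTH),
            [Segment("chr1", 20, 69, g), Segment("chr4", 10, 59, l), Segment("chr3", 0, 49, g)],
        ),
        CloneSpec(
            "c2",
            dict(_BOTH),
            [Segment("chr2", 10, 59, g), Segment("chr6", 40, 89, l), Segment("chr5", 60, 109, g)],
        ),
    ]
    return _tumor_cohort(seed, clones)


def marker_programs_config(seed: int = 7, marker_fold: float = 3.0) -> SimConfig:
    """Three equally sized cell states with 60-gene marker programs."""
    third = 1 / 3
    return SimConfig(
        n_patients_per_condition=2,
        cells_per_patient=250,
        n_chromosomes=8,
        genes_per_chromosome=150,
        cell_types=[
            CellTypeSpec("stateA", {"primary": third, "metastatic": third}, 60, marker_fold),
            CellTypeSpec("stateB", {"primary": third, "metastatic": third}, 60, marker_fold),
            CellTypeSpec("stateC", {"primary": third, "metastatic": third}, 60, marker_fold),
        ],
        clones=[],
        malignant_fraction_by_condition={},
        malignant_cell_type="stateA",
        seed=seed,
    )


def composition_shift_config(seed: int = 1, shifted: bool = True) -> SimConfig:
    """Five lineages; myeloid drops 4% -> 0.5% in the metastatic condition
    (true log2FC = 3, comfortably past the |log2FC| > 2 rule)."""
    myeloid_met = 0.005 if shifted else 0.04
    rest_met = (1 - myeloid_met - 0.40 - 0.10) / 2
    return SimConfig(
        n_patients_per_condition=3,
        cells_per_patient=300,
        n_chromosomes=4,
        genes_per_chromosome=100,
        cell_types=[
            CellTypeSpec("epithelial", {"primary": 0.40, "metastatic": 0.40}, 20, 3.0),
            CellTypeSpec("T cells", {"primary": 0.25, "metastatic": rest_met}, 20, 3.0),
            CellTypeSpec("myeloid", {"primary": 0.04, "metastatic": myeloid_met}, 20, 3.0),
            CellTypeSpec("B cells", {"primary": 0.10, "metastatic": 0.10}, 20, 3.0),
            CellTypeSpec("fibroblasts", {"primary": 0.21, "metastatic": rest_met}, 20, 3.0),
        ],
        clones=[],
        malignant_fraction_by_condition={},
        seed=seed,
    )
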