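"""CNV inference, burden scoring, calling, subclones, windows, region test."""

import numpy as np
import pandas as pd
import pytest

from clonescope import cnv
from clonescope import presets
from clonescope.cnv import (
    CNVParams,
    CNVProfileMatrix,
    RegionTestParams,
    cnv_score,
    call_malignant,
    detect_subclones,
    infer_cnv_profiles,
    ithgex_score,
    make_gene_windows,
    region_group_test,
    region_overlap,
    arm_level_summary,
)
from clonescope.simulate import make_null_config, simulate_cohort
from clonescope.io import normalize_log

from conftest import analyzed_cohort, brute_force_cnv_oracle, make_expr_adata


def profile_from(values, chromosomes=None, is_reference=None):
    values = np.asarray(values, float)
    n, g = values.shape
    genes = pd.DataFrame(
        {
            "chromosome": chromosomes if chromosomes is not None else ["chr1"] * g,
            "start": np.arange(g) * 1000,
        },
        index=pd.Index([f"g{i:04d}" for i in range(g)], name="gene_id"),
    )
    return CNVProfileMatrix(
        values=values,
        genes=genes,
        cell_ids=pd.Index([f"c{i}" for i in range(n)]),
        is_reference=is_reference if is_reference is not None else np.zeros(n, bool),
    )


class TestInferProfiles:
    def test_matches_brute_force_oracle_elementwise(self):
        rng = np.random.default_rng(42)
        n, g = 40, 180
        X = rng.gamma(2.0, 1.0, size=(n, g))
        chroms = np.repeat(["chr1", "chr2", "chr3"], g // 3)
        starts = np.tile(np.arange(g // 3) * 500, 3)
        expr = make_expr_adata(np.log1p(X), chroms, starts)
        ref = np.zeros(n, bool)
        ref[:32] = True
        params = CNVParams(window_genes=21, min_mean_expression=0.0)
        P = infer_cnv_profiles(expr, ref, params)
        oracle, genes, ref_pre_clamp = brute_force_cnv_oracle(expr, ref, params)
        np.testing.assert_allclose(P.values, oracle, atol=1e-10)
        assert list(P.genes.index) == list(genes.index)
        # reference neutrality before clamping
        assert np.abs(ref_pre_clamp).max() < 1e-8

    def test_identical_cells_give_zero_profiles(self):
        X = np.tile(np.log1p(np.arange(1, 61, dtype=float)), (40, 1))
        expr = make_expr_adata(X)
        ref = np.zeros(40, bool)
        ref[:30] = True
        P = infer_cnv_profiles(expr, ref, CNVParams(window_genes=5, min_mean_expression=0.0))
        np.testing.assert_allclose(P.values, 0.0, atol=1e-12)

    def test_planted_gain_shows_in_carriers_only(self):
        """A 1.5x segment of 60 genes (window 21) lifts the segment interior
        in carrier cells while normal cells stay near zero."""
        rng = np.random.default_rng(0)
        n, g = 120, 200
        base = rng.gamma(5.0, 2.0, size=g)
        X = rng.poisson(base, size=(n, g)).astype(float)
        carriers = np.zeros(n, bool)
        carriers[60:] = True
        X[np.ix_(carriers, np.arange(70, 130))] *= 1.5
        expr = make_expr_adata(np.log1p(X))
        ref = np.zeros(n, bool)
        ref[:40] = True  # reference = normal cells
        P = infer_cnv_profiles(expr, ref, CNVParams(window_genes=21, min_mean_expression=0.0))
        interior = slice(85, 115)
        assert P.values[np.ix_(carriers, range(85, 115))].mean() > 0.1
        assert abs(P.values[np.ix_(~carriers, range(85, 115))].mean()) < 0.05

    def test_too_few_reference_cells_rejected(self):
        expr = make_expr_adata(np.ones((40, 30)))
        with pytest.raises(ValueError, match="reference cells"):
            infer_cnv_profiles(expr, np.zeros(40, bool), CNVParams())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            CNVParams(window_genes=10).validate()


class TestCnvScore:
    def test_closed_forms(self):
        assert cnv_score(profile_from(np.zeros((3, 10))))[0] == 0.0
        vals = np.zeros((1, 100))
        vals[0, :10] = 0.1
        assert cnv_score(profile_from(vals))[0] == pytest.approx(0.001)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 40))
        perm = rng.permutation(40)
        np.testing.assert_allclose(
            cnv_score(profile_from(vals)), cnv_score(profile_from(vals[:, perm]))
        )

    def test_score_increases_with_planted_segment_count(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 0.02, size=(1, 300))
        scores = []
        for k in (1, 2, 3):
            vals = base.copy()
            for s in range(k):
                vals[0, s * 100 : s * 100 + 40] += 0.3
            scores.append(cnv_score(profile_from(vals))[0])
        assert scores[0] < scores[1] < scores[2]


class TestMalignantCalling:
    def test_reference_cells_never_called_malignant(self):
        _, expr, truth, P = analyzed_cohort(presets.malignant_calling_config(seed=2))
        scores = cnv_score(P)
        epi = (expr.obs["cell_type"] == "epithelial").to_numpy()
        calls = call_malignant(P, scores, epi | P.is_reference, seed=0)
        assert (np.asarray(calls)[P.is_reference] == "normal").all()

    def test_cnv_free_cohort_yields_all_normal_with_warning(self, caplog):
        cfg = presets.malignant_calling_config(seed=3)
        cfg.clones = []
        _, expr, _, P = analyzed_cohort(cfg)
        epi = (expr.obs["cell_type"] == "epithelial").to_numpy()
        with caplog.at_level("WARNING"):
            calls = call_malignant(P, cnv_score(P), epi, seed=0)
        assert (np.asarray(calls) == "normal").all()
        assert any("not separated" in r.message for r in caplog.records)

    def test_too_few_candidates_rejected(self):
        P = profile_from(np.zeros((30, 10)))
        with pytest.raises(ValueError, match="candidate"):
            call_malignant(P, np.zeros(30), np.arange(30) < 5)


class TestSubclones:
    def test_identical_profiles_give_single_clone(self):
        P = profile_from(np.tile(np.linspace(-1, 1, 50), (25, 1)))
        labels = detect_subclones(P, np.ones(25, bool))
        assert len(np.unique(labels)) == 1

    def test_minimum_cell_count_enforced(self):
        P = profile_from(np.zeros((10, 5)))
        with pytest.raises(ValueError, match=">= 20"):
            detect_subclones(P, np.ones(10, bool))


class TestIthgex:
    def test_identical_cells_score_zero(self):
        X = np.tile(np.arange(1.0, 31.0), (15, 1))
        expr = make_expr_adata(X)
        assert ithgex_score(expr, np.ones(15, bool)) == 0.0

    def test_two_divergent_clones_score_higher_than_one(self):
        cfg2 = presets.ithgex_ladder_config(0.5, seed=4)
        cfg1 = presets.ithgex_ladder_config(0.5, seed=4)
        cfg1.clones = cfg1.clones[:1]
        a1, _ = simulate_cohort(cfg1)
        a2, _ = simulate_cohort(cfg2)
        e1, e2 = normalize_log(a1), normalize_log(a2)
        s1 = ithgex_score(e1, e1.obs["is_malignant"].to_numpy())
        s2 = ithgex_score(e2, e2.obs["is_malignant"].to_numpy())
        assert 0.0 < s1 < s2 < 2.0


class TestGeneWindows:
    @pytest.mark.parametrize(
        "n_genes,window,sizes",
        [(100, 25, [25, 25, 25, 25]), (105, 25, [25, 25, 25, 25, 5])],
    )
    def test_window_sizes(self, n_genes, window, sizes):
        genes = pd.DataFrame(
            {"chromosome": ["chr1"] * n_genes, "start": np.arange(n_genes) * 10}
        )
        regions = make_gene_windows(genes, window)
        assert regions["n_genes"].tolist() == sizes

    def test_windows_partition_genes(self):
        genes = pd.DataFrame(
            {
                "chromosome": np.repeat(["chr1", "chr2"], [37, 52]),
                "start": np.concatenate([np.arange(37), np.arange(52)]) * 10,
            }
        )
        regions = make_gene_windows(genes, 10)
        covered = []
        for r in regions.itertuples():
            covered.extend(range(r.start_idx, r.end_idx))
        assert sorted(covered) == list(range(89))
        assert len(covered) == len(set(covered))
        assert (regions.groupby("chromosome")["n_genes"].sum() == pd.Series({"chr1": 37, "chr2": 52})).all()


class TestRegionTest:
    def test_duplicated_groups_give_p_one(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(30, 40))
        P = profile_from(np.vstack([vals, vals]))
        labels = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        regions = make_gene_windows(P.genes, 10)
        tab = region_group_test(P, labels, regions, RegionTestParams(n_perm=200, seed=0))
        assert (tab["p_value"] == 1.0).all()
        assert (tab["statistic"] == 0.0).all()

    def test_single_condition_rejected(self):
        P = profile_from(np.zeros((10, 10)))
        with pytest.raises(ValueError, match="2 conditions"):
            region_group_test(
                P, np.array(["A"] * 10, dtype=object), make_gene_windows(P.genes, 5)
            )

    def test_patient_permutation_unit(self):
        _, expr, truth, P = analyzed_cohort(presets.region_test_config(seed=5), window_genes=21)
        regions = make_gene_windows(P.genes, 10)
        mal = expr.obs["is_malignant"].to_numpy()
        labels = np.where(mal, expr.obs["condition"].to_numpy(dtype=object), None)
        tab = region_group_test(
            P,
            labels,
            regions,
            RegionTestParams(n_perm=200, seed=0, permutation_unit="patient"),
            patient_labels=expr.obs["patient"].to_numpy(),
        )
        assert ((tab["p_value"] > 0) & (tab["p_value"] <= 1)).all()

    def test_seeded_runs_are_identical(self):
        rng = np.random.default_rng(4)
        P = profile_from(rng.normal(size=(60, 50)))
        labels = np.array(["A", "B"] * 30, dtype=object)
        regions = make_gene_windows(P.genes, 10)
        t1 = region_group_test(P, labels, regions, RegionTestParams(n_perm=300, seed=9))
        t2 = region_group_test(P, labels, regions, RegionTestParams(n_perm=300, seed=9))
        pd.testing.assert_frame_equal(t1, t2)

    def test_q_values_monotone_in_p(self):
        rng = np.random.default_rng(5)
        P = profile_from(rng.normal(size=(40, 60)))
        labels = np.array(["A", "B"] * 20, dtype=object)
        tab = region_group_test(
            P, labels, make_gene_windows(P.genes, 10), RegionTestParams(n_perm=200, seed=1)
        )
        s = tab.sort_values("p_value")
        assert (np.diff(s["q_value"].to_numpy()) >= -1e-12).all()


class TestOverlap:
    def make_table(self, sig):
        return pd.DataFrame(
            {"region_id": [f"r{i}" for i in range(len(sig))], "significant": sig}
        )

    def test_identical_and_disjoint_sets(self):
        A = self.make_table([True] * 5 + [False] * 5)
        assert region_overlap(A, A.copy(), "of_A") == 1.0
        B = self.make_table([False] * 5 + [True] * 5)
        assert region_overlap(A, B, "of_A") == 0.0
        assert region_overlap(A, B, "jaccard") == 0.0

    def test_partial_overlap_closed_form(self):
        A = self.make_table([True] * 10 + [False] * 10)
        sig_b = [True] * 7 + [False] * 3 + [True] * 3 + [False] * 7
        B = self.make_table(sig_b)
        assert region_overlap(A, B, "of_A") == pytest.approx(0.70)

    def test_empty_significant_set_undefined(self):
        A = self.make_table([False] * 4)
        B = self.make_table([True] * 4)
        with pytest.raises(ValueError, match="undefined"):
            region_overlap(A, B, "of_A")


class TestArmSummary:
    def arms_for(self, P):
        rows = []
        for chrom in pd.unique(P.genes["chromosome"]):
            s = P.genes.loc[P.genes["chromosome"] == chrom, "start"]
            mid = (s.min() + s.max()) / 2
            rows.append({"chromosome": chrom, "arm": "p", "start": 0, "end": mid})
            rows.append({"chromosome": chrom, "arm": "q", "start": mid, "end": s.max() + 1})
        return pd.DataFrame(rows)

    def test_neutral_profiles_give_zero_means(self):
        P = profile_from(np.zeros((20, 60)), chromosomes=["chr1"] * 30 + ["chr2"] * 30)
        groups = np.array(["A", "B"] * 10, dtype=object)
        tab = arm_level_summary(P, self.arms_for(P), groups)
        assert np.allclose(tab["specificity"], 0.0)

    def test_planted_arm_gain_ranks_first(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 0.02, size=(40, 120))
        groups = np.array(["met"] * 20 + ["prim"] * 20, dtype=object)
        vals[:20, 60:90] += 0.4  # chr2 p-arm gain in "met" only
        P = profile_from(vals, chromosomes=["chr1"] * 60 + ["chr2"] * 60)
        tab = arm_level_summary(P, self.arms_for(P), groups, n_top=25)
        assert tab.iloc[0]["chromosome"] == "chr2"
        assert tab.iloc[0]["arm"] == "p"
        assert tab.iloc[0]["direction"] == "gain"
        assert len(tab) <= 25
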