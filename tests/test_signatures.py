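"""Marker ranking, signature derivation, scoring, classification, pseudobulk."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import anndata as ad
from hypothesis import given, settings, strategies as hst

from clonescope.signatures import (
    GeneSet,
    auc_score,
    classify_by_signatures,
    derive_signature,
    mean_scaled_score,
    pseudobulk_de,
    rank_markers,
    read_gmt,
    read_weighted_set,
    state_coordinates,
    weighted_activity,
    write_gmt,
    write_weighted_set,
)


def expr_adata(X, gene_ids=None):
    X = np.asarray(X, float)
    n, g = X.shape
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=gene_ids or [f"g{i:03d}" for i in range(g)]),
    )


class TestRankMarkers:
    def test_exclusive_gene_ranks_first_with_positive_effect(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 20))
        X[:15, 5] += 5.0  # gene g005 only in group A
        labels = ["A"] * 15 + ["B"] * 15
        tabs = rank_markers(expr_adata(X), labels)
        top = tabs["A"].iloc[0]
        assert top["gene"] == "g005"
        assert top["log2fc"] > 0

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 300))
        labels = rng.permutation(["A"] * 100 + ["B"] * 100)
        tabs = rank_markers(expr_adata(X), labels)
        ks = st.kstest(tabs["A"]["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_small_group_skipped_with_warning(self, caplog):
        X = np.random.default_rng(2).random((10, 5))
        labels = ["A"] * 8 + ["B"] * 2
        with caplog.at_level("WARNING"):
            tabs = rank_markers(expr_adata(X), labels)
        assert "B" not in tabs and "A" in tabs


class TestDeriveSignature:
    def marker_table(self, n_up, n_down=0):
        genes = [f"g{i:03d}" for i in range(n_up + n_down)]
        return pd.DataFrame(
            {
                "gene": genes,
                "log2fc": [1.0] * n_up + [-1.0] * n_down,
                "p_value": np.linspace(1e-6, 0.04, n_up + n_down),
                "q_value": np.linspace(1e-5, 0.05, n_up + n_down),
            }
        )

    def test_exact_count_returned(self):
        s = derive_signature(self.marker_table(200), n_top=200)
        assert len(s.genes) == 200

    def test_insufficient_genes_error_states_count(self):
        with pytest.raises(ValueError, match="150 available"):
            derive_signature(self.marker_table(150), n_top=200)

    def test_ties_resolved_by_gene_id_stably(self):
        tab = self.marker_table(10)
        tab["p_value"] = 0.01
        tab["log2fc"] = 2.0
        s1 = derive_signature(tab, n_top=5)
        s2 = derive_signature(tab.sample(frac=1, random_state=3), n_top=5)
        assert s1.genes == s2.genes == sorted(tab["gene"])[:5]


class TestAucScore:
    def test_set_at_top_ranks_scores_one(self):
        g = 200
        X = np.zeros((1, g))
        X[0, :10] = np.arange(10, 0, -1) + 100.0
        gs = GeneSet("top", [f"g{i:03d}" for i in range(10)])
        score = auc_score(expr_adata(X), gs, top_fraction=0.1, seed=0)
        assert score[0] == pytest.approx(1.0)

    def test_scores_stay_in_unit_interval(self):
        rng = np.random.default_rng(4)
        X = rng.random((50, 100))
        gs = GeneSet("s", [f"g{i:03d}" for i in range(0, 100, 7)])
        sc = auc_score(expr_adata(X), gs, top_fraction=0.05, seed=0)
        assert ((sc >= 0) & (sc <= 1)).all()

    def test_promoting_a_set_gene_never_lowers_score(self):
        rng = np.random.default_rng(5)
        X = rng.random((1, 100))
        gs = GeneSet("s", ["g010", "g020", "g030"])
        base = auc_score(expr_adata(X), gs, top_fraction=0.2, seed=7)[0]
        X2 = X.copy()
        X2[0, 10] = X2.max() + 1.0
        boosted = auc_score(expr_adata(X2), gs, top_fraction=0.2, seed=7)[0]
        assert boosted >= base

    def test_missing_set_errors(self):
        X = np.random.default_rng(6).random((3, 10))
        with pytest.raises(ValueError, match="no gene of set"):
            auc_score(expr_adata(X), GeneSet("none", ["absent1", "absent2"]), 0.1)


class TestWeightedActivity:
    def test_matches_closed_form_regression_oracle(self):
        w = np.array([0.5, -1.2, 2.0, 0.0, 0.3, 1.1, -0.7, 0.9, 0.0, 1.5])
        x = np.array([1.2, 0.1, 3.4, 0.5, 0.7, 2.2, 0.05, 1.9, 0.3, 2.8])
        gs = GeneSet("w", [f"g{i:03d}" for i in range(10)], weights=list(w))
        act = weighted_activity(expr_adata(x[None, :]), gs)[0]
        lr = st.linregress(w, x)
        assert act == pytest.approx(lr.slope / lr.stderr, abs=1e-8)

    def test_expression_proportional_to_weights_gives_large_positive(self):
        w = np.linspace(-2, 2, 12)
        x = 0.5 + 3.0 * w
        gs = GeneSet("w", [f"g{i:03d}" for i in range(12)], weights=list(w))
        act = weighted_activity(expr_adata(x[None, :]), gs)[0]
        assert act > 1e3
        neg = weighted_activity(expr_adata((-x)[None, :]), gs)[0]
        assert neg < -1e3

    def test_permuted_weights_center_on_zero(self):
        rng = np.random.default_rng(8)
        n_cells, g = 500, 120
        X = rng.normal(size=(n_cells, g))
        w = rng.permutation(np.concatenate([rng.normal(size=40), np.zeros(80)]))
        gs = GeneSet("w", [f"g{i:03d}" for i in range(g)], weights=list(w))
        act = weighted_activity(expr_adata(X), gs)
        se = act.std(ddof=1) / math.sqrt(n_cells)
        assert abs(act.mean()) < 3 * se

    def test_constant_weights_rejected(self):
        gs = GeneSet("w", [f"g{i:03d}" for i in range(5)], weights=[1.0] * 5)
        with pytest.raises(ValueError, match="variance"):
            weighted_activity(expr_adata(np.random.default_rng(9).random((2, 5))), gs)


class TestClassify:
    def test_argmax_label_and_margin(self):
        scores = pd.DataFrame(
            [[0.9, 0.1, 0.2], [0.5, 0.5, 0.1]], columns=["A", "B", "C"], index=["c0", "c1"]
        )
        res = classify_by_signatures(scores)
        assert res.labels["c0"] == "A"
        assert res.margin["c0"] == pytest.approx(0.7)
        assert not res.tie["c0"]
        assert res.labels["c1"] == "A"  # tie broken by column order
        assert res.margin["c1"] == 0.0
        assert res.tie["c1"]

    def test_mean_scaled_scorer_shares_classifier(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 30))
        X[:20, :10] += 2.0
        X[20:, 10:20] += 2.0
        adata = expr_adata(X)
        sa = GeneSet("A", [f"g{i:03d}" for i in range(10)])
        sb = GeneSet("B", [f"g{i:03d}" for i in range(10, 20)])
        scores = pd.DataFrame(
            {"A": mean_scaled_score(adata, sa), "B": mean_scaled_score(adata, sb)},
            index=adata.obs_names,
        )
        res = classify_by_signatures(scores)
        assert (res.labels[:20] == "A").all() and (res.labels[20:] == "B").all()


class TestPseudobulk:
    def counts(self, rng, n_cells, g, boost=None):
        X = rng.poisson(5.0, size=(n_cells, g)).astype(float)
        if boost is not None:
            X[:, boost] *= 2.0
        return X

    def test_identical_samples_give_zero_logfc(self):
        rng = np.random.default_rng(11)
        block = self.counts(rng, 20, 30)
        X = np.vstack([block, block, block, block])
        samples = np.repeat(["s1", "s2", "s3", "s4"], 20)
        conds = np.repeat(["A", "A", "B", "B"], 20)
        tab = pseudobulk_de(expr_adata(X), samples, conds)
        np.testing.assert_allclose(tab["log2fc"], 0.0, atol=1e-12)

    def test_planted_twofold_gene_recovers_unit_log2fc(self):
        rng = np.random.default_rng(12)
        blocks, samples, conds = [], [], []
        for i in range(4):
            blocks.append(self.counts(rng, 400, 60, boost=7))
            samples += [f"a{i}"] * 400
            conds += ["A"] * 400
        for i in range(4):
            blocks.append(self.counts(rng, 400, 60))
            samples += [f"b{i}"] * 400
            conds += ["B"] * 400
        tab = pseudobulk_de(expr_adata(np.vstack(blocks)), samples, conds)
        row = tab[tab["gene"] == "g007"].iloc[0]
        assert row["log2fc"] == pytest.approx(1.0, abs=0.15)
        assert tab.iloc[0]["gene"] == "g007"

    def test_single_sample_condition_rejected(self):
        X = np.random.default_rng(13).poisson(5, size=(30, 10)).astype(float)
        samples = np.repeat(["s1", "s2", "s3"], 10)
        conds = np.repeat(["A", "A", "B"], 10)
        with pytest.raises(ValueError, match="single sample"):
            pseudobulk_de(expr_adata(X), samples, conds)


class TestStateCoordinates:
    def test_two_and_four_signature_axes(self):
        scores = pd.DataFrame(
            [[0.2, 0.8, 0.5, 0.5]], columns=["w", "x", "y", "z"], index=["c0"]
        )
        two = state_coordinates(scores, ["w", "x"])
        assert two.loc["c0"].tolist() == pytest.approx([0.2, 0.8])
        four = state_coordinates(scores, ["y", "z", "y", "z"])
        assert four.loc["c0"].tolist() == pytest.approx([0.0, 0.0])
        a = state_coordinates(scores, ["w", "x", "y", "z"])
        b = state_coordinates(scores, ["x", "w", "y", "z"])
        assert a.loc["c0", "x"] == pytest.approx(-b.loc["c0", "x"])

    def test_unknown_signature_rejected(self):
        scores = pd.DataFrame([[0.1]], columns=["A"], index=["c0"])
        with pytest.raises(ValueError, match="unknown"):
            state_coordinates(scores, ["A", "missing"])


class TestGeneSetIO:
    def test_gmt_roundtrip(self, tmp_path):
        sets = [GeneSet("s1", ["a", "b", "c"]), GeneSet("s2", ["d", "e"])]
        write_gmt(sets, tmp_path / "x.gmt")
        back = read_gmt(tmp_path / "x.gmt")
        assert [(s.name, s.genes) for s in back] == [(s.name, s.genes) for s in sets]

    def test_weighted_set_roundtrip(self, tmp_path):
        s = GeneSet("w", ["a", "b", "c"], weights=[0.5, -1.0, 2.0])
        write_weighted_set(s, tmp_path / "w.tsv")
        back = read_weighted_set(tmp_path / "w.tsv", name="w")
        assert back.genes == s.genes
        assert back.weights == pytest.approx(s.weights)

    def test_duplicate_members_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneSet("bad", ["a", "a"])


@settings(max_examples=20, deadline=None)
@given(hst.integers(0, 2**31 - 1))
def test_auc_score_deterministic_per_seed(seed):
    rng = np.random.default_rng(17)
    X = rng.random((5, 40))
    adata = expr_adata(X)
    gs = GeneSet("s", [f"g{i:03d}" for i in range(0, 40, 5)])
    s1 = auc_score(adata, gs, top_fraction=0.25, seed=seed)
    s2 = auc_score(adata, gs, top_fraction=0.25, seed=seed)
    np.testing.assert_array_equal(s1, s2)
    assert ((s1 >= 0) & (s1 <= 1)).all()
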