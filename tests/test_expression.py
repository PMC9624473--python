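"""QC, normalization, occupancy, and cross-cohort DEG consolidation."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonolink import expression as xp


def make_adata(X, genes=None, obs=None):
    X = np.asarray(X)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    obs = obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    return ad.AnnData(
        X=X.astype(np.int32),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


class TestQCFilter:
    def test_feature_and_mito_rules_are_strict(self):
        n_genes = 600
        X = np.ones((3, n_genes), dtype=int)
        X[0, 499:] = 0               # 499 detected features -> removed
        # cell 1: exactly 10.0% mito -> kept; cell 2: 5% mito -> kept
        genes = [f"g{i}" for i in range(n_genes - 60)] + [
            f"mt-{i}" for i in range(60)
        ]
        X[1, :] = 1                  # 60/600 = 10.0% mito
        X[2, -60:] = 0
        X[2, :30] = 2                # dilute; mito share 0/... -> small
        adata = make_adata(X, genes=genes)
        kept, tally = xp.qc_filter(adata, min_features=500, max_mito=0.10)
        assert tally == {"kept": 2, "low_features": 1, "high_mito": 0}
        assert "c0" not in kept.obs_names

    def test_high_mito_removed(self):
        genes = ["g0", "g1", "mt-0"]
        X = np.array([[500, 400, 101], [500, 500, 100]])
        adata = make_adata(X, genes=genes)
        kept, tally = xp.qc_filter(adata, min_features=2, max_mito=0.10)
        assert tally["high_mito"] == 1
        assert kept.n_obs == 1

    def test_no_mito_genes_warns_and_skips_rule(self):
        adata = make_adata(np.ones((2, 5), dtype=int))
        with pytest.warns(UserWarning, match="mitochondrial"):
            kept, tally = xp.qc_filter(adata, min_features=2, max_mito=0.10)
        assert kept.n_obs == 2

    def test_planted_violators_removed_from_synthetic_data(self, tiny_adata, tiny_config):
        # thresholds scaled to the reduced gene universe of the fixture
        kept, tally = xp.qc_filter(
            tiny_adata, min_features=int(tiny_config.n_genes * 0.5),
            max_mito=0.10,
        )
        planted = (tiny_adata.obs["qc_planted"] != "").sum()
        removed = tally["low_features"] + tally["high_mito"]
        assert removed >= 0.8 * planted
        assert (kept.obs["qc_planted"] == "").mean() > 0.99


class TestNormalize:
    def test_formula(self):
        X = np.array([[100, 0], [50, 50]])
        adata = make_adata(X)
        xp.normalize(adata)
        layer = adata.layers["lognorm"]
        assert layer[0, 0] == pytest.approx(np.log(1 + 1e4))
        assert layer[0, 1] == 0.0
        assert layer[1, 0] == pytest.approx(np.log(1 + 5e3))

    def test_monotone_within_cell(self):
        X = np.array([[1, 5, 10, 0]])
        adata = make_adata(X)
        xp.normalize(adata)
        vals = adata.layers["lognorm"][0]
        assert vals[3] < vals[0] < vals[1] < vals[2]

    def test_zero_total_cell_rejected(self):
        adata = make_adata(np.array([[0, 0], [1, 1]]))
        with pytest.raises(ValueError):
            xp.normalize(adata)


def occupancy_obs(assignments):
    """assignments: list of (clonotype, cluster[, group])."""
    rows = []
    for i, a in enumerate(assignments):
        rows.append(
            {
                "barcode": f"b{i}", "clonotype_key": a[0],
                "cluster_label": a[1],
                "group": a[2] if len(a) > 2 else "R",
                "sample_id": "S1",
            }
        )
    return pd.DataFrame(rows)


class TestOccupancy:
    def test_cluster_distribution_rows_sum_to_hundred(self, tiny_adata):
        dist = xp.cluster_distribution(tiny_adata.obs)
        assert np.allclose(dist.sum(axis=1), 100.0, atol=1e-9)

    def test_single_cluster_sample(self):
        obs = occupancy_obs([("c1", "A6")] * 4)
        dist = xp.cluster_distribution(obs)
        assert dist.loc["S1", "A6"] == 100.0

    def test_clonotype_split(self):
        obs = occupancy_obs([("c1", "A6")] * 6 + [("c1", "A5")] * 4)
        occ = xp.clonotype_occupancy(obs, ["c1"])
        assert occ.loc["c1", "A6"] == pytest.approx(60.0)
        assert occ.loc["c1", "A5"] == pytest.approx(40.0)

    def test_min_cells_filter(self):
        obs = occupancy_obs([("big", "A6")] * 40 + [("small", "A6")] * 39)
        with pytest.warns(UserWarning):
            occ = xp.clonotype_occupancy(obs, ["big", "small"], min_cells=40)
        assert list(occ.index) == ["big"]

    def test_log10_display_masks_zero(self):
        occ = pd.DataFrame({"A6": [100.0], "A5": [0.0]}, index=["c1"])
        disp = xp.log10_occupancy(occ)
        assert disp.loc["c1", "A6"] == pytest.approx(2.0)
        assert np.isnan(disp.loc["c1", "A5"])

    def test_compare_identical_gives_p_one(self):
        occ = pd.DataFrame({"A6": [50.0, 60.0, 70.0]})
        comp = xp.occupancy_compare(occ, occ.copy())
        assert comp.loc["A6", "p"] == 1.0

    def test_compare_complete_separation_exact(self):
        occ_r = pd.DataFrame({"A5": [90.0, 85.0, 80.0]})
        occ_nr = pd.DataFrame({"A5": [10.0, 15.0, 20.0]})
        comp = xp.occupancy_compare(occ_r, occ_nr)
        assert comp.loc["A5", "p"] == pytest.approx(0.1, abs=1e-12)

    def test_compare_requires_three_per_side(self):
        occ = pd.DataFrame({"A6": [50.0, 60.0]})
        with pytest.raises(ValueError):
            xp.occupancy_compare(occ, occ)

    def test_cluster_ratio(self):
        occ = pd.DataFrame(
            {"A6": [60.0, 0.0, 30.0], "A5": [40.0, 40.0, 0.0]},
            index=["a", "b", "c"],
        )
        ratio = xp.cluster_ratio(occ)
        assert ratio["a"] == pytest.approx(1.5)
        assert ratio["b"] == 0.0
        assert np.isnan(ratio["c"])

    def test_shared_profile_min_cells_boundary(self):
        obs = occupancy_obs(
            [("s1", "A6", "R")] * 25 + [("s1", "A5", "NR")] * 19
        )
        prof = xp.shared_clonotype_profile(obs, ["s1"], min_cells=20)
        assert prof.empty
        prof = xp.shared_clonotype_profile(obs, ["s1"], min_cells=19)
        assert set(prof.index.get_level_values("group")) == {"R", "NR"}

    def test_shared_profile_empty_when_no_shared(self):
        obs = occupancy_obs([("c1", "A6", "R")] * 30)
        assert xp.shared_clonotype_profile(obs, [], min_cells=1).empty

    def test_occupancy_rows_sum_to_hundred(self, tiny_adata, tiny_data):
        _, truth = tiny_data
        til = tiny_adata.obs[tiny_adata.obs["compartment"] == "TIL"]
        occ = xp.clonotype_occupancy(til, truth.r_top | truth.nr_top)
        assert np.allclose(occ.sum(axis=1), 100.0, atol=1e-9)


class TestFCTransform:
    def test_reference_points(self):
        assert xp.fc_transform(np.log(2)) == pytest.approx(2.0)
        assert xp.fc_transform(-np.log(2)) == pytest.approx(-2.0)
        assert xp.fc_transform(0.0) == 1.0

    @given(st.floats(min_value=0.001, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_magnitude(self, x):
        assert xp.fc_transform(-x) == pytest.approx(-xp.fc_transform(x))
        assert abs(xp.fc_transform(x)) >= 1.0
        assert abs(xp.fc_transform(-x)) >= 1.0


class TestConsolidation:
    def records(self):
        return pd.DataFrame(
            {
                "gene": ["g1"] * 4 + ["g2"] * 2 + ["g3"],
                "cohort_id": [1, 2, 3, 4, 1, 2, 3],
                "ln_fc": [0.5, 0.7, 0.6, 0.6, 0.5, 0.7, -0.2],
                "p": [0.01, 0.2, 0.03, 0.04, 0.5, 0.001, 0.9],
            }
        )

    def test_most_conservative_p_is_maximum(self):
        cons = xp.consolidate_deg(self.records()).set_index("gene")
        assert cons.loc["g1", "p_conservative"] == 0.2
        assert cons.loc["g2", "p_conservative"] == 0.5

    def test_mean_ln_fc(self):
        cons = xp.consolidate_deg(self.records()).set_index("gene")
        assert cons.loc["g2", "ln_fc_mean"] == pytest.approx(0.6)

    def test_single_cohort_passthrough(self):
        cons = xp.consolidate_deg(self.records()).set_index("gene")
        assert cons.loc["g3", "p_conservative"] == 0.9
        assert cons.loc["g3", "ln_fc_mean"] == pytest.approx(-0.2)
        assert cons.loc["g3", "n_cohorts"] == 1

    def test_cohort_order_invariance(self):
        rec = self.records()
        shuffled = rec.sample(frac=1, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            xp.consolidate_deg(rec), xp.consolidate_deg(shuffled)
        )

    def test_p_conservative_dominates_every_cohort(self):
        rec = self.records()
        cons = xp.consolidate_deg(rec).set_index("gene")
        for gene, block in rec.groupby("gene"):
            assert (cons.loc[gene, "p_conservative"] >= block["p"]).all()

    def test_fold_change_sign_matches_mean(self):
        cons = xp.consolidate_deg(self.records()).set_index("gene")
        assert cons.loc["g1", "fold_change"] > 1
        assert cons.loc["g3", "fold_change"] < 0


class TestDEG:
    def normalized_adata(self, X, obs):
        adata = make_adata(X, obs=obs)
        xp.normalize(adata)
        return adata

    def test_identical_arms_give_null_result(self):
        X = np.tile(np.array([[5, 1, 0], [5, 1, 0]]), (3, 1))
        obs = pd.DataFrame({"arm": ["a", "b", "a", "b", "a", "b"]},
                           index=[f"c{i}" for i in range(6)])
        adata = self.normalized_adata(X, obs)
        rec = xp.deg_per_cohort(
            adata, (obs["arm"] == "a").to_numpy(),
            (obs["arm"] == "b").to_numpy(), 1,
        )
        assert np.allclose(rec["ln_fc"], 0.0)
        assert (rec["p"] == 1.0).all()

    def test_gene_only_in_one_arm_has_positive_lnfc(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(20, 4))
        X[:10, 0] += 10
        X[10:, 0] = 0
        obs = pd.DataFrame({"arm": ["a"] * 10 + ["b"] * 10},
                           index=[f"c{i}" for i in range(20)])
        adata = self.normalized_adata(X, obs)
        rec = xp.deg_per_cohort(
            adata, (obs["arm"] == "a").to_numpy(),
            (obs["arm"] == "b").to_numpy(), 1,
        ).set_index("gene")
        assert rec.loc["g0", "ln_fc"] > 0
        assert rec.loc["g0", "p"] < 0.01

    def test_small_arm_warns_and_skips(self):
        X = np.ones((4, 3), dtype=int)
        obs = pd.DataFrame({"arm": ["a", "a", "b", "b"]},
                           index=[f"c{i}" for i in range(4)])
        adata = self.normalized_adata(X, obs)
        with pytest.warns(UserWarning, match="arm too small"):
            rec = xp.deg_per_cohort(
                adata, (obs["arm"] == "a").to_numpy(),
                (obs["arm"] == "b").to_numpy(), 1, min_cells=3,
            )
        assert rec.empty

    def test_comparisons_iii_iv_antisymmetric(self, tiny_adata, tiny_data):
        _, truth = tiny_data
        adata = tiny_adata.copy()
        xp.normalize(adata)
        results = xp.deg_comparisons(adata, truth.r_top, truth.nr_top)
        iii = results["III"].set_index("gene")["ln_fc_mean"]
        iv = results["IV"].set_index("gene")["ln_fc_mean"]
        common = iii.index.intersection(iv.index)
        assert np.allclose(iii[common], -iv[common], atol=1e-12)

    def test_planted_gene_positive_in_i_and_iii(self, tiny_adata, tiny_data):
        _, truth = tiny_data
        adata = tiny_adata.copy()
        xp.normalize(adata)
        results = xp.deg_comparisons(adata, truth.r_top, truth.nr_top)
        for name in ("I", "III"):
            cons = results[name].set_index("gene")
            planted = [g for g in truth.planted_deg if g in cons.index]
            assert planted
            frac_up = (cons.loc[planted, "fold_change"] > 1).mean()
            assert frac_up >= 0.8

    def test_differential_gene_filter_threshold(self):
        cons_r = pd.DataFrame({"gene": ["g1", "g2"], "fold_change": [2.0, 1.1]})
        cons_nr = pd.DataFrame({"gene": ["g1", "g2"], "fold_change": [1.2, 1.0]})
        out = xp.differential_gene_filter(cons_r, cons_nr, min_diff=0.4)
        assert list(out.index) == ["g1"]
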