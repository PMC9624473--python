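"""Overlap, binned abundance, V-J usage, K-means, exclusivity test."""

import numpy as np
import pandas as pd
import pytest

from clonolink import repertoire as rep
from clonolink import synth
from tests.test_clonotypes import make_cells, toy_tables


class TestOverlap:
    def test_identity_is_one(self):
        assert rep.overlap_coefficient({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_is_zero(self):
        assert rep.overlap_coefficient({"a"}, {"b"}) == 0.0

    def test_formula(self):
        a = set("abcde")
        b = set("abcfghijkl")
        assert rep.overlap_coefficient(a, b) == pytest.approx(3 / 5)

    def test_both_empty_is_missing_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(rep.overlap_coefficient(set(), set()))

    def test_matrix_symmetric_with_unit_diagonal(self):
        sets = {"s1": {"a", "b"}, "s2": {"b", "c"}, "s3": {"x"}}
        mat = rep.overlap_matrix(sets)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert (np.diag(mat.to_numpy()) == 1.0).all()

    def test_disjoint_samples_give_zero_offdiagonal(self):
        sets = {"s1": {"a"}, "s2": {"b"}, "s3": {"c"}}
        mat = rep.overlap_matrix(sets)
        off = mat.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off == 0.0).all()

    def test_sample_order_permutes_consistently(self):
        sets = {"s1": {"a", "b"}, "s2": {"b"}, "s3": {"a", "c"}}
        m1 = rep.overlap_matrix(sets)
        m2 = rep.overlap_matrix({k: sets[k] for k in ["s3", "s1", "s2"]})
        pd.testing.assert_frame_equal(
            m1.loc[m2.index, m2.columns], m2
        )

    def test_within_mouse_exceeds_cross_mouse(self, tiny_tables):
        # TIL and spleen of one mouse share its expanded clonotypes
        sets = rep.sample_clonotype_sets(tiny_tables)
        mat = rep.overlap_matrix(sets)
        within = mat.loc["RTIL1", "RSP1"]
        cross = mat.loc["RTIL1", "NRSP2"]
        assert within > cross


class TestRelativeClonalAbundance:
    BINS = ((0.0, 0.01), (0.01, 1.0))

    def test_single_dominant_clonotype(self):
        table = toy_tables({"s": [100.0]})["s"]
        out = rep.relative_clonal_abundance(table, self.BINS)
        assert out.loc["(0.01, 1]", "n_clonotypes"] == 1
        assert out.loc["(0.01, 1]", "cell_share"] == pytest.approx(1.0)

    def test_uniform_singletons_fall_in_first_bin(self):
        table = pd.DataFrame(
            {
                "clonotype_key": [f"k{i}" for i in range(1000)],
                "cell_count": 1,
                "percent": 0.1,
            }
        )
        out = rep.relative_clonal_abundance(table, self.BINS)
        assert out.loc["(0, 0.01]", "n_clonotypes"] == 1000

    def test_shares_conserved(self, tiny_tables):
        for table in tiny_tables.values():
            out = rep.relative_clonal_abundance(table)
            assert out["cell_share"].sum() == pytest.approx(1.0, abs=1e-9)
            assert out["n_clonotypes"].sum() == len(table)

    @pytest.mark.parametrize(
        "bins",
        [
            ((0.0, 0.5), (0.4, 1.0)),     # overlap
            ((0.0, 0.4), (0.5, 1.0)),     # gap
            ((0.1, 0.5), (0.5, 1.0)),     # does not start at 0
            ((0.5, 0.5),),                # empty bin
        ],
    )
    def test_bad_bins_rejected(self, bins):
        table = toy_tables({"s": [100.0]})["s"]
        with pytest.raises(ValueError):
            rep.relative_clonal_abundance(table, bins)


class TestVJUsage:
    def test_single_pair(self):
        cells = make_cells([("b1", "S", "AAA", "K", "CCC", "T")])
        mat = rep.vj_usage(cells, "TRB")
        assert mat.loc["TRBV1", "TRBJ1-1"] == 1.0

    def test_even_split(self):
        cells = make_cells([
            ("b1", "S", "AAA", "K", "CCC", "T"),
            ("b2", "S", "GGG", "G", "CCC", "T"),
        ])
        cells.loc[1, ["trb_v", "trb_j"]] = ["TRBV2", "TRBJ2-2"]
        mat = rep.vj_usage(cells, "TRB")
        assert mat.loc["TRBV1", "TRBJ1-1"] == 0.5
        assert mat.loc["TRBV2", "TRBJ2-2"] == 0.5

    def test_dual_alpha_half_weight(self):
        cells = make_cells([
            ("b1", "S", "AAA", "K", "CCC", "T", "GGG", "W"),
        ])
        mat = rep.vj_usage(cells, "TRA")
        assert mat.loc["TRAV1", "TRAJ1"] == 0.5
        assert mat.loc["TRAV2", "TRAJ2"] == 0.5

    def test_proportions_sum_to_one_and_reorder_invariant(self, tiny_cells):
        sample = tiny_cells[tiny_cells["sample_id"] == "RTIL1"]
        for chain in ("TRA", "TRB"):
            mat = rep.vj_usage(sample, chain)
            assert mat.to_numpy().sum() == pytest.approx(1.0, abs=1e-9)
            shuffled = rep.vj_usage(sample.sample(frac=1, random_state=0), chain)
            pd.testing.assert_frame_equal(mat, shuffled)


class TestKMeansUsage:
    def test_duplicate_samples_co_cluster(self):
        usage = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.1, 0.9]],
            index=["a1", "a2", "b1", "b2"],
        )
        labels = rep.kmeans_usage(usage, k=2, seed=0)
        assert labels["a1"] == labels["a2"]
        assert labels["b1"] == labels["b2"]
        assert labels["a1"] != labels["b1"]

    def test_k_equals_n_gives_singletons(self):
        usage = pd.DataFrame(np.eye(4), index=list("abcd"))
        labels = rep.kmeans_usage(usage, k=4, seed=0)
        assert labels.nunique() == 4

    def test_k_larger_than_samples_rejected(self):
        usage = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError):
            rep.kmeans_usage(usage, k=4, seed=0)

    def test_separates_skewed_tils_from_uniform_spleens(self):
        # strong clonal expansion concentrates TIL beta-V usage on the top
        # clonotypes' V genes while spleens stay near-uniform
        import io

        from clonolink import vdj

        cfg = synth.SyntheticConfig(
            n_mice_per_group=2, n_cells_til=600, n_cells_spleen=300,
            n_top_clonotypes=8, top_abundance_range=(5.0, 15.0),
            n_tail_clonotypes=150,
        )
        tables, _ = synth.generate_repertoire(cfg, seed=13)
        frames = []
        for s, t in tables.items():
            cells, _ = vdj.assemble_cells(
                vdj.filter_contigs(
                    vdj.read_contigs(io.StringIO(t.to_csv(index=False)), s)
                )
            )
            frames.append(cells)
        allc = pd.concat(frames, ignore_index=True)
        by_sample = {
            s: allc[allc["sample_id"] == s] for s in allc["sample_id"].unique()
        }
        usage = rep.trbv_usage_vectors(by_sample)
        hits = 0
        runs = 20
        for seed in range(runs):
            labels = rep.kmeans_usage(usage, k=2, seed=seed)
            spleen = labels[[s for s in labels.index if "SP" in s]]
            if spleen.nunique() == 1:
                hits += 1
        assert hits >= 0.9 * runs


class TestExclusivity:
    def test_perfectly_exclusive_three_detections(self):
        # one top clonotype per group, detected only in its own 3 samples
        tr = {f"R{i}": toy_tables({"x": [5.0]})["x"].assign(
            clonotype_key="RTOP|A") for i in range(3)}
        tnr = {f"N{i}": toy_tables({"x": [5.0]})["x"].assign(
            clonotype_key="NRTOP|A") for i in range(3)}
        res = rep.exclusivity_test({"RTOP|A"}, {"NRTOP|A"}, tr, tnr)
        assert res.table.tolist() == [[3, 0], [0, 3]]
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_symmetric_detections_give_p_one(self):
        both = pd.DataFrame(
            {"clonotype_key": ["A|x", "B|x"], "cell_count": [5, 5],
             "percent": [50.0, 50.0]}
        )
        tr = {f"R{i}": both for i in range(5)}
        tnr = {f"N{i}": both for i in range(5)}
        res = rep.exclusivity_test({"A|x"}, {"B|x"}, tr, tnr)
        assert res.table.tolist() == [[5, 5], [5, 5]]
        assert res.p == 1.0

    def test_clonotype_unit_caps_detections_at_one_per_group(self):
        tr = {f"R{i}": toy_tables({"x": [5.0]})["x"].assign(
            clonotype_key="RTOP|A") for i in range(3)}
        tnr = {f"N{i}": toy_tables({"x": [5.0]})["x"].assign(
            clonotype_key="NRTOP|A") for i in range(3)}
        res = rep.exclusivity_test(
            {"RTOP|A"}, {"NRTOP|A"}, tr, tnr, unit="clonotypes"
        )
        assert res.table.tolist() == [[1, 0], [0, 1]]

    def test_empty_top_set_rejected(self):
        t = {"R1": toy_tables({"x": [5.0]})["x"]}
        with pytest.raises(ValueError):
            rep.exclusivity_test(set(), {"K0|A"}, t, t)

    def test_planted_disjoint_pools_detected(self, tiny_data, tiny_tables):
        _, truth = tiny_data
        tr = {s: t for s, t in tiny_tables.items() if s.startswith("RTIL")}
        tnr = {s: t for s, t in tiny_tables.items() if s.startswith("NRTIL")}
        res = rep.exclusivity_test(truth.r_top, truth.nr_top, tr, tnr)
        assert res.p < 0.001
        assert res.odds_ratio > 1
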