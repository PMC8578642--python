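"""Profile-matrix construction, clade selection and gene ages."""

import numpy as np
import pandas as pd
import pytest

from mlpp.profiles import (
    binarize_by_evalue,
    build_bitscore_matrix,
    clades_from_taxonomy,
    gene_age_category,
    mask_species,
    select_clades,
    self_hit_normalize,
    threshold_bitscores,
)


def hits_df(rows):
    return pd.DataFrame(rows, columns=["gene", "species", "bitscore", "evalue"])


class TestBitscoreMatrix:
    def test_absent_hits_are_zero(self):
        hits = hits_df([("g1", "s1", 120.0, 1e-30), ("g1", "s2", 80.0, 1e-10)])
        m = build_bitscore_matrix(hits, ["g1"], ["s1", "s2", "s3"])
        assert m.loc["g1"].tolist() == [120.0, 80.0, 0.0]

    def test_duplicate_hits_keep_max(self):
        hits = hits_df([("g1", "s1", 120.0, 0.0), ("g1", "s1", 90.0, 0.0)])
        m = build_bitscore_matrix(hits, ["g1"], ["s1"])
        # oracle: max-reduction over the record list
        assert m.loc["g1", "s1"] == 120.0

    def test_empty_table_gives_zero_matrix(self):
        m = build_bitscore_matrix(hits_df([]), ["g1", "g2"], ["s1"])
        assert (m.to_numpy() == 0).all() and m.shape == (2, 1)

    def test_unknown_ids_rejected_with_offender(self):
        hits = hits_df([("gX", "s1", 10.0, 1.0)])
        with pytest.raises(ValueError, match="gX"):
            build_bitscore_matrix(hits, ["g1"], ["s1"])


class TestThreshold:
    @pytest.mark.parametrize("value,expected", [(59.0, 0.0), (60.0, 60.0),
                                                (61.0, 61.0)])
    def test_strictly_below_60_zeroed(self, value, expected):
        m = pd.DataFrame([[value]], index=["g"], columns=["s"])
        assert threshold_bitscores(m).iloc[0, 0] == expected

    def test_zero_threshold_is_identity(self, rng):
        m = pd.DataFrame(rng.random((4, 5)) * 100)
        pd.testing.assert_frame_equal(threshold_bitscores(m, 0.0), m)

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.random((6, 8)) * 150)
        once = threshold_bitscores(m)
        pd.testing.assert_frame_equal(threshold_bitscores(once), once)


class TestSelfHitNormalize:
    def test_row_division(self):
        m = pd.DataFrame([[120.0, 60.0, 0.0]], index=["g1"], columns=list("abc"))
        out = self_hit_normalize(m, {"g1": 120.0})
        assert out.loc["g1"].tolist() == [1.0, 0.5, 0.0]

    def test_self_hit_above_entries_bounds_row_at_one(self, rng):
        vals = rng.random((5, 6)) * 100
        m = pd.DataFrame(vals, index=[f"g{i}" for i in range(5)])
        selfh = {f"g{i}": vals[i].max() for i in range(5)}
        out = self_hit_normalize(m, selfh)
        assert np.isclose(out.max(axis=1), 1.0).all()
        assert (out.to_numpy() >= 0).all()

    def test_missing_self_hit_drops_row_with_warning(self):
        m = pd.DataFrame([[10.0], [20.0]], index=["g1", "g7"], columns=["s"])
        with pytest.warns(UserWarning, match="g7"):
            out = self_hit_normalize(m, {"g1": 10.0})
        assert list(out.index) == ["g1"]

    def test_cap_and_no_cap(self):
        m = pd.DataFrame([[150.0]], index=["g"], columns=["s"])
        assert self_hit_normalize(m, {"g": 100.0}).iloc[0, 0] == 1.0
        assert self_hit_normalize(m, {"g": 100.0}, cap=False).iloc[0, 0] == 1.5

    def test_strict_mode_raises(self):
        m = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError):
            self_hit_normalize(m, {}, strict=True)


class TestBinarize:
    def test_evalue_threshold(self):
        hits = hits_df([("g", "s1", 50.0, 1e-4), ("g", "s2", 50.0, 1e-2)])
        b = binarize_by_evalue(hits, ["g"], ["s1", "s2", "s3"])
        assert b.loc["g"].tolist() == [1, 0, 0]

    def test_infinite_threshold_marks_any_hit(self):
        hits = hits_df([("g", "s1", 5.0, 10.0)])
        b = binarize_by_evalue(hits, ["g"], ["s1", "s2"], np.inf)
        assert b.loc["g"].tolist() == [1, 0]

    def test_agrees_with_bitscore_matrix_on_zero_support(self, small_sim):
        raw = build_bitscore_matrix(
            small_sim.hits, list(small_sim.bitscore_matrix.index),
            list(small_sim.bitscore_matrix.columns))
        bpm = binarize_by_evalue(
            small_sim.hits, list(raw.index), list(raw.columns),
            evalue_threshold=np.inf)
        assert ((raw.to_numpy() == 0) == (bpm.to_numpy() == 0)).all()


class TestSelectClades:
    def taxonomy(self, groups):
        rows = {}
        for lineage, n in groups.items():
            for i in range(n):
                rows[f"{lineage.replace(';', '_')}_{i}"] = lineage
        return pd.Series(rows)

    def test_small_clade_dropped(self):
        tax = self.taxonomy({"root;A": 9, "root;B": 12})
        cs = select_clades(tax, min_size=10)
        assert "A" not in cs.names and "B" in cs.names
        assert cs.dropped["A"] == "small"

    def test_identical_clade_redundant(self):
        # B has exactly the species of A (same lineage level): J = 1 > 0.8
        tax = pd.Series({f"s{i}": "A;B" for i in range(12)})
        cs = select_clades(tax, min_size=10)
        assert len(cs.kept) == 1
        assert "redundant" in list(cs.dropped.values())[0]

    def test_disjoint_clades_both_kept(self):
        tax = self.taxonomy({"root;A": 20, "root;B": 15})
        cs = select_clades(tax, min_size=10, jaccard_max=0.8)
        assert {"A", "B"} <= set(cs.names)

    def test_order_independent_and_deterministic(self):
        tax = self.taxonomy({"root;A": 20, "root;B": 15, "root;C": 11})
        a = select_clades(tax, min_size=10)
        b = select_clades(tax.sample(frac=1.0, random_state=1), min_size=10)
        assert a.names == b.names

    def test_greedy_largest_first(self):
        # C overlaps the larger A above threshold -> C dropped, A kept
        tax = {}
        for i in range(20):
            tax[f"x{i}"] = "root;A;C" if i < 18 else "root;A"
        cs = select_clades(pd.Series(tax), min_size=10, jaccard_max=0.8)
        assert "A" in cs.names and cs.dropped["C"].startswith("redundant")

    def test_empty_taxonomy_errors(self):
        with pytest.raises(ValueError):
            select_clades(pd.Series(dtype=str))


class TestMasking:
    def test_empty_mask_is_identity(self, small_profile):
        pd.testing.assert_frame_equal(mask_species(small_profile, set()),
                                      small_profile)

    def test_unmasked_entries_unchanged(self, small_profile):
        masked = mask_species(small_profile, {small_profile.columns[0]})
        rest = list(small_profile.columns[1:])
        pd.testing.assert_frame_equal(masked[rest], small_profile[rest])
        assert masked[small_profile.columns[0]].isna().all()

    def test_masked_column_leaves_conservation(self):
        # recompute per-organism conservation on a 3x3 toy by hand
        from mlpp.parasites import conservation_fraction

        bpm = pd.DataFrame([[1, 0, 1], [1, 1, 0], [0, 1, 1]],
                           index=list("abc"), columns=["s1", "s2", "s3"])
        masked = mask_species(bpm.astype(float), {"s2"})
        frac = conservation_fraction(masked)
        assert frac["s1"] == pytest.approx(2 / 3)
        assert np.isnan(frac["s2"])
        assert frac["s3"] == pytest.approx(2 / 3)


class TestGeneAge:
    def test_definition_on_toy(self):
        bpm = pd.DataFrame(
            [[1, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]],
            index=["chordate_only", "deep_chordate", "metazoan", "ancient"],
            columns=["c1", "c2", "m1", "f1"],
        )
        clades = {"Chordata": {"c1", "c2"}, "Metazoa": {"c1", "c2", "m1"}}
        ages = gene_age_category(bpm, clades)
        assert ages["chordate_only"] == "Chordata-specific"
        assert ages["deep_chordate"] == "Chordata-specific"
        assert ages["metazoan"] == "Metazoa-specific"
        assert ages["ancient"] == "all"

    def test_planted_young_genes_flagged_exactly(self, small_sim, small_binary):
        origin = next(iter(small_sim.truth.young_genes.values()))
        clades = small_sim.clade_species
        ages = gene_age_category(small_binary, clades, order=(origin,))
        flagged = set(ages.index[ages == f"{origin}-specific"])
        # exhaustive-scan oracle: zero presence outside the origin clade
        outside = [s for s in small_binary.columns if s not in clades[origin]]
        expected = set(small_binary.index[(small_binary[outside] == 0).all(axis=1)])
        assert flagged == expected
        assert set(small_sim.truth.young_genes) <= flagged

    def test_unknown_clade_errors(self, small_binary):
        with pytest.raises(KeyError):
            gene_age_category(small_binary, {"X": set()}, order=("Y",))
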