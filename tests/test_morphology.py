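"""Morphology matrix I/O, MANOVA/Hotelling/CVA and diagnosability."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taxonlines import (MorphMatrix, SchemaError, amadon_75, cva,
                        fixed_diagnostic_characters, hotelling_t2, manova,
                        read_morph_matrix, wilks_manova)

CSV = """specimen_id,population,sex,SVL|metric,V|meristic,SLAB_L|meristic,SLAB_R|meristic,loreal|qualitative,pattern|qualitative|graded;sex-limited
a1,Anjouan,male,650.0,242,8,9,2+3,blotches
a2,Anjouan,female,610.5,238,8,8,2+3,
m1,Mayotte,male,600.0,240,9,9,2+3,spots
g1,GrandComoro,male,560.0,246,8,8,2,uniform
g2,GrandComoro,female,575.0,249,9,8,2,
"""


def small_matrix():
    return read_morph_matrix(io.StringIO(CSV))


def make_numeric(groups, rng=None, chars=("x", "y")):
    """Build a MorphMatrix from {population: ndarray (n, p)} blocks."""
    rows, idx = [], []
    for pop, arr in groups.items():
        for i, row in enumerate(np.atleast_2d(arr)):
            rows.append({"population": pop, "sex": "unknown",
                         **{c: float(v) for c, v in zip(chars, row)}})
            idx.append(f"{pop}_{i}")
    df = pd.DataFrame(rows, index=pd.Index(idx, name="specimen_id"))
    return MorphMatrix(df, {c: "meristic" for c in chars},
                       {c: frozenset() for c in chars})


class TestIO:
    def test_reads_types_and_flags(self):
        mm = small_matrix()
        assert mm.char_types["SVL"] == "metric"
        assert mm.char_types["loreal"] == "qualitative"
        assert mm.char_flags["pattern"] == {"graded", "sex-limited"}

    def test_bilateral_mean_accessor(self):
        mm = small_matrix()
        assert mm.values("SLAB").loc["a1"] == pytest.approx(8.5)
        assert "SLAB" in mm.numeric_characters()

    def test_unknown_type_tag(self):
        bad = CSV.replace("SVL|metric", "SVL|continuous")
        with pytest.raises(SchemaError, match="type tag"):
            read_morph_matrix(io.StringIO(bad))

    def test_empty_data_section(self):
        header = CSV.splitlines()[0]
        with pytest.raises(SchemaError):
            read_morph_matrix(io.StringIO(header + "\n"))

    def test_non_numeric_in_numeric_column(self):
        bad = CSV.replace("650.0", "tall")
        with pytest.raises(SchemaError, match="non-numeric"):
            read_morph_matrix(io.StringIO(bad))

    def test_roundtrip_through_csv(self, tmp_path):
        mm = small_matrix()
        path = tmp_path / "morph.csv"
        mm.to_csv(path)
        back = read_morph_matrix(path)
        assert back.char_types == mm.char_types
        pd.testing.assert_frame_equal(back.data, mm.data)


class TestManova:
    def test_identical_groups_lambda_one(self):
        block = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 1.0], [4.0, 4.0]])
        mm = make_numeric({"A": block, "B": block})
        res = manova(mm, ["x", "y"])
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.overall_p == pytest.approx(1.0)

    def test_single_character_hotelling_is_squared_t(self):
        rng = np.random.default_rng(5)
        xa = rng.normal(0, 1, (12, 1))
        xb = rng.normal(0.8, 1, (15, 1))
        t2, _, _, p_h = hotelling_t2(xa, xb)
        t, p_t = stats.ttest_ind(xa[:, 0], xb[:, 0])
        assert t2 == pytest.approx(t ** 2)
        assert p_h == pytest.approx(p_t)

    def test_wilks_matches_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA as SMManova
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 3))
        labels = np.repeat(["a", "b", "c"], 10)
        x[labels == "b"] += 0.5
        lam, f, df, p = wilks_manova(x, labels)
        sm = SMManova(x, pd.get_dummies(labels, drop_first=False,
                                        dtype=float).to_numpy())
        tbl = sm.mv_test([("grp", np.array([[1., -1, 0], [0, 1, -1]]))])
        row = tbl.results["grp"]["stat"].loc["Wilks' lambda"]
        assert lam == pytest.approx(row["Value"], rel=1e-6)
        assert p == pytest.approx(row["Pr > F"], rel=1e-4)

    def test_tiny_group_reported_untestable(self):
        mm = make_numeric({
            "A": np.array([[1.0, 2.0]]),
            "B": np.array([[0.0, 1.0], [1.0, 0.0]]),
            "C": np.random.default_rng(1).normal(size=(8, 2)),
        })
        res = manova(mm, ["x", "y"])
        assert res.pairwise[("A", "B")] is None
        assert "untestable" in res.pairwise_notes[("A", "B")]

    def test_specimen_order_invariance(self):
        rng = np.random.default_rng(2)
        blocks = {p: rng.normal(size=(8, 2)) for p in "ABC"}
        mm = make_numeric(blocks)
        perm = rng.permutation(len(mm.data))
        mm2 = MorphMatrix(mm.data.iloc[perm], mm.char_types, mm.char_flags)
        r1, r2 = manova(mm, ["x", "y"]), manova(mm2, ["x", "y"])
        assert r1.wilks_lambda == pytest.approx(r2.wilks_lambda)
        assert r1.pairwise[("A", "B")] == pytest.approx(r2.pairwise[("A", "B")])


class TestCva:
    def test_two_groups_single_axis(self):
        rng = np.random.default_rng(1)
        mm = make_numeric({"A": rng.normal(0, 1, (10, 3)),
                           "B": rng.normal(1, 1, (10, 3))},
                          chars=("x", "y", "z"))
        res = cva(mm, ["x", "y", "z"])
        assert res.scores.shape[1] == 1
        assert len(res.eigenvalues) == 1

    def test_translation_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(4)
        blocks = {"A": rng.normal(0, 1, (10, 2)),
                  "B": rng.normal(0.7, 1, (10, 2)),
                  "C": rng.normal(-0.5, 1, (10, 2))}
        mm1 = make_numeric(blocks)
        shifted = {p: a + np.array([100.0, 0]) for p, a in blocks.items()}
        mm2 = make_numeric(shifted)
        r1, r2 = cva(mm1, ["x", "y"]), cva(mm2, ["x", "y"])
        np.testing.assert_allclose(r1.loadings.values, r2.loadings.values,
                                   atol=1e-8)

    def test_dominant_character_has_largest_axis1_loading(self):
        # only `sc` separates the groups, so it must dominate CV1
        rng = np.random.default_rng(9)
        blocks = {}
        for k, pop in enumerate(["A", "B", "C"]):
            sc = rng.normal(5 * k, 1, (15, 1))
            noise = rng.normal(0, 1, (15, 2))
            blocks[pop] = np.hstack([noise[:, :1], sc, noise[:, 1:]])
        mm = make_numeric(blocks, chars=("v", "sc", "slab"))
        res = cva(mm, ["v", "sc", "slab"])
        assert res.loadings["CV1"].abs().idxmax() == "sc"

    def test_eigenvalues_sorted_descending(self):
        rng = np.random.default_rng(12)
        blocks = {p: rng.normal(i, 1, (10, 3)) for i, p in enumerate("ABCD")}
        res = cva(make_numeric(blocks, chars=("x", "y", "z")),
                  ["x", "y", "z"])
        assert all(a >= b for a, b in
                   zip(res.eigenvalues, res.eigenvalues[1:]))


class TestDiagnosis:
    def test_loreal_fixed_between_clades(self):
        mm = small_matrix()
        rep = fixed_diagnostic_characters(mm, {"Anjouan", "Mayotte"},
                                          {"GrandComoro"})
        assert rep.records["loreal"]["status"] == "fixed-qualitative"
        assert "loreal" in rep.diagnostic_characters()

    def test_overlapping_state_sets(self):
        mm = small_matrix()
        rep = fixed_diagnostic_characters(mm, {"Anjouan"}, {"Mayotte"})
        assert rep.records["loreal"]["status"] == "overlapping"

    def test_graded_characters_excluded_by_default(self):
        mm = small_matrix()
        rep = fixed_diagnostic_characters(mm, {"Anjouan", "Mayotte"},
                                          {"GrandComoro"})
        assert rep.records["pattern"]["status"] == "excluded"
        rep2 = fixed_diagnostic_characters(mm, {"Anjouan", "Mayotte"},
                                           {"GrandComoro"},
                                           include_graded=True)
        assert rep2.records["pattern"]["status"] != "excluded"

    def test_range_disjoint_numeric_is_diagnosable(self):
        mm = make_numeric({"A": np.array([[1.0, 0], [2.0, 1]]),
                           "B": np.array([[5.0, 0.5], [7.0, 0.2]])})
        rep = fixed_diagnostic_characters(mm, {"A"}, {"B"})
        assert rep.records["x"]["status"] == "quantitative-diagnosable"
        assert rep.records["y"]["status"] == "overlapping"

    def test_adding_a_specimen_cannot_create_a_fixed_character(self):
        mm = small_matrix()
        rep_full = fixed_diagnostic_characters(mm, {"Anjouan", "Mayotte"},
                                               {"GrandComoro"})
        sub = MorphMatrix(mm.data.iloc[:-1], mm.char_types, mm.char_flags)
        rep_sub = fixed_diagnostic_characters(sub, {"Anjouan", "Mayotte"},
                                              {"GrandComoro"})
        fixed_full = set(rep_full.diagnostic_characters())
        fixed_sub = set(rep_sub.diagnostic_characters())
        assert fixed_full <= fixed_sub


class TestAmadon:
    def test_identical_samples_fail(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        res = amadon_75(a, a)
        assert res.fraction_outside < 0.1
        assert not res.passes

    def test_large_shift_passes(self):
        rng = np.random.default_rng(1)
        b = rng.normal(0, 1, 50)
        a = rng.normal(10, 1, 50)
        res = amadon_75(a, b)
        assert res.fraction_outside > 0.95
        assert res.passes

    def test_zero_variance_reference_degenerates_to_point(self):
        res = amadon_75([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert res.passes

    def test_matches_straight_line_oracle_across_effect_sizes(self):
        rng = np.random.default_rng(3)
        z99 = stats.norm.ppf(0.995)
        for shift in (0.5, 2.0, 3.5):
            agree = 0
            for _ in range(100):
                b = rng.normal(0, 1, 15)
                a = rng.normal(shift, 1, 15)
                res = amadon_75(a, b)
                lo, hi = b.mean() - z99 * b.std(ddof=1), \
                    b.mean() + z99 * b.std(ddof=1)
                expected = np.mean((a < lo) | (a > hi)) >= 0.75
                agree += (res.passes == expected)
            assert agree == 100

    def test_range_mode(self):
        res = amadon_75([10.0] * 10, [0.0, 1.0, 2.0], interval="range")
        assert res.passes
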