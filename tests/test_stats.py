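"""Pearson screening, strength bands, and compact-letter group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dustrisk as dr
from dustrisk.stats import _compact_letter_display


def brute_force_pearson(x, y):
    """Independent oracle: Pearson r from first principles and the p-value
    from the t transform t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * t_dist.sf(abs(t), n - 2)
    return r, p


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = dr.pearson_r_p(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_hand_computed_four_points(self):
        # r = 0.8; t = 0.8*sqrt(2)/0.6 with 2 df gives two-tailed p = 0.200
        r, p = dr.pearson_r_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.200, abs=5e-4)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            x = rng.normal(size=31)
            y = rng.normal(size=31)
            r, p = dr.pearson_r_p(x, y)
            r0, p0 = brute_force_pearson(x, y)
            assert r == pytest.approx(r0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_constant_variable_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            dr.pearson_r_p([1, 1, 1, 1], [1, 2, 3, 4])


class TestCorrelationMatrix:
    def test_cell_by_cell_oracle_equivalence(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame(
            rng.lognormal(size=(31, 5)), columns=list("abcde")
        )
        matrix = dr.correlation_matrix(frame)
        for i in frame.columns:
            for j in frame.columns:
                if i == j:
                    assert matrix.r.loc[i, j] == 1.0
                    continue
                r0, p0 = brute_force_pearson(frame[i], frame[j])
                assert matrix.r.loc[i, j] == pytest.approx(r0, abs=1e-12)
                assert matrix.p.loc[i, j] == pytest.approx(p0, abs=1e-12)

    def test_symmetric_and_invariant_to_row_permutation(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(rng.normal(size=(31, 4)), columns=list("wxyz"))
        matrix = dr.correlation_matrix(frame)
        shuffled = dr.correlation_matrix(
            frame.sample(frac=1.0, random_state=5)
        )
        pd.testing.assert_frame_equal(matrix.r, matrix.r.T)
        pd.testing.assert_frame_equal(matrix.r, shuffled.r)

    def test_pairwise_complete_counts(self):
        frame = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, np.nan, 6], "b": [2.0, 1, 4, 3, 5, np.nan],
             "c": [1.0, 2, 1, 2, 1, 2]}
        )
        matrix = dr.correlation_matrix(frame)
        assert matrix.n.loc["a", "b"] == 4
        assert matrix.n.loc["a", "c"] == 5

    def test_constant_column_flagged_not_propagated(self):
        frame = pd.DataFrame(
            {"a": [1.0, 2, 3, 4, 5], "k": [7.0] * 5, "b": [2.0, 1, 4, 3, 5]}
        )
        matrix = dr.correlation_matrix(frame)
        assert ("a", "k") in matrix.undefined
        assert np.isnan(matrix.r.loc["a", "k"])
        # the unrelated cell is still computed
        assert np.isfinite(matrix.r.loc["a", "b"])

    def test_study_variables_include_bacteria(self, study31):
        matrix = dr.correlation_matrix(study31)
        assert "TB" in matrix.variables and "EB" in matrix.variables
        assert matrix.stars.loc["TB", "EB"] in ("", "*", "**")


class TestStrengthBands:
    @pytest.mark.parametrize(
        "r, label",
        [
            (0.0, "weak"), (0.39, "weak"), (0.40, "moderate"),
            (0.55, "moderate"), (0.69, "moderate"), (0.70, "strong"),
            (-0.75, "strong"), (0.89, "strong"), (0.90, "very strong"),
            (1.0, "very strong"), (-1.0, "very strong"),
        ],
    )
    def test_bands(self, r, label):
        assert dr.classify_correlation(r) == label

    def test_out_of_range_refused(self):
        with pytest.raises(ValueError):
            dr.classify_correlation(1.5)

    @given(st.floats(min_value=-1, max_value=1))
    @settings(max_examples=200, deadline=None)
    def test_total_and_monotone_in_magnitude(self, r):
        order = ["weak", "moderate", "strong", "very strong"]
        label = dr.classify_correlation(r)
        assert label in order
        shrunk = dr.classify_correlation(r * 0.5)
        assert order.index(shrunk) <= order.index(label)


class TestStars:
    @pytest.mark.parametrize(
        "p, stars", [(0.2, ""), (0.04, "*"), (0.005, "**")]
    )
    def test_annotation(self, p, stars):
        assert dr.significance_stars(p) == stars


def groups_frame(**groups):
    rows = [
        {"level": name, "value": v} for name, vs in groups.items() for v in vs
    ]
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_share_a_letter(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        frame = groups_frame(a=values, b=values)
        result = dr.compare_groups(frame, "level", "value")
        assert result.letters["a"] == result.letters["b"]
        assert min(result.p_values.values()) > 0.9

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(12)
        frame = groups_frame(
            low=rng.normal(0, 1, 50), high=rng.normal(10, 1, 50)
        )
        result = dr.compare_groups(frame, "level", "value")
        assert set(result.letters["low"]) & set(result.letters["high"]) == set()

    def test_intermediate_level_bridges_extremes(self):
        # only the extremes differ: expect the a / ab / b letter pattern
        rng = np.random.default_rng(1)
        frame = groups_frame(
            g1=rng.normal(0.0, 1, 12),
            g2=rng.normal(0.8, 1, 12),
            g3=rng.normal(1.6, 1, 12),
        )
        result = dr.compare_groups(frame, "level", "value")
        letters = result.letters
        assert set(letters["g1"]) & set(letters["g3"]) == set()
        assert set(letters["g2"]) & set(letters["g1"])
        assert set(letters["g2"]) & set(letters["g3"])

    def test_small_level_excluded_with_note(self):
        frame = groups_frame(a=[1.0, 2, 3, 4], b=[5.0, 6, 7, 8], c=[9.0])
        result = dr.compare_groups(frame, "level", "value")
        assert result.excluded == ["c"]
        assert "c" not in result.levels

    def test_fewer_than_two_usable_levels_refused(self):
        frame = groups_frame(a=[1.0, 2, 3], c=[9.0])
        with pytest.raises(ValueError, match="2 levels"):
            dr.compare_groups(frame, "level", "value")

    def test_group_summary_table_layout(self, study31):
        table = dr.group_summary_table(
            study31, "home_type", ["Pb", "Cu", "Zn"]
        )
        assert set(table.columns) <= {"Pb", "Cu", "Zn"}
        assert set(table.index) <= {"apartment", "single_family"}


class TestCompactLetterDisplay:
    def test_chain_pattern(self):
        letters = _compact_letter_display(
            ["g1", "g2", "g3"], distinct={("g1", "g3")}
        )
        assert letters == {"g1": "a", "g2": "ab", "g3": "b"}

    def test_all_distinct(self):
        letters = _compact_letter_display(
            ["x", "y", "z"],
            distinct={("x", "y"), ("y", "z"), ("x", "z")},
        )
        assert len({letters["x"], letters["y"], letters["z"]}) == 3

    def test_shared_letter_never_spans_a_significant_pair(self):
        rng = np.random.default_rng(0)
        levels = ["a", "b", "c", "d"]
        for _ in range(50):
            pairs = [
                (levels[i], levels[j])
                for i in range(4) for j in range(i + 1, 4)
                if rng.random() < 0.4
            ]
            letters = _compact_letter_display(levels, set(pairs))
            for x, y in pairs:
                assert set(letters[x]) & set(letters[y]) == set()
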