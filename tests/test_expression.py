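import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from refstab.expression import (
    _compact_letters,
    compare_normalizers,
    ddct_expression,
    one_way_anova,
    tukey_letters,
)

from conftest import make_ct_table


def letters_valid(letters: dict, significant: set) -> bool:
    """Brute-force verifier: groups share a letter iff allowed."""
    for a, b in itertools.combinations(letters, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        if tuple(sorted((a, b))) in significant and share:
            return False
        if tuple(sorted((a, b))) not in significant and not share:
            return False
    return True


class TestDdct:
    def test_target_equal_to_ref_is_flat_one(self):
        m = [[20.0, 21.0, 22.0, 23.0], [20.0, 21.0, 22.0, 23.0]]
        t = make_ct_table(m, genes=["target", "ref"], levels=["a", "a", "b", "b"])
        res = ddct_expression(t, "target", ["ref"], calibrator="a")
        assert np.allclose(res.expression, 1.0)

    def test_hand_example_fold_four(self):
        # calibrator: target 24 / ref 20; test: target 22 / ref 20 -> fold 4
        t = make_ct_table(
            [[24.0, 22.0], [20.0, 20.0]],
            genes=["target", "ref"],
            levels=["cal", "test"],
        )
        res = ddct_expression(t, "target", ["ref"], calibrator="cal")
        assert res.expression["s01"] == pytest.approx(4.0)
        assert res.expression["s00"] == pytest.approx(1.0)

    def test_two_refs_equal_their_mean_ct(self):
        target = [24.0, 22.0, 23.0, 21.0]
        t2 = make_ct_table(
            [target, [19.0, 19.0, 19.0, 19.0], [21.0, 21.0, 21.0, 21.0]],
            genes=["target", "refA", "refB"],
            levels=["cal", "cal", "x", "x"],
        )
        t1 = make_ct_table(
            [target, [20.0, 20.0, 20.0, 20.0]],
            genes=["target", "ref"],
            levels=["cal", "cal", "x", "x"],
        )
        r2 = ddct_expression(t2, "target", ["refA", "refB"], calibrator="cal")
        r1 = ddct_expression(t1, "target", ["ref"], calibrator="cal")
        assert np.allclose(r2.expression, r1.expression)

    def test_calibrator_group_mean_is_one(self, rng):
        m = rng.uniform(18, 26, size=(3, 6))
        t = make_ct_table(
            m, genes=["target", "r1", "r2"], levels=["a", "a", "a", "b", "b", "b"]
        )
        res = ddct_expression(t, "target", ["r1", "r2"], calibrator="a")
        # 2^-ddCT averages to 1 on the log scale over the calibrator group
        cal = res.expression[["s00", "s01", "s02"]]
        assert np.log2(cal).mean() == pytest.approx(0.0, abs=1e-12)

    def test_per_sample_ct_shift_cancels(self, rng):
        m = rng.uniform(18, 26, size=(3, 6))
        levels = ["a", "a", "a", "b", "b", "b"]
        shift = rng.uniform(-2, 2, size=(1, 6))
        t1 = make_ct_table(m, genes=["t", "r1", "r2"], levels=levels)
        t2 = make_ct_table(m + shift, genes=["t", "r1", "r2"], levels=levels)
        r1 = ddct_expression(t1, "t", ["r1", "r2"], calibrator="a")
        r2 = ddct_expression(t2, "t", ["r1", "r2"], calibrator="a")
        assert np.allclose(r1.expression, r2.expression, atol=1e-9)

    def test_target_in_refs_rejected(self):
        t = make_ct_table([[20.0, 21.0], [19.0, 20.0]], genes=["t", "r"])
        with pytest.raises(ValueError, match="own reference"):
            ddct_expression(t, "t", ["t", "r"])


class TestCompareNormalizers:
    def test_identical_normalizers_ratio_one(self, rng):
        m = rng.uniform(18, 26, size=(3, 6))
        t = make_ct_table(m, genes=["t", "r1", "r2"], levels=["a"] * 3 + ["b"] * 3)
        ratios = compare_normalizers(t, "t", [["r1"], ["r1"]], calibrator="a")
        assert np.allclose(ratios["ratio"], 1.0)

    def test_uniform_one_ct_shift_doubles(self, rng):
        m = rng.uniform(18, 26, size=(3, 6))
        m[2] = m[1] + 1.0  # r2 is r1 shifted +1 CT everywhere
        t = make_ct_table(m, genes=["t", "r1", "r2"], levels=["a"] * 3 + ["b"] * 3)
        ratios = compare_normalizers(t, "t", [["r1"], ["r2"]], calibrator="a")
        # same shift applies in the calibrator: ddCT and expression are equal
        assert np.allclose(ratios["ratio"], 1.0, atol=1e-9)

    def test_planted_tissue_drift_shows_in_ratio(self):
        # unstable ref drifts +1 CT only in tissue b: looks like 2x target rise
        levels = ["a", "a", "b", "b"]
        target = [20.0, 20.0, 20.0, 20.0]
        good = [18.0, 18.0, 18.0, 18.0]
        bad = [18.0, 18.0, 19.0, 19.0]
        t = make_ct_table([target, good, bad], genes=["t", "good", "bad"], levels=levels)
        ratios = compare_normalizers(t, "t", [["bad"], ["good"]], calibrator="a")
        r_b = ratios.query("level == 'b' and normalizer_a == 'bad'")["ratio"].iloc[0]
        assert r_b == pytest.approx(2.0)


class TestAnova:
    def test_equal_groups_f_zero(self):
        f, p = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        f, p = one_way_anova(np.concatenate([x, y]), ["a"] * 8 + ["b"] * 8)
        t, pt = stats.ttest_ind(x, y)
        assert f == pytest.approx(t**2, rel=1e-9)
        assert p == pytest.approx(pt, rel=1e-9)

    def test_huge_separation_significant(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 3), rng.normal(100, 1, 3)])
        f, p = one_way_anova(vals, ["a"] * 3 + ["b"] * 3)
        assert p < 0.001

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestCompactLetters:
    def test_no_significant_pairs_single_letter(self):
        letters = _compact_letters(["a", "b", "c"], set())
        assert set(letters.values()) == {"A"}

    def test_one_group_differs(self):
        sig = {("a", "b"), ("a", "c")}
        letters = _compact_letters(["a", "b", "c"], sig)
        assert letters_valid(letters, sig)
        assert letters["b"] == letters["c"]
        assert letters["a"] != letters["b"]

    def test_all_pairs_distinct_letters(self):
        sig = {("a", "b"), ("a", "c"), ("b", "c")}
        letters = _compact_letters(["a", "b", "c"], sig)
        assert sorted(letters.values()) == ["A", "B", "C"]

    def test_chain_pattern_valid(self):
        # a != c only: a and b share, b and c share, a and c do not
        sig = {("a", "c")}
        letters = _compact_letters(["a", "b", "c"], sig)
        assert letters_valid(letters, sig)

    def test_random_significance_patterns_always_valid(self, rng):
        groups = list("abcde")
        for _ in range(50):
            sig = {
                tuple(sorted(p))
                for p in itertools.combinations(groups, 2)
                if rng.random() < 0.4
            }
            letters = _compact_letters(groups, sig)
            for a, b in sig:
                assert not (set(letters[a]) & set(letters[b]))
            # non-significant pairs must share a letter unless separated
            # transitively; the insert-and-absorb construction guarantees it
            for a, b in itertools.combinations(groups, 2):
                if tuple(sorted((a, b))) not in sig:
                    assert set(letters[a]) & set(letters[b])


class TestTukeyLetters:
    def test_separated_group_gets_own_letter(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 0.5, 5), rng.normal(10, 0.5, 5), rng.normal(10.2, 0.5, 5)]
        )
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = tukey_letters(vals, groups)
        assert res.p_value < 0.001
        assert res.letters["a"] == "A"
        assert res.letters["b"] == res.letters["c"] == "B"

    def test_homogeneous_groups_share_letter(self, rng):
        vals = rng.normal(0, 1, 15)
        res = tukey_letters(vals, ["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        assert set(res.letters.values()) == {"A"}

    def test_letters_consistent_with_p_matrix(self, rng):
        vals = np.concatenate(
            [rng.normal(i * 1.5, 1.0, 4) for i in range(4)]
        )
        groups = sum([[f"g{i}"] * 4 for i in range(4)], [])
        res = tukey_letters(vals, groups)
        sig = {
            tuple(sorted((a, b)))
            for a, b in itertools.combinations(res.letters, 2)
            if res.pairwise_p.loc[a, b] < res.alpha
        }
        for a, b in itertools.combinations(res.letters, 2):
            share = bool(set(res.letters[a]) & set(res.letters[b]))
            assert share != (tuple(sorted((a, b))) in sig)
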