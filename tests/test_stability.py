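"""The four stability statistics, each checked against an independent
brute-force oracle or a hand calculation, plus the rank conventions."""

import itertools

import numpy as np
import pandas as pd
import pytest

from refstab.data_model import ct_to_quantity
from refstab.published import published_stabilities, published_table
from refstab.stability import (
    assign_ranks,
    bestkeeper,
    delta_ct,
    genorm,
    normfinder,
    run_all_methods,
)

from conftest import make_ct_table


# -- independent oracles -----------------------------------------------------


def brute_force_m(q: pd.DataFrame) -> pd.Series:
    """Full-panel geNorm M by direct enumeration of every pair SD."""
    genes = list(q.index)
    m = {}
    for g in genes:
        vs = []
        for h in genes:
            if h == g:
                continue
            ratio = np.log2(q.loc[g].to_numpy() / q.loc[h].to_numpy())
            vs.append(np.std(ratio, ddof=1))
        m[g] = np.mean(vs)
    return pd.Series(m)


def brute_force_delta_ct(ct: pd.DataFrame) -> pd.Series:
    genes = list(ct.index)
    out = {}
    for g in genes:
        sds = [
            np.std(ct.loc[g].to_numpy() - ct.loc[h].to_numpy(), ddof=1)
            for h in genes
            if h != g
        ]
        out[g] = np.mean(sds)
    return pd.Series(out)


def naive_min_tie_ranks(values: pd.Series) -> pd.Series:
    return pd.Series(
        {g: int(1 + (values < values[g]).sum()) for g in values.index}
    )


# -- geNorm ------------------------------------------------------------------


class TestGenorm:
    def test_proportional_genes_have_zero_pairwise_v(self):
        base = np.array([1.0, 0.5, 0.25, 0.8])
        t = make_ct_table(
            np.log2(1 / np.vstack([base, base * 0.5, [1.0, 0.9, 0.2, 0.6]])) + 20
        )
        q = ct_to_quantity(t)
        res = genorm(q)
        # proportional profiles: their mutual V is 0, so full-panel M of each
        # equals its V against the third gene alone / (n-1)... check directly
        v01 = np.std(np.log2(q.q.iloc[0] / q.q.iloc[1]), ddof=1)
        assert v01 == pytest.approx(0.0, abs=1e-12)

    def test_m_matches_brute_force_oracle(self, rng):
        m = rng.uniform(15, 25, size=(5, 6))
        t = make_ct_table(m)
        q = ct_to_quantity(t)
        res = genorm(q)
        expected = brute_force_m(q.q)
        pd.testing.assert_series_equal(
            res.detail.full_panel_m, expected, check_names=False, atol=1e-12
        )

    def test_final_pair_ties_at_rank_1(self, rng):
        m = rng.uniform(15, 25, size=(4, 8))
        t = make_ct_table(m)
        res = genorm(ct_to_quantity(t))
        pair = res.detail.final_pair
        assert res.stability[pair[0]] == res.stability[pair[1]]
        assert res.ranks[pair[0]] == res.ranks[pair[1]] == 1
        # next-best gene gets rank 3 under min-tie competition ranking
        assert sorted(res.ranks) == [1, 1, 3, 4]

    def test_exclusion_order_length(self, rng):
        t = make_ct_table(rng.uniform(15, 25, size=(6, 5)))
        res = genorm(ct_to_quantity(t))
        assert len(res.detail.exclusion_order) == 4
        assert res.detail.stability_order[-1] == res.detail.exclusion_order[0]

    def test_requires_three_genes(self):
        t = make_ct_table([[20.0, 21.0], [19.0, 20.0]])
        with pytest.raises(ValueError, match="3 genes"):
            genorm(ct_to_quantity(t))

    def test_invariant_to_per_gene_ct_offset(self, rng):
        m = rng.uniform(15, 25, size=(5, 6))
        shift = rng.uniform(-3, 3, size=(5, 1))
        r1 = genorm(ct_to_quantity(make_ct_table(m)))
        r2 = genorm(ct_to_quantity(make_ct_table(m + shift)))
        pd.testing.assert_series_equal(r1.stability, r2.stability, atol=1e-9)


# -- NormFinder --------------------------------------------------------------


class TestNormfinder:
    def test_identical_genes_all_zero(self):
        y = pd.DataFrame(
            np.tile(np.linspace(0, 1, 6), (4, 1)),
            index=list("abcd"),
            columns=[f"s{j}" for j in range(6)],
        )
        res = normfinder(y)
        assert (res.stability == 0).all()

    def test_noisiest_gene_scores_worst_single_group(self):
        rng = np.random.default_rng(42)
        y = rng.normal(0, 0.1, size=(10, 500))
        y[3] = rng.normal(0, 1.0, 500)
        res = normfinder(pd.DataFrame(y, index=[f"g{i}" for i in range(10)]))
        assert res.ranks.iloc[3] == 10

    def test_planted_group_shift_dominates_and_sums_to_zero(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 0.1, size=(6, 12))
        y[0, 6:] += 2.0  # between-group shift of 2 CT-equivalents
        groups = ["A"] * 6 + ["B"] * 6
        res = normfinder(pd.DataFrame(y, index=list("abcdef")), groups)
        d = res.detail.intergroup_deviation
        assert np.allclose(d.sum(axis=0), 0.0, atol=1e-9)
        assert d.abs().loc["a"].max() == d.abs().max().max()
        assert res.ranks["a"] == 6

    def test_single_group_sigma_recovery(self):
        # parameter recovery validates the estimator constants
        true_sigma = np.linspace(0.1, 1.0, 10)
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, true_sigma[:, None], size=(10, 1000))
            res = normfinder(pd.DataFrame(y, index=[f"g{i}" for i in range(10)]))
            errs.append(np.abs(res.stability.to_numpy() - true_sigma) / true_sigma)
        assert np.mean(errs) < 0.05

    def test_requires_three_genes(self):
        with pytest.raises(ValueError, match="3 genes"):
            normfinder(pd.DataFrame(np.zeros((2, 5))))

    def test_small_group_rejected(self):
        y = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 5)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            normfinder(y, ["A", "A", "A", "A", "B"])

    def test_intragroup_variance_nonnegative(self, rng):
        y = pd.DataFrame(rng.normal(size=(5, 12)), index=list("abcde"))
        res = normfinder(y, ["A"] * 6 + ["B"] * 6)
        assert (res.detail.intragroup_variance.to_numpy() >= 0).all()
        assert res.detail.intergroup_variance >= 0


# -- BestKeeper --------------------------------------------------------------


class TestBestkeeper:
    def test_hand_calculation(self):
        t = make_ct_table([[20.0, 21.0, 22.0], [18.0, 18.0, 18.0]])
        res = bestkeeper(t)
        d = res.detail.descriptives
        assert d.loc["g00", "mean"] == pytest.approx(21.0)
        assert d.loc["g00", "sd"] == pytest.approx(2.0 / 3.0)
        assert d.loc["g00", "cv_pct"] == pytest.approx((2 / 3) / 21 * 100, abs=1e-6)

    def test_constant_gene_is_best(self):
        t = make_ct_table([[20.0, 21.0, 22.0], [18.0, 18.0, 18.0]])
        res = bestkeeper(t)
        assert res.ranks["g01"] == 1
        assert res.stability["g01"] == 0.0

    def test_identical_rows_correlate_perfectly_with_index(self):
        row = [20.0, 21.0, 22.0, 20.5]
        t = make_ct_table([row, row])
        res = bestkeeper(t)
        assert res.detail.correlation["r"].tolist() == pytest.approx([1.0, 1.0])

    def test_descriptive_orderings(self, rng):
        t = make_ct_table(rng.uniform(12, 30, size=(4, 8)))
        d = bestkeeper(t).detail.descriptives
        assert (d["min"] <= d["geo_mean"]).all()
        assert (d["geo_mean"] <= d["mean"]).all()
        assert (d["mean"] <= d["max"]).all()

    def test_classic_sd_switch(self):
        t = make_ct_table([[20.0, 21.0, 22.0], [18.0, 18.0, 18.0]])
        res = bestkeeper(t, sd="classic")
        assert res.stability["g00"] == pytest.approx(1.0)

    def test_invariant_to_sample_permutation_not_shift(self, rng):
        m = rng.uniform(15, 25, size=(3, 6))
        r1 = bestkeeper(make_ct_table(m))
        perm = rng.permutation(6)
        r2 = bestkeeper(make_ct_table(m[:, perm]))
        pd.testing.assert_series_equal(r1.stability, r2.stability, atol=1e-12)
        # per-sample shift changes BestKeeper SD (unlike dCT)
        shift = rng.uniform(-2, 2, size=(1, 6))
        r3 = bestkeeper(make_ct_table(m + shift))
        assert not np.allclose(r1.stability, r3.stability)


# -- comparative dCT ---------------------------------------------------------


class TestDeltaCt:
    def test_hand_calculation_two_genes(self):
        t = make_ct_table([[20.0, 21.0], [22.0, 24.0]])
        res = delta_ct(t)
        expected = np.std([-2.0, -3.0], ddof=1)  # 0.7071
        assert res.stability["g00"] == pytest.approx(expected, abs=1e-9)
        assert res.stability["g01"] == pytest.approx(expected, abs=1e-9)

    def test_parallel_profiles_zero_sd(self):
        t = make_ct_table([[20.0, 21.0, 19.5], [23.0, 24.0, 22.5], [25.0, 20.0, 22.0]])
        res = delta_ct(t)
        assert res.detail.pairwise_sd.loc["g00", "g01"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        m = rng.uniform(12, 30, size=(4, 7))
        t = make_ct_table(m)
        res = delta_ct(t)
        expected = brute_force_delta_ct(t.matrix)
        pd.testing.assert_series_equal(res.stability, expected, check_names=False, atol=1e-12)

    def test_pairwise_matrix_symmetric_zero_diagonal(self, rng):
        t = make_ct_table(rng.uniform(12, 30, size=(5, 6)))
        p = delta_ct(t).detail.pairwise_sd
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 0.0)

    def test_invariant_to_per_sample_and_per_gene_shifts(self, rng):
        m = rng.uniform(15, 25, size=(4, 6))
        r1 = delta_ct(make_ct_table(m))
        shifted = m + rng.uniform(-2, 2, size=(4, 1)) + rng.uniform(-2, 2, size=(1, 6))
        r2 = delta_ct(make_ct_table(shifted))
        pd.testing.assert_series_equal(r1.stability, r2.stability, atol=1e-9)


# -- ranks -------------------------------------------------------------------


class TestAssignRanks:
    def test_published_genorm_ranks_reproduced(self):
        # developmental-stages geNorm column: the printed 1,1,3 tie pattern
        stab = published_stabilities("developmental_stages")["genorm"]
        expected = published_table("developmental_stages")["genorm_rank"]
        ranks = assign_ranks(stab)
        pd.testing.assert_series_equal(
            ranks, expected.astype(int), check_names=False
        )

    def test_all_equal_all_rank_one(self):
        r = assign_ranks(pd.Series([0.5, 0.5, 0.5]))
        assert r.tolist() == [1, 1, 1]

    def test_strictly_increasing(self):
        r = assign_ranks(pd.Series([0.1, 0.2, 0.3, 0.4]))
        assert r.tolist() == [1, 2, 3, 4]

    def test_descending_flag(self):
        r = assign_ranks(pd.Series([0.1, 0.3, 0.2]), ascending=False)
        assert r.tolist() == [3, 1, 2]

    def test_matches_naive_oracle_on_random_ties(self, rng):
        for _ in range(20):
            v = pd.Series(rng.integers(0, 5, size=8) / 2.0)
            pd.testing.assert_series_equal(
                assign_ranks(v), naive_min_tie_ranks(v), check_names=False
            )


# -- cross-method properties -------------------------------------------------


class TestCrossMethod:
    def test_genorm_m_equals_delta_ct_at_base_2(self, rng):
        """With E = 2 the log2 quantity ratios ARE the CT differences, so the
        full-panel M and the comparative-dCT statistic must coincide."""
        for _ in range(20):
            n_genes = rng.integers(3, 8)
            n_samples = rng.integers(3, 10)
            t = make_ct_table(rng.uniform(10, 30, size=(n_genes, n_samples)))
            m_full = genorm(ct_to_quantity(t)).detail.full_panel_m
            dct = delta_ct(t).stability
            pd.testing.assert_series_equal(m_full, dct, check_names=False, atol=1e-9)

    def test_every_method_ranks_validly(self, rng):
        t = make_ct_table(rng.uniform(12, 28, size=(5, 9)))
        for res in run_all_methods(t).values():
            pd.testing.assert_series_equal(
                res.ranks,
                naive_min_tie_ranks(res.stability).astype(res.ranks.dtype),
                check_names=False,
            )
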