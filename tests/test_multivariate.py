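import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from sterolome import DegenerateInputError, SterolomeError
from sterolome import multivariate as mv


def _dm(points: np.ndarray) -> pd.DataFrame:
    d = squareform(pdist(points))
    ids = [f"s{i}" for i in range(len(points))]
    return pd.DataFrame(d, index=ids, columns=ids)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert mv.benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_worked_step_up(self):
        out = mv.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        out = mv.benjamini_hochberg([0.2, 0.2, 0.2])
        assert out == pytest.approx([0.2, 0.2, 0.2])

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = mv.benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 15)
        adj = mv.benjamini_hochberg(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert adj == pytest.approx(ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(SterolomeError):
            mv.benjamini_hochberg([0.5, 1.5])


class TestNmds:
    def test_equilateral_triangle_embeds_exactly(self):
        d = pd.DataFrame(
            1.0 - np.eye(3), index=list("abc"), columns=list("abc")
        )
        res = mv.nmds(d, k=2, max_tries=3, seed=1)
        assert res.stress < 1e-6

    def test_euclidean_distances_re_embed(self, rng):
        pts = rng.standard_normal((12, 2))
        res = mv.nmds(_dm(pts), k=2, max_tries=5, seed=2)
        assert res.stress < 1e-4

    def test_stress_monotone_in_k(self, rng):
        pts = rng.standard_normal((8, 5))
        d = _dm(pts)
        s2 = mv.nmds(d, k=2, max_tries=5, seed=3).stress
        s7 = mv.nmds(d, k=7, max_tries=5, seed=3).stress
        assert s7 <= s2 + 1e-9

    def test_identical_points_degenerate(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        with pytest.raises(DegenerateInputError):
            mv.nmds(d, k=2, max_tries=2, seed=0)

    def test_deterministic_for_seed(self, rng):
        pts = rng.standard_normal((9, 3))
        d = _dm(pts)
        a = mv.nmds(d, k=2, max_tries=4, seed=11)
        b = mv.nmds(d, k=2, max_tries=4, seed=11)
        assert a.stress == b.stress
        assert np.array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())

    def test_coordinates_centered(self, rng):
        pts = rng.standard_normal((10, 4))
        res = mv.nmds(_dm(pts), k=2, max_tries=3, seed=5)
        assert np.abs(res.coordinates.mean(axis=0)).max() < 1e-8


class TestPermanova:
    def test_matches_brute_force_on_six_points(self):
        pts = np.array(
            [[0.0, 0], [0.1, 0], [0.2, 0.1], [2.0, 2], [2.1, 2], [1.9, 2.2]]
        )
        d = _dm(pts)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = mv.permanova(d, groups, n_permutations=99, seed=0)
        # brute force straight from the sums-of-squares definitions
        arr = d.to_numpy() ** 2
        n = 6
        ss_total = arr[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for idx in ([0, 1, 2], [3, 4, 5]):
            sub = arr[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(3, 1)].sum() / 3
        f_brute = ((ss_total - ss_within) / 1) / (ss_within / 4)
        assert res.statistic == pytest.approx(f_brute)
        assert res.r_squared == pytest.approx((ss_total - ss_within) / ss_total)

    def test_matches_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        pts = rng.standard_normal((10, 3))
        pts[5:] += 1.5
        d = squareform(pdist(pts))
        groups = ["a"] * 5 + ["b"] * 5
        mine = mv.permanova(pd.DataFrame(d), groups, n_permutations=99, seed=0)
        ref = sk_permanova(
            DistanceMatrix(d, ids=[str(i) for i in range(10)]), groups,
            permutations=99,
        )
        assert mine.statistic == pytest.approx(ref["test statistic"])

    def test_separated_clusters_minimal_p(self, rng):
        # groups of 8 so the chance of a random permutation recreating the
        # observed split (the only way to tie the maximal F) is negligible
        pts = np.vstack(
            [rng.normal(0, 0.01, (8, 2)), rng.normal(100, 0.01, (8, 2))]
        )
        res = mv.permanova(_dm(pts), ["a"] * 8 + ["b"] * 8,
                           n_permutations=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)

    def test_null_p_values_approximately_uniform(self, rng):
        """Type-I error calibration: on exchangeable data the permutation p
        is ~Uniform(0,1); check rejection rate at 0.05 within a binomial CI
        over 200 replicates."""
        rejections = 0
        for rep in range(200):
            pts = rng.standard_normal((12, 3))
            groups = ["a"] * 6 + ["b"] * 6
            res = mv.permanova(_dm(pts), groups, n_permutations=99, seed=rep)
            rejections += res.p_value <= 0.05
        # Binomial(200, 0.05): 3-sigma band around 10
        assert 1 <= rejections <= 20

    def test_singleton_group_rejected(self, rng):
        pts = rng.standard_normal((5, 2))
        with pytest.raises(SterolomeError):
            mv.permanova(_dm(pts), ["a", "a", "a", "a", "b"],
                         n_permutations=9, seed=0)


class TestPairwisePermanova:
    def test_pair_count_and_bh(self, rng):
        pts = rng.standard_normal((12, 3))
        d = _dm(pts)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        table = mv.pairwise_permanova(d, groups, n_permutations=49, seed=0)
        assert len(table) == 3  # C(3, 2)
        assert (table["p_adjusted"] >= table["p_value"] - 1e-12).all()


class TestDispersion:
    def test_distances_non_negative_and_equal_spread_ns(self, rng):
        pts = np.vstack(
            [rng.normal(0, 1, (10, 2)), rng.normal(8, 1, (10, 2))]
        )
        res = mv.dispersion_test(_dm(pts), ["a"] * 10 + ["b"] * 10,
                                 n_permutations=199, seed=0)
        assert (res.extras["distances"] >= 0).all()
        assert res.p_value > 0.05

    def test_tenfold_spread_detected(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.1, (10, 2)), rng.normal(0, 1.0, (10, 2))]
        )
        res = mv.dispersion_test(_dm(pts), ["a"] * 10 + ["b"] * 10,
                                 n_permutations=199, seed=1)
        assert res.p_value < 0.05


class TestIndval:
    def test_perfect_indicator(self):
        x = pd.DataFrame(
            {"sterol": [1.0, 1.0, 0.0, 0.0, 0.0, 0.0]},
            index=[f"s{i}" for i in range(6)],
        )
        groups = ["g1", "g1", "g2", "g2", "g3", "g3"]
        table = mv.indval(x, groups, n_permutations=99, seed=0)
        best = table[table["best"]].iloc[0]
        assert best["group"] == "g1"
        assert best["A"] == pytest.approx(1.0)
        assert best["B"] == pytest.approx(1.0)
        assert best["stat"] == pytest.approx(1.0)

    def test_equal_means_give_a_equal_inverse_group_count(self):
        x = pd.DataFrame({"sterol": [2.0] * 6}, index=[f"s{i}" for i in range(6)])
        groups = ["g1", "g1", "g2", "g2", "g3", "g3"]
        table = mv.indval(x, groups, n_permutations=9, seed=0)
        assert table["A"].to_numpy() == pytest.approx([1 / 3] * 3)

    def test_matches_brute_force_definitions(self, rng):
        x = pd.DataFrame(
            rng.uniform(0, 1, (9, 4)) * (rng.uniform(0, 1, (9, 4)) > 0.3),
            index=[f"s{i}" for i in range(9)],
            columns=list("wxyz"),
        )
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        table = mv.indval(x, groups, n_permutations=9, seed=0)
        gseries = pd.Series(groups, index=x.index)
        for _, row in table.iterrows():
            col, grp = row["sterol"], row["group"]
            means = x[col].groupby(gseries).mean()
            a_brute = means[grp] / means.sum() if means.sum() > 0 else 0.0
            members = gseries == grp
            b_brute = float((x.loc[members, col] > 0).mean())
            assert row["A"] == pytest.approx(a_brute)
            assert row["B"] == pytest.approx(b_brute)
            assert row["stat"] == pytest.approx(np.sqrt(a_brute * b_brute))

    def test_specificity_sums_to_one_per_sterol(self, rng):
        x = pd.DataFrame(
            rng.uniform(0.1, 1, (8, 3)), index=[f"s{i}" for i in range(8)]
        )
        groups = ["a"] * 4 + ["b"] * 4
        table = mv.indval(x, groups, n_permutations=9, seed=0)
        sums = table.groupby("sterol")["A"].sum()
        assert sums.to_numpy() == pytest.approx(np.ones(3))


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        res = mv.kruskal_dunn([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert res["H"] == 0.0
        assert res["p_value"] == 1.0

    def test_matches_scipy_oracle(self):
        vals = [1, 2, 3, 10, 11, 12, 20, 21, 22]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = mv.kruskal_dunn(vals, groups)
        ref = stats.kruskal([1, 2, 3], [10, 11, 12], [20, 21, 22])
        assert res["H"] == pytest.approx(ref.statistic)
        assert res["p_value"] == pytest.approx(ref.pvalue)

    def test_matches_scipy_with_ties(self, rng):
        vals = rng.integers(0, 5, 20).astype(float)
        groups = ["a"] * 7 + ["b"] * 6 + ["c"] * 7
        if np.all(vals == vals[0]):
            vals[0] += 1
        res = mv.kruskal_dunn(vals, groups)
        ref = stats.kruskal(vals[:7], vals[7:13], vals[13:])
        assert res["H"] == pytest.approx(ref.statistic)

    def test_dunn_bh_monotone(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, 5), rng.normal(2, 1, 5), rng.normal(5, 1, 5)]
        )
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = mv.kruskal_dunn(vals, groups)
        pairs = res["dunn"].sort_values("p_value")
        assert (np.diff(pairs["p_adjusted"].to_numpy()) >= -1e-12).all()
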