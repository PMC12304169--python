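import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from benthoscan import community
from benthoscan.community import (
    anosim,
    bray_curtis,
    double_root,
    fit_vectors,
    kruskal_stress,
    nmds,
    shannon,
    simper,
    upgma,
)


def random_abundance(rng, n=12, p=6):
    X = rng.gamma(0.5, 1.0, size=(n, p))
    X[rng.random((n, p)) < 0.3] = 0.0
    X[X.sum(axis=1) == 0, 0] = 0.1
    return pd.DataFrame(X, index=[f"u{i}" for i in range(n)],
                        columns=[f"t{j}" for j in range(p)])


class TestDoubleRoot:
    @pytest.mark.parametrize("x, expected", [(16.0, 2.0), (0.0, 0.0), (81.0, 3.0)])
    def test_fourth_root_values(self, x, expected):
        assert double_root(np.array([[x]]))[0, 0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            double_root(np.array([[-1.0]]))

    def test_sqrt_mode(self):
        assert double_root(np.array([[16.0]]), mode="sqrt")[0, 0] == pytest.approx(4.0)


class TestBrayCurtis:
    def test_hand_computed_pair(self):
        m = pd.DataFrame([[1.0, 2, 3], [3, 2, 1]], index=["a", "b"])
        d = bray_curtis(m)
        assert d["a", "b"] == pytest.approx(4.0 / 12.0)

    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1.0, 2], [1, 2], [0.5, 0.1]], index=list("abc"))
        assert bray_curtis(m)["a", "b"] == 0.0

    def test_disjoint_support_is_one(self):
        m = pd.DataFrame([[1.0, 0], [0, 2.0]], index=["a", "b"])
        assert bray_curtis(m)["a", "b"] == pytest.approx(1.0)

    def test_all_zero_rows_excluded(self, rng):
        m = random_abundance(rng)
        m.iloc[3] = 0.0
        d = bray_curtis(m)
        assert d.shape[0] == len(m) - 1 and "u3" not in d.ids

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(float, (5, 4), elements=st.floats(0, 100)))
    def test_range_and_symmetry(self, X):
        X = X + 1e-6  # keep rows non-zero
        d = bray_curtis(pd.DataFrame(X)).data
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestUpgma:
    def test_hand_worked_three_points(self):
        d = DistanceMatrix(np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]]),
                           ids=list("ABC"))
        Z, _ = upgma(d)
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.9)

    def test_identical_points_single_cluster_at_zero(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        Z, labels = upgma(d, cut_height=0.5)
        assert np.allclose(Z[:, 2], 0.0)
        assert len(set(labels)) == 1

    def test_merge_heights_monotone(self, rng):
        m = random_abundance(rng, n=15)
        Z, _ = upgma(bray_curtis(m))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        m = pd.DataFrame(
            [[10.0, 0, 0], [11, 1, 0], [10, 0, 1], [0, 10, 10], [1, 11, 10], [0, 10, 11]],
            index=[f"u{i}" for i in range(6)])
        d = bray_curtis(m)
        res = anosim(d, ["A"] * 3 + ["B"] * 3, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        # 3+3 design: R=1 occurs for 2 of the 20 splits, so min p ~ 0.1
        assert res.p == pytest.approx(0.1, abs=0.05)

    def test_null_r_centred_on_zero(self, rng):
        rs = []
        for seed in range(20):
            m = random_abundance(np.random.default_rng(seed), n=10)
            d = bray_curtis(m)
            labels = np.array(["A"] * 5 + ["B"] * 5)
            rs.append(anosim(d, np.random.default_rng(seed).permutation(labels),
                             n_perm=99, seed=seed).r)
        assert abs(np.mean(rs)) < 0.15

    def test_matches_skbio_r_statistic(self, rng):
        m = random_abundance(rng, n=12)
        d = bray_curtis(m)
        groups = ["A"] * 6 + ["B"] * 6
        ours = anosim(d, groups, n_perm=99, seed=0)
        theirs = skbio_anosim(d, grouping=list(groups), permutations=99)
        assert ours.r == pytest.approx(float(theirs["test statistic"]), abs=1e-12)

    def test_permutation_p_matches_exhaustive_enumeration(self, rng):
        # n=6 split 3+3: only 20 distinct label assignments
        m = random_abundance(rng, n=6)
        d = bray_curtis(m)
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        res = anosim(d, groups, n_perm=999, seed=1)
        from scipy.stats import rankdata

        ranks = rankdata(d.condensed_form())
        iu, ju = np.triu_indices(6, k=1)
        r_obs = None
        r_all = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.zeros(6, dtype=int)
            lab[list(combo)] = 1
            r = community._anosim_r(ranks, lab[iu] != lab[ju], 6)
            r_all.append(r)
            if combo == (0, 1, 2):
                r_obs = r
        exact_p = np.mean([r >= r_obs for r in r_all])
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(exact_p, abs=0.05)

    def test_r_bounded_for_random_inputs(self, rng):
        for seed in range(5):
            m = random_abundance(np.random.default_rng(seed), n=9)
            res = anosim(bray_curtis(m), ["A"] * 4 + ["B"] * 5, n_perm=99, seed=seed)
            assert -1.0 <= res.r <= 1.0

    def test_singleton_group_rejected(self, rng):
        d = bray_curtis(random_abundance(rng, n=5))
        with pytest.raises(ValueError):
            anosim(d, ["A"] + ["B"] * 4)


class TestSimper:
    def test_contributions_sum_to_mean_between_dissimilarity(self, rng):
        m = random_abundance(rng, n=10)
        groups = ["A"] * 5 + ["B"] * 5
        table = simper(m, groups)
        d = bray_curtis(m).data
        between = d[:5, 5:].mean()
        assert table["contribution"].sum() == pytest.approx(between, abs=1e-12)
        assert table["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_differing_taxon_contributes_everything(self):
        m = pd.DataFrame([[1.0, 5, 2], [1, 5, 8]], index=["a", "b"], columns=list("xyz"))
        table = simper(m, ["A", "B"])
        assert table["taxon"].iloc[0] == "z"
        assert table["percent"].iloc[0] == pytest.approx(100.0)

    def test_two_singleton_groups_equal_single_pair_terms(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 2.0, 0.0])
        m = pd.DataFrame([x, y], index=["a", "b"], columns=list("pqr"))
        table = simper(m, ["A", "B"]).set_index("taxon")
        expected = np.abs(x - y) / (x + y).sum()
        for taxon, e in zip("pqr", expected):
            assert table.loc[taxon, "contribution"] == pytest.approx(e)

    def test_cumulative_percent_is_sorted_running_sum(self, rng):
        table = simper(random_abundance(rng), ["A"] * 6 + ["B"] * 6)
        assert (np.diff(table["contribution"]) <= 1e-15).all()
        assert table["cumulative_percent"].iloc[-1] == pytest.approx(100.0)


class TestShannon:
    @pytest.mark.parametrize(
        "abund, expected",
        [([5.0], 0.0), ([1.0, 1.0], np.log(2)), ([2.0] * 7, np.log(7))],
    )
    def test_known_values(self, abund, expected):
        assert shannon(abund) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])


class TestNmds:
    def test_exact_euclidean_configuration_embeds_with_tiny_stress(self, rng):
        pts = rng.random((6, 2)) * 10
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(6)])
        res = nmds(d, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_three_equidistant_points_plus_centre(self):
        # 4-point configuration from an equilateral triangle with centroid
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0.5, np.sqrt(3) / 6]])
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        res = nmds(d, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_more_dimensions_never_hurt(self, rng):
        m = random_abundance(rng, n=10)
        d = bray_curtis(m)
        s2 = nmds(d, dims=2, n_starts=8, seed=0).stress
        s1 = nmds(d, dims=1, n_starts=8, seed=0).stress
        assert s2 <= s1 + 1e-6

    def test_stress_invariant_under_rotation_and_scale(self, rng):
        m = random_abundance(rng, n=9)
        d = bray_curtis(m)
        res = nmds(d, n_starts=6, seed=0)
        X = res.coordinates.to_numpy()
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert kruskal_stress(X, d) == pytest.approx(kruskal_stress(3.0 * X @ R, d), abs=1e-9)

    def test_too_few_samples_rejected(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]]), ids=list("abc"))
        with pytest.raises(ValueError):
            nmds(d)


class TestFitVectors:
    def test_variable_equal_to_first_axis(self, rng):
        coords = pd.DataFrame(rng.normal(size=(20, 2)), columns=["nmds1", "nmds2"])
        fits = fit_vectors(coords, pd.DataFrame({"v": coords["nmds1"]}), n_perm=99, seed=0)
        assert fits["r2"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert abs(fits["dir1"].iloc[0]) == pytest.approx(1.0, abs=1e-6)

    def test_independent_variable_low_r2(self, rng):
        coords = pd.DataFrame(rng.normal(size=(50, 2)))
        fits = fit_vectors(coords, pd.DataFrame({"v": rng.normal(size=50)}), n_perm=199, seed=0)
        assert fits["r2"].iloc[0] < 0.3
        assert fits["p"].iloc[0] > 0.01

    def test_affine_rescaling_leaves_fit_unchanged(self, rng):
        coords = pd.DataFrame(rng.normal(size=(25, 2)))
        v = rng.normal(size=25)
        a = fit_vectors(coords, pd.DataFrame({"v": v}), n_perm=99, seed=3)
        b = fit_vectors(coords, pd.DataFrame({"v": 10.0 * v + 5.0}), n_perm=99, seed=3)
        assert a["r2"].iloc[0] == pytest.approx(b["r2"].iloc[0], abs=1e-10)
        assert a["p"].iloc[0] == b["p"].iloc[0]

    def test_zero_variance_variable_skipped(self, rng):
        coords = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.warns(UserWarning):
            fits = fit_vectors(coords, pd.DataFrame({"flat": np.ones(10)}), n_perm=99)
        assert len(fits) == 0
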