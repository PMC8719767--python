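"""Bray-Curtis distances and sequential-SS PERMANOVA against exact oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lingcod_burden as lb
from lingcod_burden.permanova import DissimilarityMatrix, _gower_center


class TestBrayCurtis:
    def test_identity(self):
        assert lb.bray_curtis([3, 1, 2], [3, 1, 2]) == 0.0

    def test_disjoint_supports(self):
        assert lb.bray_curtis([2, 0, 1], [0, 3, 0]) == 1.0

    def test_known_value(self):
        assert lb.bray_curtis([1, 2], [3, 0]) == pytest.approx(2 / 3, abs=1e-4)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            lb.bray_curtis([0, 0], [0, 0])

    def test_matches_scipy(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(2)
        for _ in range(20):
            u, v = rng.integers(0, 20, 6), rng.integers(0, 20, 6)
            if u.sum() == 0 and v.sum() == 0:
                continue
            assert lb.bray_curtis(u, v) == pytest.approx(braycurtis(u, v))


class TestDissimilarityMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(["a", "b"], np.array([[0.0, 0.3], [0.4, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DissimilarityMatrix(["a", "b"], np.array([[0.1, 0.3], [0.3, 0.0]]))

    def test_all_zero_fish_excluded(self, small_dataset):
        wide = small_dataset.counts.to_wide()
        wide.iloc[0] = 0
        dist, excluded = lb.community_dissimilarity(wide)
        assert excluded == [wide.index[0]]
        assert dist.n == len(wide) - 1


def _equal_distance_four_points():
    d = np.ones((4, 4)) - np.eye(4)
    return DissimilarityMatrix(["a", "b", "c", "d"], d)


class TestPermanova:
    def test_equal_distances_closed_form(self):
        """4 points, all pairwise distances 1, 2 groups of 2:
        SS_total = 1.5, SS_within = 1.0, pseudo-F = 1, p = 1."""
        dist = _equal_distance_four_points()
        factors = pd.DataFrame({"g": ["x", "x", "y", "y"]})
        table = lb.permanova(dist, factors, continuous=(), n_permutations=99, seed=0)
        row = table.set_index("term")
        assert row.loc["Total", "ss"] == pytest.approx(1.5, abs=1e-10)
        assert row.loc["Residual", "ss"] == pytest.approx(1.0, abs=1e-10)
        assert row.loc["g", "pseudo_F"] == pytest.approx(1.0, abs=1e-10)
        assert row.loc["g", "p"] == pytest.approx(1.0)

    def test_perfect_separation_boundary(self):
        """Zero within-group and constant between-group distances: residual
        SS is 0 and the pseudo-F is reported as undefined."""
        d = np.zeros((6, 6))
        d[:3, 3:] = 0.8
        d[3:, :3] = 0.8
        dist = DissimilarityMatrix(list("abcdef"), d)
        factors = pd.DataFrame({"g": ["x"] * 3 + ["y"] * 3})
        table = lb.permanova(dist, factors, continuous=(), n_permutations=49, seed=0)
        row = table.set_index("term")
        assert row.loc["Residual", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(row.loc["g", "pseudo_F"])

    def test_r2_partition_and_df(self, small_dataset):
        wide = small_dataset.counts.to_wide()
        dist, _ = lb.community_dissimilarity(wide)
        hosts = small_dataset.hosts_frame().set_index("fish_id").loc[dist.labels]
        factors = pd.DataFrame(
            {
                "sex_color": (hosts["sex"] + "-" + hosts["color"]).to_numpy(),
                "depth": hosts["depth_m"].to_numpy(),
            }
        )
        table = lb.permanova(dist, factors, n_permutations=49, seed=1)
        row = table.set_index("term")
        assert table["R2"].iloc[:-1].sum() == pytest.approx(1.0, abs=1e-10)
        assert row["df"].drop("Total").sum() == dist.n - 1
        assert (table["ss"] > -1e-9).all()

    def test_row_permutation_invariance(self, small_dataset):
        """Permuting input row order leaves every SS unchanged."""
        wide = small_dataset.counts.to_wide()
        dist, _ = lb.community_dissimilarity(wide)
        hosts = small_dataset.hosts_frame().set_index("fish_id").loc[dist.labels]
        factors = pd.DataFrame(
            {"sex_color": (hosts["sex"] + "-" + hosts["color"]).to_numpy()}
        )
        t1 = lb.permanova(dist, factors, continuous=(), n_permutations=1, seed=0)

        rng = np.random.default_rng(5)
        perm = rng.permutation(dist.n)
        dist2 = DissimilarityMatrix(
            [dist.labels[i] for i in perm], dist.values[np.ix_(perm, perm)]
        )
        t2 = lb.permanova(
            dist2, factors.iloc[perm].reset_index(drop=True), continuous=(),
            n_permutations=1, seed=0,
        )
        np.testing.assert_allclose(t1["ss"], t2["ss"], atol=1e-10)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """n = 6, one 2-level factor: Monte-Carlo p within 2 MC SEs of the
        exact p over all 6! label permutations."""
        rng = np.random.default_rng(11)
        counts = rng.integers(1, 30, size=(6, 4)).astype(float)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(counts, metric="braycurtis"))
        dist = DissimilarityMatrix(list("abcdef"), d)
        labels = np.array(["x", "x", "x", "y", "y", "y"])
        factors = pd.DataFrame({"g": labels})

        def pseudo_f(dd, lab):
            G = _gower_center(dd)
            n = 6
            X = np.column_stack([np.ones(n), (lab == "x").astype(float)])
            H = X @ np.linalg.pinv(X.T @ X) @ X.T
            ss_model = float(np.sum(H * G))
            ss_total = float(np.trace(G))
            ss_res = ss_total - ss_model
            return (ss_model / 1) / (ss_res / 4)

        f_obs = pseudo_f(d, labels)
        f_all = [
            pseudo_f(d, labels[list(perm)]) for perm in itertools.permutations(range(6))
        ]
        exact_p = np.mean([f >= f_obs - 1e-12 for f in f_all])

        table = lb.permanova(dist, factors, continuous=(), n_permutations=999, seed=3)
        mc_p = table.set_index("term").loc["g", "p"]
        mc_se = np.sqrt(exact_p * (1 - exact_p) / 999)
        assert abs(mc_p - exact_p) <= 2 * mc_se + 1 / 999

    def test_single_factor_matches_skbio(self):
        """Independent cross-check of the pseudo-F against scikit-bio."""
        from skbio.stats.distance import DistanceMatrix, permanova as skbio_permanova

        rng = np.random.default_rng(23)
        counts = rng.integers(0, 25, size=(12, 6)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(counts, metric="braycurtis"))
        labels = [f"s{i}" for i in range(12)]
        grouping = ["a"] * 4 + ["b"] * 4 + ["c"] * 4

        mine = lb.permanova(
            DissimilarityMatrix(labels, d),
            pd.DataFrame({"g": grouping}),
            continuous=(),
            n_permutations=99,
            seed=0,
        )
        ref = skbio_permanova(DistanceMatrix(d, labels), grouping, permutations=99)
        assert mine.set_index("term").loc["g", "pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-10
        )
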