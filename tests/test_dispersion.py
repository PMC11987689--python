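"""Distances, ordination, PERMDISP/PERMANOVA, and group summaries."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

import oracles
from asynchom.dispersion import (
    bray_curtis,
    compact_letter_display,
    group_mean_distance,
    pcoa,
    permanova,
    permdisp,
    tukey_hsd_dispersion,
)
from asynchom.exceptions import (
    InsufficientSamplesError,
    InvalidDesignError,
)
from asynchom.io_tables import CommunityTable


def euclidean_dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = CommunityTable(["a", "b"], ["x", "y"], np.array([[1.0, 2], [1, 2]]))
        assert bray_curtis(t)[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        t = CommunityTable(["a", "b"], ["x", "y"], np.array([[1.0, 0], [0, 3]]))
        assert bray_curtis(t)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        t = CommunityTable(["a", "b"], ["x", "y", "z"],
                           np.array([[1.0, 2, 3], [3, 2, 1]]))
        assert bray_curtis(t)[0, 1] == pytest.approx(4 / 12, abs=1e-12)

    def test_matches_skbio(self, small_community):
        import skbio.diversity

        ours = bray_curtis(small_community)
        ref = skbio.diversity.beta_diversity(
            "braycurtis", small_community.abundance, ids=small_community.plot_ids
        )
        np.testing.assert_allclose(ours.data, ref.data, atol=1e-12)


class TestPcoa:
    def test_euclidean_input_reproduced_exactly(self):
        rng = np.random.default_rng(1)
        points = rng.normal(size=(4, 2))
        eigvals, coords = pcoa(euclidean_dm(points))
        # planar data: exactly 2 positive eigenvalues reproduce the distances
        top2 = coords[:, :2]
        np.testing.assert_allclose(pdist(top2), pdist(points), atol=1e-9)
        assert (eigvals[2:] < 1e-9).all()

    def test_identical_points_all_zero_eigenvalues(self):
        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        eigvals, _ = pcoa(d)
        np.testing.assert_allclose(eigvals, 0.0, atol=1e-12)

    def test_eigenvalue_sum_equals_centered_trace(self, small_community):
        d = bray_curtis(small_community)
        eigvals, _ = pcoa(d)
        n = d.shape[0]
        a = -0.5 * d.data ** 2
        j = np.eye(n) - np.ones((n, n)) / n
        assert eigvals.sum() == pytest.approx(np.trace(j @ a @ j), abs=1e-9)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientSamplesError):
            pcoa(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))


class TestPermdisp:
    def test_zero_between_group_variance_gives_f_zero(self):
        # two triangles with identical centroid distances
        pts = np.array([
            [0, 0], [1, 0], [0.5, np.sqrt(3) / 2],
            [10, 0], [11, 0], [10.5, np.sqrt(3) / 2],
        ])
        res = permdisp(euclidean_dm(pts), ["a"] * 3 + ["b"] * 3, n_perm=99,
                       seed=0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_p_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        pts[3:] *= 3.0
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = permdisp(euclidean_dm(pts), labels, n_perm=999, seed=11)
        p_ex = oracles.exhaustive_permutation_p(res.distances, labels)
        assert abs(res.p_value - p_ex) <= 2 / (999 + 1)

    def test_euclidean_distances_match_direct_centroid_computation(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 4))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        res = permdisp(euclidean_dm(pts), labels, n_perm=99, seed=0)
        direct = np.concatenate([
            np.linalg.norm(pts[:5] - pts[:5].mean(axis=0), axis=1),
            np.linalg.norm(pts[5:] - pts[5:].mean(axis=0), axis=1),
        ])
        np.testing.assert_allclose(res.distances, direct, atol=1e-8)

    def test_singleton_group_rejected(self):
        pts = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(InvalidDesignError, match="singleton"):
            permdisp(euclidean_dm(pts), ["a", "a", "a", "b"], seed=0)

    def test_p_value_lower_bound(self, small_community, small_design):
        d = bray_curtis(small_community)
        groups = [p.disturbance for p in small_design.plots]
        res = permdisp(d, groups, n_perm=99, seed=3)
        assert res.p_value >= 1 / (99 + 1)


class TestTukeyLetters:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=12)
        pts = np.column_stack([z, np.zeros(12)])
        labels = np.array(["a", "b"] * 6)
        res = permdisp(euclidean_dm(pts), labels, n_perm=99, seed=0)
        _, letters = tukey_hsd_dispersion(res)
        assert set(letters["a"]) & set(letters["b"])

    def test_pairwise_p_symmetric_in_group_order(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(size=(5, 2)),
                         rng.normal(scale=4, size=(5, 2)),
                         rng.normal(scale=0.2, size=(5, 2))])
        labels = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        res = permdisp(euclidean_dm(pts), labels, n_perm=99, seed=0)
        pm, _ = tukey_hsd_dispersion(res)
        np.testing.assert_allclose(pm.to_numpy(), pm.to_numpy().T, atol=1e-12)

    def test_letter_display_consistency(self):
        # p-matrix where a-b differ, b-c differ, a-c do not
        p = np.array([
            [1.0, 0.01, 0.5],
            [0.01, 1.0, 0.01],
            [0.5, 0.01, 1.0],
        ])
        letters = compact_letter_display(["a", "b", "c"], p)
        assert set(letters["a"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["b"])
        assert not set(letters["b"]) & set(letters["c"])


class TestPermanova:
    def test_duplicated_samples_saturate_r2(self):
        base = np.vstack([np.zeros((6, 2)), np.full((6, 2), 5.0)])
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(euclidean_dm(base), labels, n_perm=199, seed=1)
        assert res.r_squared["factor"] > 0.999
        assert res.p_values["factor"] == pytest.approx(1 / 200, abs=1e-12)

    def test_matches_direct_f_and_exhaustive_p(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(5, 3))
        labels = np.array(["a", "a", "a", "b", "b"])
        d = euclidean_dm(pts)
        res = permanova(d, labels, n_perm=999, seed=2)
        f_direct = oracles.permanova_f_direct(d.data, labels)
        assert res.pseudo_f["factor"] == pytest.approx(f_direct, rel=1e-10)
        p_ex = oracles.exhaustive_permanova_p(d.data, labels)
        assert abs(res.p_values["factor"] - p_ex) <= 2 / (999 + 1)

    def test_matches_skbio_pseudo_f(self, small_community, small_design):
        import skbio.stats.distance

        d = bray_curtis(small_community)
        groups = [p.disturbance for p in small_design.plots]
        res = permanova(d, groups, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(d, grouping=list(groups),
                                             permutations=0)
        assert res.pseudo_f["factor"] == pytest.approx(ref["test statistic"],
                                                       rel=1e-8)

    def test_single_level_rejected(self):
        pts = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(InvalidDesignError):
            permanova(euclidean_dm(pts), ["a"] * 4)

    def test_two_factor_r2_partition_sums_to_one(self, small_community,
                                                 small_design):
        d = bray_curtis(small_community)
        factors = {
            "zone": [p.zone for p in small_design.plots],
            "disturbance": [p.disturbance for p in small_design.plots],
        }
        res = permanova(d, factors, n_perm=49, seed=0)
        assert sum(res.r_squared.values()) == pytest.approx(1.0, abs=1e-10)
        assert all(0 <= v <= 1 for v in res.r_squared.values())


class TestGroupMeanDistance:
    def _result(self, distances, labels):
        from asynchom.dispersion import DispersionResult

        return DispersionResult(
            ids=[f"s{i}" for i in range(len(distances))],
            groups=np.asarray(labels), distances=np.asarray(distances),
            group_means={}, f_statistic=0.0, p_value=1.0,
            eigenvalues=np.array([]), coordinates=np.empty((0, 0)),
            n_permutations=0,
        )

    def test_log_mean_hand_value(self):
        res = self._result([np.e, np.e ** 2, np.e, np.e ** 2],
                           ["a", "a", "b", "b"])
        out = group_mean_distance(res, log_transform=True)
        assert out.group_means["a"] == pytest.approx(1.5, abs=1e-12)

    def test_equal_groups_share_letter(self):
        res = self._result([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        out = group_mean_distance(res)
        assert set(out.letters["a"]) & set(out.letters["b"])

    def test_group_ordering_invariant_under_log(self):
        rng = np.random.default_rng(3)
        dists = np.concatenate([rng.uniform(1, 2, 6), rng.uniform(3, 4, 6)])
        labels = ["a"] * 6 + ["b"] * 6
        raw = group_mean_distance(self._result(dists, labels))
        logd = group_mean_distance(self._result(dists, labels),
                                   log_transform=True)
        assert (raw.group_means["a"] < raw.group_means["b"]) == (
            logd.group_means["a"] < logd.group_means["b"]
        )
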