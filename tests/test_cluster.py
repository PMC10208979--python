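import numpy as np
import pytest

import resikit as rk
from resikit.cluster import STATUS_KEPT, STATUS_MEAN_FRAME, STATUS_WINDOW
from resikit.errors import ValidationError

from conftest import make_table


def brute_force_neighbor_counts(coords, r, r_z=None):
    """O(N^2) oracle: counts within the (scaled) radius, excluding self."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] == 3:
        coords = coords.copy()
        coords[:, 2] *= r / r_z
    n = len(coords)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        counts[i] = int(np.sum(d <= r)) - 1
    return counts


def brute_force_local_maxima(coords, counts, r, r_z=None):
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] == 3:
        coords = coords.copy()
        coords[:, 2] *= r / r_z
    maxima = []
    for i in range(len(coords)):
        d = np.linalg.norm(coords - coords[i], axis=1)
        nbrs = [j for j in np.flatnonzero(d <= r) if j != i]
        if all(counts[j] < counts[i] or (counts[j] == counts[i] and j > i) for j in nbrs):
            maxima.append(i)
    return np.asarray(maxima)


class TestNeighborCounts:
    def test_isolated_point(self):
        tab = make_table(np.array([[0.0, 0.0], [100.0, 100.0]]))
        counts = rk.neighbor_counts(tab, rk.ClusterParams(r=5.0, n_min=1))
        assert counts.tolist() == [0, 0]

    def test_collinear_geometry(self):
        tab = make_table(np.array([[0.0, 0.0], [5.0, 0.0], [10.0, 0.0]]))
        counts = rk.neighbor_counts(tab, rk.ClusterParams(r=5.0, n_min=1))
        assert counts.tolist() == [1, 2, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_2d(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 50, size=(200, 2))
        tab = make_table(pts)
        params = rk.ClusterParams(r=4.0, n_min=1)
        np.testing.assert_array_equal(
            rk.neighbor_counts(tab, params), brute_force_neighbor_counts(pts, 4.0)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_3d(self, seed):
        rng = np.random.default_rng(100 + seed)
        pts = rng.uniform(0, 40, size=(150, 3))
        tab = make_table(pts[:, :2], z=pts[:, 2])
        params = rk.ClusterParams(r=4.0, r_z=8.0, n_min=1)
        np.testing.assert_array_equal(
            rk.neighbor_counts(tab, params),
            brute_force_neighbor_counts(pts, 4.0, r_z=8.0),
        )

    def test_3d_requires_rz(self):
        tab = make_table(np.zeros((3, 2)), z=np.arange(3.0))
        with pytest.raises(ValidationError):
            rk.neighbor_counts(tab, rk.ClusterParams(r=4.0, n_min=1))


class TestLocalMaxima:
    def test_single_cloud_one_maximum(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 2.0, size=(200, 2))
        tab = make_table(pts)
        params = rk.ClusterParams(r=4.0, n_min=1)
        counts = rk.neighbor_counts(tab, params)
        maxima = rk.find_local_maxima(tab, counts, params)
        assert len(maxima) == 1
        assert counts[maxima[0]] == counts.max()

    def test_two_separated_clouds(self):
        rng = np.random.default_rng(2)
        pts = np.concatenate(
            [rng.normal(0, 2.0, size=(100, 2)), rng.normal(40.0, 2.0, size=(100, 2))]
        )
        tab = make_table(pts)
        params = rk.ClusterParams(r=4.0, n_min=1)
        counts = rk.neighbor_counts(tab, params)
        assert len(rk.find_local_maxima(tab, counts, params)) == 2

    def test_all_isolated_points_are_maxima(self):
        pts = np.arange(10, dtype=float)[:, None] * np.array([100.0, 0.0])
        tab = make_table(pts)
        params = rk.ClusterParams(r=4.0, n_min=1)
        counts = rk.neighbor_counts(tab, params)
        maxima = rk.find_local_maxima(tab, counts, params)
        assert len(maxima) == 10 and (counts == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        pts = rng.uniform(0, 30, size=(150, 2))
        tab = make_table(pts)
        params = rk.ClusterParams(r=4.0, n_min=1)
        counts = rk.neighbor_counts(tab, params)
        np.testing.assert_array_equal(
            rk.find_local_maxima(tab, counts, params),
            brute_force_local_maxima(pts, counts, 4.0),
        )


def two_cloud_table(seed=3, k=100, sep=20.0, sigma=2.0, n_frames=10_000):
    rng = np.random.default_rng(seed)
    pts = np.concatenate(
        [rng.normal(0.0, sigma, size=(k, 2)), rng.normal(sep, sigma, size=(k, 2))]
    )
    truth = np.repeat([0, 1], k)
    return make_table(pts, n_frames=n_frames, seed=seed), truth


class TestCluster:
    def test_two_clouds_recovered(self):
        """Two sigma=2 clouds 20 nm apart, r=4, n_min=10: 2 kept clusters,
        each pure (>=95% own-cloud members) and capturing the bulk of its
        cloud (r = 2 sigma truncates the Gaussian at ~86% mass)."""
        tab, truth = two_cloud_table()
        result = rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=10))
        assert result.n_kept == 2
        for cid in result.kept_ids:
            members = truth[result.assignment == cid]
            counts = np.bincount(members, minlength=2)
            assert counts.max() / counts.sum() >= 0.95
            assert counts.max() >= 75

    def test_early_cluster_rejected_mean_frame(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 2.0, size=(100, 2))
        frames = rng.integers(0, 1000, size=100)  # first 10% of 10000 frames
        tab = make_table(pts, frames=frames)
        result = rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=10))
        assert list(result.clusters["status"]) == [STATUS_MEAN_FRAME]
        assert result.n_kept == 0

    def test_sticking_cluster_rejected_window(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 2.0, size=(100, 2))
        # 90% of frames inside one 5% window mid-acquisition, rest uniform
        frames = np.concatenate(
            [rng.integers(5000, 5500, size=90), rng.integers(0, 10_000, size=10)]
        )
        tab = make_table(pts, frames=frames)
        result = rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=10))
        assert list(result.clusters["status"]) == [STATUS_WINDOW]

    def test_uniform_cluster_kept(self):
        tab, _ = two_cloud_table(seed=6, k=80)
        result = rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=10))
        assert set(result.clusters["status"]) == {STATUS_KEPT}

    def test_n_min_strictness_and_monotonicity(self):
        tab, _ = two_cloud_table(seed=7, k=50)
        kept = [
            rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=m)).n_kept
            for m in (5, 20, 49, 50, 200)
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))
        assert kept[0] == 2 and kept[-1] == 0

    def test_strict_threshold_exact(self):
        # 12 coincident points: cluster of 12 survives n_min=11, dies at 12
        pts = np.zeros((12, 2))
        tab = make_table(pts)
        assert rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=11)).n_kept == 1
        assert rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=12)).n_kept == 0

    def test_deterministic(self):
        tab, _ = two_cloud_table(seed=8)
        a = rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=10))
        b = rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=10))
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert a.clusters.equals(b.clusters)

    def test_no_shared_localizations(self):
        tab, _ = two_cloud_table(seed=9, sep=7.0)  # overlapping clouds
        result = rk.cluster(tab, rk.ClusterParams(r=4.0, n_min=5))
        # assignment is single-valued by construction; every id is valid
        assert result.assignment.max() < len(result.clusters)

    def test_site_count_recovery_well_separated(self):
        """On layouts with inter-site distance >= 6 sigma and r = 2 sigma,
        the kept-cluster count equals the true site count for >= 99% of
        seeds, with centroid error ~ sigma/sqrt(K)."""
        sigma, k = 2.0, 100
        hits = 0
        errs = []
        n_seeds = 30
        for seed in range(n_seeds):
            lay = rk.make_layout("grid", nx=3, ny=3, pitch=6 * sigma + 10)
            (tab,) = rk.sample_localizations(lay, sigma, locs_per_site=k, seed=seed)
            res = rk.cluster(tab, rk.ClusterParams(r=2 * sigma, n_min=10))
            if res.n_kept == 9:
                hits += 1
                cent = res.clusters.loc[res.kept_ids, ["x", "y"]].to_numpy()
                for s in lay.sites:
                    d = np.min(np.linalg.norm(cent - s, axis=1))
                    errs.append(d)
        assert hits == n_seeds
        # centroid error on the order of sigma/sqrt(K) = 0.2 nm
        assert np.median(errs) < 3 * sigma / np.sqrt(k)


class TestSuggestNMin:
    def test_bimodal_mixture_threshold(self):
        rng = np.random.default_rng(10)
        counts = np.concatenate([rng.poisson(3, 2000), rng.poisson(50, 2000)])
        out = rk.suggest_n_min(counts)
        assert out["bimodal"]
        thr = out["threshold"]
        sep = np.mean((counts < thr) == (np.arange(4000) < 2000))
        assert sep >= 0.99

    def test_unimodal_flagged(self):
        rng = np.random.default_rng(11)
        out = rk.suggest_n_min(rng.poisson(20, 2000))
        assert not out["bimodal"]
        assert out["threshold"] is None

    def test_insufficient_data_flagged(self):
        out = rk.suggest_n_min([5])
        assert out["flag"] == "insufficient data"

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            rk.suggest_n_min([])
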