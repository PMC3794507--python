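import numpy as np
import pytest
from sklearn.cluster import KMeans

from gelseg.fcm import (FcmParams, FuzzyCMeans, fcm_fit, fcm_objective,
                        hard_labels, init_membership, update_centers,
                        update_membership)


class TestInitMembership:
    def test_rows_sum_to_one(self):
        U = init_membership(3, 3, seed=0)
        assert U.shape == (3, 3)
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-12)

    def test_deterministic_under_seed(self):
        np.testing.assert_array_equal(init_membership(10, 4, seed=9),
                                      init_membership(10, 4, seed=9))

    def test_single_cluster_is_all_ones(self):
        np.testing.assert_array_equal(init_membership(5, 1, seed=0), np.ones((5, 1)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            init_membership(2, 3, seed=0)


class TestUpdates:
    def test_centers_uniform_membership(self):
        U = np.full((2, 2), 0.5)
        centers = update_centers(U, np.array([0.0, 10.0]), m=2.0)
        np.testing.assert_allclose(centers, [5.0, 5.0])

    def test_centers_crisp_identity(self):
        centers = update_centers(np.eye(2), np.array([0.0, 10.0]), m=2.0)
        np.testing.assert_allclose(centers, [0.0, 10.0])

    def test_centers_constant_data(self):
        U = init_membership(4, 2, seed=1)
        np.testing.assert_allclose(update_centers(U, np.full(4, 7.0), m=2.0), [7.0, 7.0])

    def test_centers_zero_mass_rejected(self):
        U = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            update_centers(U, np.array([0.0, 1.0]), m=2.0)

    def test_membership_single_cluster(self):
        np.testing.assert_array_equal(
            update_membership(np.array([1.0, 5.0]), np.array([3.0]), m=2.0),
            np.ones((2, 1)))

    def test_membership_symmetric_midpoint(self):
        U = update_membership(np.array([5.0]), np.array([0.0, 10.0]), m=2.0)
        np.testing.assert_allclose(U, [[0.5, 0.5]])

    def test_membership_on_center_singularity(self):
        U = update_membership(np.array([0.0]), np.array([0.0, 10.0]), m=2.0)
        np.testing.assert_array_equal(U, [[1.0, 0.0]])

    def test_membership_split_between_coincident_centers(self):
        U = update_membership(np.array([0.0]), np.array([0.0, 0.0, 5.0]), m=2.0)
        np.testing.assert_array_equal(U, [[0.5, 0.5, 0.0]])

    def test_membership_rows_sum_to_one(self, rng):
        data = rng.normal(0, 50, 40)
        U = update_membership(data, np.array([-10.0, 0.0, 30.0]), m=1.7)
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-12)

    def test_bad_fuzzifier_rejected(self):
        with pytest.raises(ValueError):
            update_membership(np.array([1.0]), np.array([0.0]), m=1.0)


class TestObjective:
    def test_zero_when_points_on_centers(self):
        data = np.array([0.0, 10.0])
        assert fcm_objective(data, np.eye(2), data, m=2.0) == 0.0

    def test_hand_computed_single_center(self):
        J = fcm_objective(np.array([0.0, 10.0]), np.ones((2, 1)),
                          np.array([5.0]), m=2.0)
        assert J == pytest.approx(50.0)


class TestFcmFit:
    def test_recovers_well_separated_groups(self, rng):
        data = np.concatenate([rng.normal(0, 1, 20), rng.normal(100, 1, 20)])
        res = fcm_fit(data, FcmParams(C=2, seed=0))
        got = np.sort(res.centers)
        want = np.sort([data[:20].mean(), data[20:].mean()])
        assert np.abs(got - want).max() < 1.0
        # crisp k-means as independent oracle on the same data
        km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(data[:, None])
        np.testing.assert_allclose(got, np.sort(km.cluster_centers_.ravel()), atol=1.0)

    def test_c_equals_n_reaches_zero_objective(self):
        data = np.array([0.0, 10.0, 50.0])
        res = fcm_fit(data, FcmParams(C=3, seed=2, max_iter=300))
        assert res.objective_trace[-1] < 1e-6
        np.testing.assert_allclose(np.sort(res.centers), data, atol=1e-3)

    def test_deterministic_under_seed(self, rng):
        data = rng.integers(0, 256, 100).astype(float)
        a = fcm_fit(data, FcmParams(C=3, seed=5))
        b = fcm_fit(data, FcmParams(C=3, seed=5))
        np.testing.assert_array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.centers, b.centers)
        assert a.objective_trace == b.objective_trace

    def test_objective_trace_non_increasing_many_seeds(self, rng):
        """J_m never increases across alternating updates (100 runs)."""
        for seed in range(100):
            data = rng.integers(0, 256, 60).astype(float)
            res = fcm_fit(data, FcmParams(C=4, seed=seed))
            t = np.asarray(res.objective_trace)
            assert (np.diff(t) <= 1e-9).all()
            np.testing.assert_allclose(res.U.sum(axis=1), 1.0, atol=1e-9)

    def test_centers_within_data_range(self, rng):
        data = rng.uniform(10, 200, 50)
        res = fcm_fit(data, FcmParams(C=3, seed=1))
        assert res.centers.min() >= data.min() and res.centers.max() <= data.max()

    def test_constant_data_degenerates_gracefully(self):
        res = fcm_fit(np.full(10, 42.0), FcmParams(C=3, seed=0))
        assert res.converged
        np.testing.assert_allclose(res.centers, 42.0)
        np.testing.assert_allclose(res.U, 1.0 / 3.0)

    def test_permutation_equivariance(self):
        data = np.array([0.0, 1.0, 50.0, 51.0, 200.0, 201.0])
        U0 = init_membership(6, 3, seed=4)
        perm = [2, 0, 1]
        a = fcm_fit(data, FcmParams(C=3, seed=4), init_U=U0)
        b = fcm_fit(data, FcmParams(C=3, seed=4), init_U=U0[:, perm])
        np.testing.assert_allclose(b.centers, a.centers[perm], atol=1e-12)
        np.testing.assert_allclose(b.U, a.U[:, perm], atol=1e-12)

    def test_histogram_weighting_matches_per_pixel(self, rng):
        """Weighted FCM on unique levels equals per-pixel FCM when both
        start from the same (level-broadcast) initialization."""
        img = rng.integers(0, 8, 100).astype(float)
        levels, inverse, counts = np.unique(img, return_inverse=True,
                                            return_counts=True)
        U0 = init_membership(len(levels), 3, seed=0)
        hist = fcm_fit(levels, FcmParams(C=3, seed=0), weights=counts.astype(float),
                       init_U=U0)
        full = fcm_fit(img, FcmParams(C=3, seed=0), init_U=U0[inverse])
        np.testing.assert_allclose(hist.centers, full.centers, atol=1e-10)
        np.testing.assert_allclose(hist.U[inverse], full.U, atol=1e-10)


class TestEstimatorApi:
    def test_fit_sets_sklearn_style_attributes(self, rng):
        X = rng.normal(100, 30, (80, 1))
        est = FuzzyCMeans(n_clusters=3, random_state=0).fit(X)
        assert est.cluster_centers_.shape == (3,)
        assert est.membership_.shape == (80, 3)
        assert est.labels_.shape == (80,)
        assert (np.diff(est.cluster_centers_) >= 0).all()
        np.testing.assert_array_equal(est.predict(X), est.labels_)

    def test_get_set_params_round_trip(self):
        est = FuzzyCMeans(n_clusters=5, m=1.8)
        params = est.get_params()
        assert params["n_clusters"] == 5
        est.set_params(n_clusters=2)
        assert est.n_clusters == 2


class TestHardLabels:
    def test_tie_goes_to_larger_center(self):
        labels = hard_labels(np.array([5.0]), np.array([0.0, 10.0]))
        assert labels[0] == 1

    def test_matches_argmax_membership(self, rng):
        data = rng.uniform(0, 255, 200)
        centers = np.array([20.0, 90.0, 200.0])
        U = update_membership(data, centers, m=2.0)
        np.testing.assert_array_equal(hard_labels(data, centers),
                                      U.argmax(axis=1))
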