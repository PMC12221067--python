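import numpy as np
import pytest

from fasf_tle.config import FPCMConfig
from fasf_tle.fpcm import (
    ETA_FLOOR,
    FPCM,
    estimate_eta,
    fpcm_objective,
    fpcm_segment,
    init_centers,
    update_centers,
    update_fuzzy_memberships,
    update_possibilistic_memberships,
)


def two_class_values(seed, n=2000, means=(0.25, 0.75), sd=0.03):
    rng = np.random.default_rng(seed)
    vals = np.concatenate([rng.normal(m, sd, n) for m in means])
    truth = np.repeat(np.arange(len(means)), n)
    return vals, truth


class TestInitCenters:
    def test_quantile_percentiles(self):
        centers = init_centers(np.arange(100.0), 2, method="quantile")
        np.testing.assert_allclose(centers.ravel(), [24.75, 74.25])

    def test_c_equals_distinct_values_gives_distinct_sorted_centres(self):
        # the percentile rule interpolates, so centres land strictly
        # between the extremes but stay distinct and ordered
        centers = init_centers(np.array([3.0, 1.0, 2.0, 1.0]), 3,
                               method="quantile").ravel()
        assert np.unique(centers).size == 3
        assert np.all(np.diff(centers) > 0)
        assert centers[0] >= 1.0 and centers[-1] <= 3.0

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            init_centers(np.array([1.0, 1.0]), 2)

    def test_seeded_kmeanspp_deterministic(self):
        vals = np.random.default_rng(0).random(50)
        a = init_centers(vals, 3, seed=9, method="kmeanspp")
        b = init_centers(vals, 3, seed=9, method="kmeanspp")
        np.testing.assert_array_equal(a, b)


class TestMembershipUpdates:
    def test_fuzzy_hand_example(self):
        U = update_fuzzy_memberships(np.array([0.25]), np.array([0.0, 1.0]), 2.0)
        np.testing.assert_allclose(U, [[0.9, 0.1]], atol=1e-9)

    def test_zero_distance_wins(self):
        U = update_fuzzy_memberships(np.array([1.0]), np.array([1.0, 5.0]), 2.0)
        np.testing.assert_allclose(U, [[1.0, 0.0]])

    def test_midpoint_symmetry(self):
        U = update_fuzzy_memberships(np.array([0.5]), np.array([0.0, 1.0]), 2.0)
        np.testing.assert_allclose(U, [[0.5, 0.5]], atol=1e-12)

    def test_rows_sum_to_one_on_random_input(self):
        rng = np.random.default_rng(1)
        U = update_fuzzy_memberships(rng.random(200), rng.random(4), 1.8)
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((U >= 0) & (U <= 1))

    def test_invalid_fuzziness_rejected(self):
        with pytest.raises(ValueError, match="M"):
            update_fuzzy_memberships(np.array([0.5]), np.array([0.0, 1.0]), 1.0)

    @pytest.mark.parametrize(
        "dist_over_eta,Q,expected",
        [(0.0, 2.0, 1.0), (1.0, 3.0, 0.5), (2.0, 2.0, 0.2)],
    )
    def test_possibilistic_examples(self, dist_over_eta, Q, expected):
        A = update_possibilistic_memberships(
            np.array([dist_over_eta]), np.array([0.0]), Q, np.array([1.0])
        )
        np.testing.assert_allclose(A, [[expected]], atol=1e-12)

    def test_nonpositive_eta_rejected(self):
        with pytest.raises(ValueError, match="eta"):
            update_possibilistic_memberships(np.array([1.0]), np.array([0.0]), 2.0, 0.0)


class TestEta:
    def test_single_cluster_toy(self):
        eta = estimate_eta(np.ones((2, 1)), np.array([0.0, 2.0]), np.array([1.0]), 2.0)
        np.testing.assert_allclose(eta, [1.0])

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(2)
        vals = rng.random(50)
        centers = np.array([0.2, 0.8])
        U = update_fuzzy_memberships(vals, centers, 2.0)
        eta1 = estimate_eta(U, vals, centers, 2.0)
        s = 3.0
        eta2 = estimate_eta(U, s * vals, s * centers, 2.0)
        np.testing.assert_allclose(eta2, s**2 * eta1, rtol=1e-9)

    def test_degenerate_floor(self, caplog):
        # all voxels exactly at the centre: eta would be 0, floored
        eta = estimate_eta(np.ones((3, 1)), np.zeros(3), np.array([0.0]), 2.0)
        assert eta[0] == ETA_FLOOR


class TestObjectiveAndCenters:
    def test_objective_zero_at_centres(self):
        vals = np.array([0.0, 2.0])
        V = np.array([0.0, 2.0])
        U = np.eye(2)
        A = np.eye(2)
        assert fpcm_objective(U, A, vals, V, 2.0, 2.0) == 0.0

    def test_objective_matches_bruteforce_sum(self):
        rng = np.random.default_rng(3)
        vals = rng.random(2)
        V = rng.random(2)
        U = rng.random((2, 2))
        A = rng.random((2, 2))
        M, Q = 2.0, 3.0
        expected = 0.0
        for i in range(2):
            for c in range(2):
                d2 = (vals[i] - V[c]) ** 2
                expected += U[i, c] ** M * d2 + A[i, c] ** Q * d2
        assert abs(fpcm_objective(U, A, vals, V, M, Q) - expected) < 1e-9

    def test_centers_equal_weights_give_mean(self):
        vals = np.array([1.0, 2.0, 3.0])
        U = np.full((3, 1), 0.7)
        A = np.full((3, 1), 0.4)
        V = update_centers(U, A, vals, 2.0, 2.0)
        np.testing.assert_allclose(V, [[2.0]])

    def test_centers_weighted_mean_hand_example(self):
        vals = np.array([0.0, 10.0])
        U = np.array([[0.8], [0.2]])
        A = np.ones((2, 1))
        V = update_centers(U, A, vals, 1.0 + 1e-12, 1.0 + 1e-12)
        np.testing.assert_allclose(V, [[2.0]], atol=1e-9)

    def test_degenerate_cluster_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            update_centers(np.zeros((2, 1)), np.zeros((2, 1)), np.array([0.0, 1.0]),
                           2.0, 2.0)


class TestSegmentation:
    def test_two_class_phantom_recovery(self):
        vals, truth = two_class_values(seed=0)
        est = FPCM(n_clusters=2).fit(vals)
        centers = est.cluster_centers_.ravel()
        assert abs(centers[0] - 0.25) <= 0.02 and abs(centers[1] - 0.75) <= 0.02
        assert np.mean(est.labels_ == truth) >= 0.99
        trace = np.array(est.objective_trace_)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_single_cluster_gives_weighted_mean(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        labels, est = fpcm_segment(vals.reshape(2, 2), params=FPCMConfig(c=1))
        assert np.all(labels.labels == 1)
        assert 0.1 <= est.cluster_centers_[0, 0] <= 0.4

    def test_same_seed_reproducible(self):
        vals, _ = two_class_values(seed=5, n=400)
        a = FPCM(n_clusters=2, init="kmeanspp", random_state=3).fit(vals)
        b = FPCM(n_clusters=2, init="kmeanspp", random_state=3).fit(vals)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        np.testing.assert_array_equal(a.memberships_, b.memberships_)
        np.testing.assert_array_equal(a.cluster_centers_, b.cluster_centers_)

    def test_low_fuzziness_hardens_memberships(self):
        vals, _ = two_class_values(seed=1, n=500)
        est = FPCM(n_clusters=2, M=1.05).fit(vals)
        assert est.memberships_.max(axis=1).min() >= 0.99

    def test_out_of_mask_voxels_zero(self):
        data = np.random.default_rng(0).random((6, 6))
        mask = np.zeros((6, 6), dtype=bool)
        mask[:3] = True
        labels, _ = fpcm_segment(data, mask, FPCMConfig(c=2))
        assert np.all(labels.labels[~mask] == 0)
        assert np.all(labels.labels[mask] > 0)

    def test_cluster_ids_sorted_by_centre(self):
        vals, _ = two_class_values(seed=2, n=300)
        est = FPCM(n_clusters=2).fit(vals)
        assert est.cluster_centers_[0, 0] < est.cluster_centers_[1, 0]

    def test_predict_matches_labels_on_training_data(self):
        vals, _ = two_class_values(seed=4, n=300)
        est = FPCM(n_clusters=2).fit(vals)
        np.testing.assert_array_equal(est.predict(vals), est.labels_)

    def test_centre_recovery_across_seeds(self):
        hits = 0
        for seed in range(20):
            vals, _ = two_class_values(seed=seed, n=1000)
            est = FPCM(n_clusters=2).fit(vals)
            centers = est.cluster_centers_.ravel()
            hits += abs(centers[0] - 0.25) <= 0.02 and abs(centers[1] - 0.75) <= 0.02
        assert hits >= 19
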