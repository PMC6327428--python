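"""Ant-colony clustering: elementary operations, dynamics, recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acolink.ant_clustering import (
    EPS,
    AntParams,
    ClusterState,
    PheromoneMatrix,
    assign_points,
    euclidean_distance,
    init_pheromone,
    mutate,
    objective_F,
    run_clustering,
    transition_probabilities,
    update_centers,
    update_pheromone,
)
from acolink.synthetic import generate_blobs


class TestDistanceAndVisibility:
    def test_three_four_five(self):
        assert euclidean_distance([0, 0], [3, 4]) == 5.0

    def test_identity(self):
        x = np.arange(6.0)
        assert euclidean_distance(x, x) == 0.0

    def test_matches_elementwise_sum_oracle(self, rng):
        x, y = rng.normal(size=(2, 10))
        oracle = sum(abs(a - b) ** 2 for a, b in zip(x, y)) ** 0.5
        assert abs(euclidean_distance(x, y) - oracle) < 1e-12

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])

    def test_visibility_reciprocal(self):
        from acolink.ant_clustering import visibility

        assert visibility(2.0) == 0.5
        assert visibility(0.0, eps=1e-12) == 1e12

    def test_visibility_monotone(self, rng):
        from acolink.ant_clustering import visibility

        ds = np.sort(rng.random(20))
        vs = [visibility(d) for d in ds]
        assert all(a >= b for a, b in zip(vs, vs[1:]))


class TestInitPheromone:
    def test_boundary_distance_is_inclusive(self):
        pts = np.array([[0.0, 0.0]])
        centers = np.array([[3.0, 4.0]])
        assert init_pheromone(pts, centers, r=5.0).values[0, 0] == 1.0

    def test_beyond_radius_is_zero(self):
        pts = np.array([[0.0, 0.0]])
        centers = np.array([[3.0, 4.0]])
        assert init_pheromone(pts, centers, r=4.999).values[0, 0] == 0.0

    def test_saturation_at_large_radius(self, rng):
        pts = rng.random((8, 3))
        assert (init_pheromone(pts, pts, r=100.0).values == 1.0).all()


class TestTransitionProbabilities:
    def test_single_cluster_normalizes_to_one(self):
        assert transition_probabilities([3.0], [0.2], 1, 2).tolist() == [1.0]

    def test_zero_exponents_give_uniform(self):
        p = transition_probabilities([1, 2, 3, 4], [5, 6, 7, 8], 0.0, 0.0)
        np.testing.assert_allclose(p, 0.25)

    def test_arithmetic_example(self):
        p = transition_probabilities([1.0, 1.0], [2.0, 1.0], 1.0, 1.0)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3])

    def test_all_zero_products_raise(self):
        with pytest.raises(ValueError, match="no admissible transition"):
            transition_probabilities([0.0, 0.0], [1.0, 1.0], 1.0, 1.0)

    @given(
        T=st.lists(st.floats(0, 10), min_size=1, max_size=6),
        eta=st.lists(st.floats(0.01, 10), min_size=6, max_size=6),
        alpha=st.floats(0.1, 4.9),
        beta=st.floats(0.1, 4.9),
    )
    def test_output_is_probability_vector(self, T, eta, alpha, beta):
        T = np.asarray(T)
        eta = np.asarray(eta[: len(T)])
        if not (T**alpha * eta**beta).sum() > 0:
            return
        p = transition_probabilities(T, eta, alpha, beta)
        assert (p >= 0).all()
        assert abs(p.sum() - 1.0) < 1e-12


class TestCenterAndPheromoneUpdates:
    def test_center_is_member_mean(self):
        centers, _ = update_centers(np.array([[0.0, 0.0], [2.0, 2.0]]), [0, 0])
        np.testing.assert_allclose(centers, [[1.0, 1.0]])

    def test_singleton_center_is_the_point(self):
        centers, _ = update_centers(np.array([[3.0, 7.0], [0.0, 0.0]]), [0, 1])
        np.testing.assert_allclose(centers[0], [3.0, 7.0])

    def test_empty_clusters_dropped_and_compacted(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        centers, assign = update_centers(pts, [0, 0, 3])
        assert centers.shape[0] == 2
        assert assign.tolist() == [0, 0, 1]

    def test_random_partition_matches_mean_oracle(self, rng):
        pts = rng.normal(size=(20, 4))
        labels = rng.integers(0, 3, size=20)
        labels[:3] = [0, 1, 2]  # every cluster nonempty
        centers, assign = update_centers(pts, labels)
        for j in range(3):
            np.testing.assert_allclose(
                centers[j], pts[labels == j].mean(axis=0), atol=1e-12
            )

    def test_full_evaporation_leaves_deposit_only(self):
        T = PheromoneMatrix(np.array([[2.0]]))
        with pytest.warns(UserWarning, match="customary"):
            p = AntParams(rho_evap=1.0, Q=4.0)
        out = update_pheromone(T, np.array([[2.0]]), p)
        np.testing.assert_allclose(out.values, [[2.0]])  # deposit Q/d only

    def test_update_arithmetic(self):
        T = PheromoneMatrix(np.array([[2.0]]))
        with pytest.warns(UserWarning):  # Q=1 is on the customary boundary
            p = AntParams(rho_evap=0.5, Q=1.0)
        out = update_pheromone(T, np.array([[2.0]]), p)
        np.testing.assert_allclose(out.values, [[1.5]])

    def test_fixed_point(self):
        # T* = Q / (rho_evap * d) satisfies T' = T*
        p = AntParams(rho_evap=0.5, Q=100.0)
        d = 2.5
        T_star = p.Q / (p.rho_evap * d)
        out = update_pheromone(
            PheromoneMatrix(np.array([[T_star]])), np.array([[d]]), p
        )
        np.testing.assert_allclose(out.values, [[T_star]], rtol=1e-12)

    def test_pheromone_stays_nonnegative_and_finite(self, rng):
        p = AntParams(rho_evap=0.3, Q=50.0)
        T = PheromoneMatrix(rng.random((6, 3)))
        d = rng.random((6, 3)) * 5
        for _ in range(50):
            T = update_pheromone(T, d, p)
        assert np.isfinite(T.values).all() and (T.values >= 0).all()


def _state_for(points, assignments, r=2.0):
    points = np.asarray(points, float)
    assignments = np.asarray(assignments, int)
    centers, assignments = update_centers(points, assignments)
    pher = init_pheromone(points, centers, r)
    st_ = ClusterState(
        assignments=assignments,
        centers=centers,
        pheromone=pher,
        objective=0.0,
        best_objective=np.inf,
    )
    st_.objective = objective_F(points, st_)
    st_.best_objective = st_.objective
    return st_


class TestObjective:
    def test_zero_when_points_at_centers(self):
        pts = np.array([[0.0, 0.0], [5.0, 5.0]])
        st_ = _state_for(pts, [0, 1])
        assert objective_F(pts, st_) == 0.0

    def test_two_points_shared_center(self):
        pts = np.array([[-2.0], [2.0]])
        st_ = _state_for(pts, [0, 0])
        assert objective_F(pts, st_) == 4.0

    def test_matches_loop_oracle(self, rng):
        pts = rng.normal(size=(15, 3))
        labels = rng.integers(0, 3, size=15)
        labels[:3] = [0, 1, 2]
        st_ = _state_for(pts, labels)
        oracle = np.mean(
            [
                sum((pts[i, c] - st_.centers[st_.assignments[i], c]) ** 2
                    for c in range(3))
                for i in range(15)
            ]
        )
        assert abs(objective_F(pts, st_) - oracle) < 1e-12


class TestAssignPoints:
    def test_two_separated_pairs_form_two_clusters(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0], [100.0, 0.0]])
        params = AntParams(r=1.0, p0=0.5, seed=0)
        st_ = _state_for(pts, [0, 0, 0, 0], r=1.0)
        rng = np.random.default_rng(0)
        out = assign_points(pts, st_, params, rng)
        assert out.n_clusters == 2
        assert out.assignments[0] == out.assignments[1]
        assert out.assignments[2] == out.assignments[3]
        assert out.assignments[0] != out.assignments[2]

    def test_p0_at_least_one_gives_all_singletons(self):
        pts = np.arange(10.0).reshape(5, 2)
        params = AntParams(r=100.0, p0=1.0, seed=0)
        st_ = _state_for(pts, [0] * 5, r=100.0)
        out = assign_points(pts, st_, params, np.random.default_rng(0))
        assert out.n_clusters == 5

    def test_identical_points_share_one_cluster(self):
        pts = np.ones((6, 3))
        params = AntParams(r=1.0, seed=0)
        st_ = _state_for(pts, [0] * 6, r=1.0)
        out = assign_points(pts, st_, params, np.random.default_rng(0))
        assert out.n_clusters == 1


class TestMutate:
    def test_zero_rate_is_identity(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        st_ = _state_for(pts, [0, 0, 1])
        params = AntParams(mutation_rate=0.0, seed=0)
        out = mutate(pts, st_, params, np.random.default_rng(0))
        assert out is st_

    def test_single_cluster_is_noop(self):
        pts = np.array([[0.0], [1.0]])
        st_ = _state_for(pts, [0, 0])
        out = mutate(pts, st_, AntParams(mutation_rate=1.0), np.random.default_rng(0))
        assert out is st_

    def test_beneficial_move_accepted_when_drawn(self):
        # point at 9.0 mis-assigned to the cluster at ~0; enumerate all
        # possible single moves: only moving it to cluster 1 lowers F
        pts = np.array([[0.0], [1.0], [9.0], [10.0], [11.0]])
        st_ = _state_for(pts, [0, 0, 0, 1, 1])
        params = AntParams(mutation_rate=1.0, seed=0)
        best_move_F = None
        for i in range(5):
            for target in range(2):
                if target == st_.assignments[i]:
                    continue
                trial = st_.assignments.copy()
                trial[i] = target
                centers, trial_c = update_centers(pts, trial)
                F = float(
                    ((pts - centers[trial_c]) ** 2).sum(axis=1).mean()
                )
                if best_move_F is None or F < best_move_F:
                    best_move_F = F
        assert best_move_F < st_.objective  # the instance has a better move
        accepted = False
        for trial_seed in range(200):
            out = mutate(pts, st_, params, np.random.default_rng(trial_seed))
            if out is not st_:
                accepted = True
                assert out.best_objective < st_.best_objective
                assert out.assignments[2] == 1  # the mis-assigned point moved
        assert accepted

    def test_best_objective_nonincreasing_over_mutations(self, rng):
        pts = rng.normal(size=(12, 2)) * 3
        labels = rng.integers(0, 3, 12)
        labels[:3] = [0, 1, 2]
        st_ = _state_for(pts, labels)
        params = AntParams(mutation_rate=1.0, seed=0)
        best = st_.best_objective
        for _ in range(50):
            st_ = mutate(pts, st_, params, rng)
            assert st_.best_objective <= best + 1e-15
            best = st_.best_objective


class TestRunClustering:
    def test_single_point(self):
        out = run_clustering(np.array([[1.0, 2.0]]), AntParams(seed=0))
        assert out.n_clusters == 1
        assert out.objective == 0.0
        assert out.n_iter == 1

    def test_blob_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        pts, labels = generate_blobs(30, 2, 3, center_sep=10.0, sigma=0.5, seed=0)
        out = run_clustering(pts, AntParams(seed=0))
        assert adjusted_rand_score(labels, out.assignments) >= 0.9

    def test_same_seed_is_bitwise_identical(self):
        pts, _ = generate_blobs(20, 2, 2, seed=1)
        a = run_clustering(pts, AntParams(seed=7))
        b = run_clustering(pts, AntParams(seed=7))
        assert np.array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_permutation_invariance_up_to_relabeling(self, rng):
        from sklearn.metrics import adjusted_rand_score

        pts, _ = generate_blobs(15, 2, 3, seed=2)
        perm = rng.permutation(len(pts))
        a = run_clustering(pts, AntParams(seed=3))
        b = run_clustering(pts[perm], AntParams(seed=3))
        assert adjusted_rand_score(a.assignments[perm], b.assignments) == 1.0

    def test_best_objective_history_nonincreasing(self):
        pts, _ = generate_blobs(20, 3, 3, seed=4)
        out = run_clustering(pts, AntParams(seed=4))
        hist = np.array(out.history)
        assert (np.diff(hist) <= 1e-15).all()


class TestAntParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho_evap": 0.0},
            {"rho_evap": 1.5},
            {"Q": 0.0},
            {"alpha": -1.0},
            {"mutation_rate": 1.5},
            {"r": -1.0},
        ],
    )
    def test_fatal_values_raise(self, kwargs):
        with pytest.raises(ValueError):
            AntParams(**kwargs)

    def test_customary_range_violation_warns_only(self):
        with pytest.warns(UserWarning, match="customary"):
            AntParams(alpha=4.99, beta=2, Q=20000.0)
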