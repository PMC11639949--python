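"""Tests of the fuzzy expectation-maximization clustering stage."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from femvoice.fem_cluster import (
    ClusterModel,
    FemConfig,
    FuzzyEMClustering,
    e_step,
    fit_fem,
    init_centers,
    m_step,
    objective,
)


def naive_e_step(data, centers, m):
    """Independent straightforward membership computation (loops, ratios)."""
    data, centers = np.atleast_2d(data), np.atleast_2d(centers)
    n, k = data.shape[0], centers.shape[0]
    u = np.zeros((n, k))
    for i in range(n):
        d = np.array([np.linalg.norm(data[i] - centers[j]) for j in range(k)])
        if np.any(d == 0):
            u[i, int(np.argmax(d == 0))] = 1.0
            continue
        for j in range(k):
            u[i, j] = 1.0 / np.sum((d[j] / d) ** (2.0 / (m - 1.0)))
    return u


def naive_m_step(data, u, m):
    w = u**m
    return (w.T @ data) / w.sum(axis=0)[:, None]


class TestInit:
    def test_normal_center_is_mean_of_normal_points(self):
        data = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0], [7.0, 7.0]])
        mask = np.array([True, True, False, False])
        centers, normal_index = init_centers(data, mask, n_clusters=3, seed=0)
        assert normal_index == 2
        np.testing.assert_allclose(centers[2], [1.0, 1.0])

    def test_non_normal_centers_are_data_points(self):
        rng = np.random.default_rng(1)
        data = rng.random((30, 4))
        mask = np.zeros(30, bool)
        mask[:5] = True
        centers, _ = init_centers(data, mask, n_clusters=5, seed=3)
        for c in centers[:-1]:
            assert np.any(np.all(np.isclose(data, c), axis=1))

    def test_seeded_determinism(self):
        data = np.random.default_rng(2).random((20, 3))
        mask = np.arange(20) < 4
        a, _ = init_centers(data, mask, 4, seed=9)
        b, _ = init_centers(data, mask, 4, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_empty_normal_set_rejected(self):
        data = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ValueError, match="normal"):
            init_centers(data, np.zeros(10, bool), 3, seed=0)

    def test_too_few_distinct_points_rejected(self):
        data = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(ValueError, match="distinct"):
            init_centers(data, np.ones(10, bool), 5, seed=0)


class TestESTep:
    def test_hand_worked_membership(self):
        # distances (1, 2) at m = 2: mu = (1/(1+1/4), 1/(4+1)) = (0.8, 0.2)
        u = e_step(np.array([[0.0, 0.0]]), np.array([[1.0, 0.0], [2.0, 0.0]]), 2.0)
        np.testing.assert_allclose(u, [[0.8, 0.2]], atol=1e-12)

    def test_equidistant_point_uniform(self):
        u = e_step(np.array([[0.0, 0.0]]), np.array([[1.0, 0.0], [-1.0, 0.0]]), 2.0)
        np.testing.assert_allclose(u, [[0.5, 0.5]], atol=1e-12)

    def test_point_on_center_gets_indicator_row(self):
        centers = np.array([[1.0, 1.0], [3.0, 3.0]])
        u = e_step(centers[1][None], centers, 2.0)
        np.testing.assert_array_equal(u, [[0.0, 1.0]])

    def test_first_zero_distance_center_wins_tie(self):
        centers = np.array([[1.0, 1.0], [1.0, 1.0]])
        u = e_step(np.array([[1.0, 1.0]]), centers, 2.0)
        np.testing.assert_array_equal(u, [[1.0, 0.0]])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        u = e_step(rng.random((50, 3)), rng.random((4, 3)), 1.7)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((u >= 0) & (u <= 1))

    def test_m_equal_one_rejected(self):
        with pytest.raises(ValueError, match="m"):
            e_step(np.zeros((2, 2)), np.ones((2, 2)), 1.0)

    def test_matches_naive_implementation(self):
        rng = np.random.default_rng(8)
        data, centers = rng.random((25, 4)), rng.random((3, 4))
        for m in (1.5, 2.0, 3.0):
            np.testing.assert_allclose(
                e_step(data, centers, m), naive_e_step(data, centers, m), atol=1e-12
            )


class TestMStep:
    def test_full_membership_gives_global_mean(self):
        data = np.random.default_rng(3).random((10, 2))
        u = np.ones((10, 1))
        np.testing.assert_allclose(m_step(data, u, 2.0)[0], data.mean(axis=0), atol=1e-12)

    def test_degenerate_weights_pick_single_point(self):
        data = np.array([[0.0], [2.0]])
        u = np.array([[1.0], [0.0]])
        np.testing.assert_allclose(m_step(data, u, 2.0), [[0.0]], atol=1e-15)

    def test_hand_worked_weighted_mean(self):
        # points {0, 1}, mu = (0.8, 0.2), m = 2 -> (0.64*0 + 0.04*1)/0.68
        data = np.array([[0.0], [1.0]])
        u = np.array([[0.8], [0.2]])
        np.testing.assert_allclose(m_step(data, u, 2.0), [[0.04 / 0.68]], atol=1e-12)

    def test_dead_cluster_reinitialized_from_data(self, caplog):
        data = np.array([[1.0, 1.0], [2.0, 2.0]])
        u = np.array([[1.0, 0.0], [1.0, 0.0]])
        with caplog.at_level("WARNING"):
            centers = m_step(data, u, 2.0, rng=np.random.default_rng(0))
        assert any(np.allclose(centers[1], p) for p in data)
        assert "reinitialized" in caplog.text


class TestObjective:
    def test_zero_iff_points_on_centers(self):
        data = np.array([[0.0, 0.0], [1.0, 1.0]])
        u = np.eye(2)
        assert objective(data, u, data, 2.0) == 0.0

    def test_single_point_unit_distance(self):
        assert objective(np.array([[1.0, 0.0]]), np.array([[1.0]]),
                         np.array([[0.0, 0.0]]), 2.0) == pytest.approx(1.0)

    def test_alternation_never_increases_objective(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            data = rng.random((40, 3)) * 4
            centers = data[rng.choice(40, 3, replace=False)]
            prev = np.inf
            for _ in range(15):
                u = e_step(data, centers, 2.0)
                centers = m_step(data, u, 2.0)
                j = objective(data, u, centers, 2.0)
                assert j <= prev + 1e-9
                prev = j


class TestFit:
    def test_separated_blobs_recovered_exactly(self, two_blob_data):
        X, labels, normal_mask = two_blob_data
        res = fit_fem(X, normal_mask, FemConfig(n_clusters=2, seed=0, standardize=False))
        hard = res.U.argmax(axis=1)
        # cluster 1 is the normal anchor -> blob b
        assert np.array_equal(hard, labels)
        assert res.converged

    def test_huge_tolerance_stops_after_one_iteration(self, two_blob_data):
        X, _, normal_mask = two_blob_data
        res = fit_fem(X, normal_mask, FemConfig(n_clusters=2, seed=0,
                                                tol_centers=1e9, tol_memberships=1e9))
        assert res.n_iter == 1
        assert res.converged_by in ("centers", "membership")

    def test_membership_rows_sum_to_one(self, two_blob_data):
        X, _, normal_mask = two_blob_data
        res = fit_fem(X, normal_mask, FemConfig(n_clusters=2, seed=1))
        np.testing.assert_allclose(res.U.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_trace_non_increasing(self, two_blob_data):
        X, _, normal_mask = two_blob_data
        res = fit_fem(X, normal_mask, FemConfig(n_clusters=2, seed=2))
        trace = np.asarray(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_fixed_point_satisfies_self_consistency(self):
        # on tiny instances the converged (U, C) must satisfy the E/M
        # equations as evaluated by an independent naive implementation
        rng = np.random.default_rng(23)
        for n, k in ((12, 2), (20, 3)):
            data = rng.random((n, 3)) * 3
            mask = np.zeros(n, bool)
            mask[:3] = True
            res = fit_fem(data, mask, FemConfig(n_clusters=k, seed=1, standardize=False,
                                                tol_centers=1e-12, tol_memberships=1e-12,
                                                max_iter=2000))
            u_check = naive_e_step(data, res.model.centers, res.model.m)
            np.testing.assert_allclose(res.U, u_check, atol=1e-8)
            c_check = naive_m_step(data, res.U, res.model.m)
            np.testing.assert_allclose(res.model.centers, c_check, atol=1e-8)

    def test_permutation_equivariance(self, two_blob_data):
        X, _, normal_mask = two_blob_data
        res = fit_fem(X, normal_mask, FemConfig(n_clusters=2, seed=3, standardize=False))
        perm = np.random.default_rng(0).permutation(X.shape[0])
        u_perm = res.model.predict_membership(X[perm])
        np.testing.assert_allclose(u_perm, res.model.predict_membership(X)[perm], atol=1e-12)

    def test_predict_membership_matches_e_step_bitwise(self, two_blob_data):
        X, _, normal_mask = two_blob_data
        res = fit_fem(X, normal_mask, FemConfig(n_clusters=2, seed=4, standardize=False))
        np.testing.assert_array_equal(
            res.model.predict_membership(X), e_step(X, res.model.centers, res.model.m)
        )

    def test_synthetic_type_recovery_ari(self):
        from femvoice.synthetic_corpus import CorpusConfig, generate_feature_corpus

        scores = []
        for seed in range(3):
            cfg = CorpusConfig(n_types=6, utterances_per_type=4,
                               frames_per_utterance=(15, 25), min_separation=6.0,
                               seed=100 + seed)
            utterances, specs = generate_feature_corpus(cfg)
            X = np.vstack([u.frames for u in utterances])
            truth = np.concatenate(
                [np.full(u.frames.shape[0], u.type_id) for u in utterances]
            )
            normal_type = next(s.type_id for s in specs if s.is_normal)
            res = fit_fem(X, truth == normal_type,
                          FemConfig(n_clusters=6, seed=seed, tol_centers=1e-5,
                                    tol_memberships=1e-5))
            scores.append(adjusted_rand_score(truth, res.U.argmax(axis=1)))
        assert np.mean(scores) >= 0.9


class TestEstimatorApi:
    def test_sklearn_params_roundtrip_and_clone(self):
        est = FuzzyEMClustering(n_clusters=4, m=1.8, random_state=2)
        params = est.get_params()
        assert params["n_clusters"] == 4 and params["m"] == 1.8
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(m=2.5)
        assert est.m == 2.5

    def test_fitted_attributes_and_predict(self, two_blob_data):
        X, labels, normal_mask = two_blob_data
        est = FuzzyEMClustering(n_clusters=2, random_state=0).fit(X, normal_mask=normal_mask)
        assert est.normal_index_ == 1
        assert est.cluster_centers_.shape == (2, X.shape[1])
        assert est.membership_.shape == (X.shape[0], 2)
        assert np.array_equal(est.predict(X), labels)
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_missing_normal_mask_is_an_error(self, two_blob_data):
        X, _, _ = two_blob_data
        with pytest.raises(ValueError, match="normal_mask"):
            FuzzyEMClustering(n_clusters=2).fit(X)

    def test_standardized_centers_reported_in_input_units(self, two_blob_data):
        X, _, normal_mask = two_blob_data
        est = FuzzyEMClustering(n_clusters=2, standardize=True, random_state=0)
        est.fit(X, normal_mask=normal_mask)
        # the normal-anchored center must sit near the normal blob's mean
        np.testing.assert_allclose(
            est.cluster_centers_[est.normal_index_], X[normal_mask].mean(axis=0), atol=0.5
        )


class TestModelIO:
    def test_json_roundtrip(self, tmp_path, two_blob_data):
        X, _, normal_mask = two_blob_data
        res = fit_fem(X, normal_mask, FemConfig(n_clusters=2, seed=0))
        p = tmp_path / "model.json"
        res.model.to_json(p)
        loaded = ClusterModel.from_json(p)
        np.testing.assert_allclose(loaded.centers, res.model.centers, atol=1e-12)
        np.testing.assert_allclose(
            loaded.predict_membership(X), res.model.predict_membership(X), atol=1e-12
        )
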