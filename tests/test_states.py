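import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

import defnpipe as dp
from defnpipe.states import elbow_from_inertia, network_mean_t
from defnpipe.stats import fdr_bh


class TestL1KMedians:
    def test_two_clouds_perfect_recovery(self, rng):
        a = rng.normal(0, 0.5, size=(40, 6))
        b = rng.normal(10, 0.5, size=(40, 6))
        X = np.vstack([a, b])
        labels_true = np.r_[np.zeros(40), np.ones(40)]
        model = dp.cluster_states_two_step(X, 2, n_init=5, max_iter=100, seed=0)
        assert adjusted_rand_score(labels_true, model.labels) == 1.0

    def test_k1_centroid_is_median(self, rng):
        X = rng.standard_normal((30, 4))
        model = dp.cluster_states_two_step(X, 1, n_init=2, max_iter=50, seed=0)
        np.testing.assert_allclose(model.centroids[0], np.median(X, axis=0))

    def test_row_permutation_same_partition(self, rng):
        X = np.vstack([rng.normal(0, 1, (25, 5)), rng.normal(6, 1, (25, 5))])
        perm = rng.permutation(50)
        m1 = dp.cluster_states_two_step(X, 2, n_init=5, max_iter=100, seed=1)
        m2 = dp.cluster_states_two_step(X[perm], 2, n_init=5, max_iter=100, seed=1)
        assert adjusted_rand_score(m1.labels[perm], m2.labels) == 1.0

    def test_assignment_matches_bruteforce_nearest_centroid(self, rng):
        # oracle: independent nearest-centroid scan over small problems
        for K in (2, 3):
            X = rng.standard_normal((150, 8))
            model = dp.cluster_states_two_step(X, K, n_init=4, max_iter=100, seed=K)
            d = np.array(
                [[np.abs(x - c).sum() for c in model.centroids] for x in X]
            )
            assert np.array_equal(model.labels - 1, d.argmin(axis=1))

    def test_refinement_never_increases_inertia(self, rng):
        X = rng.standard_normal((120, 6))
        step1 = dp.L1KMedians(n_clusters=3, n_init=6, max_iter=5, random_state=0).fit(X)
        model = dp.cluster_states_two_step(X, 3, n_init=6, max_iter=200, seed=0)
        assert model.inertia <= step1.inertia_ + 1e-9

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((60, 5))
        m1 = dp.cluster_states_two_step(X, 2, n_init=4, max_iter=100, seed=9)
        m2 = dp.cluster_states_two_step(X, 2, n_init=4, max_iter=100, seed=9)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)


class TestElbow:
    def test_hand_second_difference(self):
        assert elbow_from_inertia([1, 2, 3, 4, 5, 6], [100, 60, 20, 18, 17, 16]) == 3

    def test_recovers_four_separated_clusters(self, rng):
        centers = np.eye(4)[:, :4] * 12
        X = np.vstack([rng.normal(c, 0.4, size=(30, 4)) for c in centers])
        k = dp.elbow_select_k(X, list(range(1, 9)), seed=0, n_init=5)
        assert k == 4

    def test_inertia_nonincreasing_in_k(self, rng):
        X = rng.standard_normal((80, 5))
        inertias = []
        for k in range(1, 6):
            if k == 1:
                inertias.append(np.abs(X - np.median(X, axis=0)).sum())
            else:
                inertias.append(
                    dp.L1KMedians(n_clusters=k, n_init=8, max_iter=200, random_state=0)
                    .fit(X).inertia_
                )
        assert all(b <= a * 1.001 for a, b in zip(inertias, inertias[1:]))

    def test_short_range_rejected(self, rng):
        with pytest.raises(ValueError):
            dp.elbow_select_k(rng.standard_normal((20, 3)), [2, 3], seed=0)


class TestOccupancyMetrics:
    def test_frequencies_sum_to_one(self, rng):
        X = rng.standard_normal((50, 4))
        model = dp.cluster_states_two_step(X, 3, n_init=3, max_iter=50, seed=0)
        f = dp.state_frequencies(model)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dwell_and_transitions_hand_count(self):
        d = dp.dwell_time([1, 1, 2, 2])
        assert d == {1: 2.0, 2: 2.0}
        T, flagged = dp.transition_matrix([1, 1, 2, 2], K=2)
        np.testing.assert_allclose(T[0], [0.5, 0.5])
        np.testing.assert_allclose(T[1], [0.0, 1.0])
        assert flagged == []

    def test_constant_sequence(self):
        assert dp.dwell_time([2] * 7) == {2: 7.0}
        T, flagged = dp.transition_matrix([2] * 7, K=3)
        np.testing.assert_allclose(T[1], [0, 1, 0])
        assert set(flagged) == {1, 3}  # unvisited states get uniform rows
        np.testing.assert_allclose(T.sum(axis=1), 1.0)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            dp.transition_matrix([1], K=2)


class TestEpisodeStateFC:
    def _series(self, windows):
        return dp.DynFCSeries(np.asarray(windows, dtype=float),
                              np.arange(len(windows)))

    def test_mean_of_assigned_windows(self):
        w1 = np.array([[0, 0.2], [0.2, 0]])
        w2 = np.array([[0, 0.4], [0.4, 0]])
        series = self._series([w1, w2])
        m = dp.episode_state_fc(series, [1, 1], state=1)
        assert m[0, 1] == pytest.approx(0.3)

    def test_absent_state_flagged(self):
        series = self._series([np.zeros((2, 2))])
        assert dp.episode_state_fc(series, [1], state=2) is None

    def test_all_windows_one_state_equals_global_mean(self, rng):
        w = rng.standard_normal((5, 3, 3))
        w = (w + np.transpose(w, (0, 2, 1))) / 2
        series = self._series(w)
        np.testing.assert_allclose(
            dp.episode_state_fc(series, [1] * 5, 1), w.mean(axis=0)
        )


class TestConditionContrast:
    def _cohort(self, diffs, base_seed=0):
        rng = np.random.default_rng(base_seed)
        cohort = {}
        for i, d in enumerate(diffs):
            base = rng.standard_normal(d.size)
            cohort[f"s{i:02d}"] = {"a_happy": base + d, "b_sad": base}
        return cohort

    def test_identical_conditions_no_significance(self):
        cohort = self._cohort([np.zeros(20)] * 5)
        c = dp.state_condition_contrast(cohort, state=1)
        assert np.all(c.t == 0) and not c.significant.any()

    def test_planted_edges_detected_with_controlled_fdr(self):
        n_edges, planted = 300, np.arange(10)
        hits, fps = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cohort = {}
            for i in range(30):
                d = rng.normal(0, 0.1, n_edges)
                d[planted] += 0.3
                base = rng.standard_normal(n_edges)
                cohort[f"s{i:02d}"] = {"a_happy": base + d, "b_sad": base}
            c = dp.state_condition_contrast(cohort, state=1)
            hits.append(c.significant[planted].sum())
            fps.append(c.significant[10:].sum())
        assert np.mean(hits) >= 9
        assert np.mean(fps) <= 0.05 * (n_edges - 10)

    def test_sign_convention_first_condition_positive(self):
        rng = np.random.default_rng(8)
        cohort = self._cohort([np.full(15, 0.5) + rng.normal(0, 0.05, 15) for _ in range(6)])
        c = dp.state_condition_contrast(cohort, state=1)
        assert (c.t > 0).all()  # happy > sad => positive t

    def test_too_few_included_subjects_refused(self):
        cohort = {"s1": {"a": np.ones(4), "b": np.ones(4)},
                  "s2": {"a": None, "b": np.ones(4)},
                  "s3": {"a": np.ones(4), "b": np.ones(4)}}
        with pytest.raises(ValueError, match="2 subjects"):
            dp.state_condition_contrast(cohort, state=1)

    def test_q_monotone_in_p(self):
        cohort = self._cohort(
            [np.r_[np.full(5, 0.4), np.zeros(45)] + 0.05 * np.random.default_rng(3).standard_normal(50)
             for _ in range(12)]
        )
        c = dp.state_condition_contrast(cohort, 1)
        order = np.argsort(c.p)
        assert (np.diff(c.q[order]) >= -1e-12).all()


class TestNetworkMeanT:
    def test_hand_means_and_null_flags(self, tiny_partition):
        t = np.zeros(10)
        q = np.ones(10)
        # edges 0,1 are within-A; put significant t of 3 and 5 there
        em = tiny_partition.pair_edge_indices()
        aa = em[("A", "A")]
        t[aa[0]], t[aa[1]] = 3.0, 5.0
        q[aa[0]] = q[aa[1]] = 0.01
        contrast = dp.EdgeContrast(1, t, q.copy(), q, alpha=0.05, n_included=10)
        mat, pairs = network_mean_t(contrast, tiny_partition)
        assert pairs[("A", "A")] == pytest.approx(4.0)
        assert np.isnan(pairs[("A", "B")]) and np.isnan(pairs[("B", "B")])

    def test_all_null_when_nothing_significant(self, tiny_partition):
        contrast = dp.EdgeContrast(1, np.ones(10), np.ones(10), np.ones(10), 0.05, 5)
        _, pairs = network_mean_t(contrast, tiny_partition)
        assert all(np.isnan(v) for v in pairs.values())
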