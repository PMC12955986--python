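import numpy as np
import pytest
from scipy import stats as sps

import defnpipe as dp
from defnpipe.simulate import _condition_chains, _default_effect_pairs, nearest_pd_correlation


class TestNearestPD:
    def test_repairs_indefinite_matrix(self, rng):
        m = np.full((4, 4), 0.9)
        np.fill_diagonal(m, 1.0)
        m[0, 1] = m[1, 0] = -0.9  # inconsistent with the other 0.9s
        r = nearest_pd_correlation(m)
        w = np.linalg.eigvalsh(r)
        assert w.min() > 0
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r, r.T)

    def test_pd_input_unchanged(self):
        m = np.array([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(nearest_pd_correlation(m), m, atol=1e-12)


class TestHealthyCohort:
    def test_determinism(self):
        cfg = dp.desk_scale_config(seed=3, n_subjects=2, n_timepoints=60)
        e1, _, t1 = dp.gen_healthy_cohort(cfg)
        e2, _, t2 = dp.gen_healthy_cohort(cfg)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a["ts"], b["ts"])
        for k in t1.state_sequences:
            np.testing.assert_array_equal(t1.state_sequences[k], t2.state_sequences[k])

    def test_cohort_structure(self):
        cfg = dp.desk_scale_config(seed=1, n_subjects=3, n_timepoints=50)
        episodes, part, truth = dp.gen_healthy_cohort(cfg)
        assert len(episodes) == 3 * 2 * cfg.episodes_per_condition
        assert episodes[0]["ts"].shape == (50, part.n_rois)
        assert set(truth.state_sequences) == {(e["subject_id"], e["episode_id"]) for e in episodes}
        for seq in truth.state_sequences.values():
            assert seq.min() >= 1 and seq.max() <= cfg.K

    def test_transition_rows_stochastic(self):
        cfg = dp.desk_scale_config()
        chains = _condition_chains(cfg)
        for T in chains.values():
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-9)

    def test_single_state_window_fc_matches_truth(self):
        # one latent state, no condition effect: long-run mean window FC
        # approximates the generating correlation
        cfg = dp.desk_scale_config(seed=7, n_subjects=1, episodes_per_condition=3,
                                   n_timepoints=600, K=1, effect_delta=0.0)
        episodes, part, truth = dp.gen_healthy_cohort(cfg)
        cond = episodes[0]["condition"]
        wins = np.concatenate(
            [
                dp.sliding_window_fc(ep["ts"], dp.DfcConfig(fisher_z=False)).windows
                for ep in episodes
                if ep["condition"] == cond
            ]
        )
        mean_fc = wins.mean(axis=0)
        np.fill_diagonal(mean_fc, 1.0)
        target = truth.true_centroid_fc[(1, cond)]
        assert np.max(np.abs(mean_fc - target)) < 0.1

    def test_two_state_windows_closer_to_own_centroid(self):
        cfg = dp.desk_scale_config(seed=11, n_subjects=4, n_timepoints=300, K=2,
                                   effect_delta=0.0)
        episodes, part, truth = dp.gen_healthy_cohort(cfg)
        iu, ju = np.triu_indices(part.n_rois, k=1)
        cents = {
            s: dp.fisher_z(truth.true_centroid_fc[(s, "sad")][iu, ju]) for s in (1, 2)
        }
        inside, correct = 0, 0
        for ep in [e for e in episodes if e["condition"] == "sad"]:
            path = truth.state_sequences[(ep["subject_id"], ep["episode_id"])]
            series = dp.sliding_window_fc(ep["ts"], dp.DfcConfig())
            for w, st in enumerate(series.window_start_indices):
                seg = path[st : st + 30]
                if np.ptp(seg) != 0:
                    continue  # only windows wholly inside a latent segment
                inside += 1
                v = series.vectors()[w]
                d = {s: np.abs(v - c).sum() for s, c in cents.items()}
                correct += int(min(d, key=d.get) == seg[0])
        assert inside > 50
        assert correct / inside >= 0.95

    def test_state_path_matches_stationary_occupancy(self):
        # chi-square goodness of fit of a long simulated path
        cfg = dp.desk_scale_config(seed=2)
        chains = _condition_chains(cfg)
        pi = dp.gen_healthy_cohort(
            dp.desk_scale_config(seed=2, n_subjects=1, n_timepoints=10)
        )[2].stationary["happy"]
        rng = np.random.default_rng(0)
        T = chains["happy"]
        n = 100_000
        path = np.empty(n, dtype=int)
        path[0] = 0
        for t in range(1, n):
            path[t] = rng.choice(cfg.K, p=T[path[t - 1]])
        counts = np.bincount(path, minlength=cfg.K)
        # thin to quasi-independent draws to respect the chi-square assumptions
        thin = path[::200]
        counts = np.bincount(thin, minlength=cfg.K)
        p = sps.chisquare(counts, pi * counts.sum()).pvalue
        assert p > 0.01

    def test_generated_fc_symmetric_unit_diagonal(self):
        cfg = dp.desk_scale_config(seed=4, n_subjects=1, n_timepoints=80)
        _, _, truth = dp.gen_healthy_cohort(cfg)
        for m in truth.true_centroid_fc.values():
            np.testing.assert_allclose(m, m.T)
            np.testing.assert_allclose(np.diag(m), 1.0)

    def test_effect_edges_in_upper_triangle_of_designated_pairs(self):
        cfg = dp.desk_scale_config(seed=6, n_subjects=1, n_timepoints=40)
        _, part, truth = dp.gen_healthy_cohort(cfg)
        pairs = set(_default_effect_pairs(part))
        idx = part.roi_network_index
        labels = part.network_labels
        for i, j in truth.condition_effect_edges:
            assert i < j
            lo, hi = sorted((idx[i], idx[j]))  # pair keys follow label order
            assert (labels[lo], labels[hi]) in pairs


class TestClinicalCohort:
    def _truth(self, es=1.0, coupling=None, pairs=None):
        part = dp.gen_network_partition([4, 4, 4], ["A", "B", "C"])
        pairs = pairs if pairs is not None else (("A", "B"),)
        return part, dp.ClinicalCohortTruth(pairs, es, coupling or {})

    def test_patient_edges_shifted(self):
        part, truth = self._truth(es=2.0)
        X, g, ph = dp.gen_clinical_cohort(200, 200, part, truth, seed=0)
        eff = part.pair_edge_indices()[("A", "B")]
        other = np.setdiff1d(np.arange(X.shape[1]), eff)
        gap_eff = X[g == 1][:, eff].mean() - X[g == 0][:, eff].mean()
        gap_other = X[g == 1][:, other].mean() - X[g == 0][:, other].mean()
        assert gap_eff == pytest.approx(2.0 * 0.2, abs=0.05)
        assert abs(gap_other) < 0.03

    def test_phenotype_table_columns(self):
        part, truth = self._truth()
        X, g, ph = dp.gen_clinical_cohort(10, 12, part, truth, seed=1)
        assert list(ph.columns) == ["subject_id", "group", "age", "sex", "score"]
        assert (ph["group"] == "patient").sum() == 12
        assert set(ph["sex"]) <= {0, 1}

    def test_empty_pairs_with_effect_rejected(self):
        part, truth = self._truth(es=1.0, pairs=())
        with pytest.raises(ValueError, match="effect_pairs"):
            dp.gen_clinical_cohort(5, 5, part, truth, seed=0)

    def test_negative_effect_size_rejected(self):
        with pytest.raises(ValueError):
            dp.ClinicalCohortTruth((("A", "B"),), -0.5)

    def test_null_effect_gives_chance_auc(self):
        from defnpipe.experiments import clinical_transfer_run

        aucs = [clinical_transfer_run(seed, effect_size=0.0)["masked_auc"] for seed in range(8)]
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_strong_effect_masked_accuracy_over_70(self):
        from defnpipe import experiments as ex

        part = ex.clinical_desk_partition()
        pairs = tuple(ex.planted_clinical_pairs(part))[:3]
        accs = []
        for seed in range(5):
            out = ex.clinical_transfer_run(seed, effect_size=1.0)
            accs.append(out["masked_accuracy"])
        assert np.mean(accs) > 0.7

    def test_confound_shortcut_removed_by_infold_regression(self):
        from defnpipe.experiments import confound_control_run

        before, after = zip(*(confound_control_run(seed) for seed in range(8)))
        assert np.mean(before) > 0.55  # classifier exploits age coupling
        assert 0.4 <= np.mean(after) <= 0.6
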