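"""Validation experiments on synthetic cohorts with known ground truth.

The real study data are restricted, so the pipeline's claims are checked by
recovery experiments: can the state clustering recover planted latent
states, does the DEFN ranking surface the planted divergent network pairs,
and does the DEFN mask transfer into a genuine classification advantage on
clinical cohorts whose group effect is confined to those pairs?  Each
experiment here is a self-contained function of a seed, shared by the test
suite and the reproduction script.

Study conditions (fixed defaults, see the methods note): healthy cohorts at
desk scale (40 ROIs / 6 networks / 12 subjects, 200 time points, K = 3
states); clinical cohorts on a 96-ROI / 12-network parcellation (4560
edges) with 3 planted between-network pairs, a 0.25-SD edge shift, and
50 + 50 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import decoding, states, transfer
from .decoding import DefnWeights
from .dfc import DfcConfig, sliding_window_fc
from .partition import NetworkPartition, gen_network_partition
from .pipeline import RunConfig, stage1_decode
from .reference import (
    DEMOGRAPHIC_SUMMARIES,
    EMOTION_DECODER_ACCURACY,
    REPORTED_CHI2,
    REPORTED_T,
    SEX_TABLES,
)
from .simulate import (
    ClinicalCohortTruth,
    _default_effect_pairs,
    desk_scale_config,
    gen_clinical_cohort,
    gen_healthy_cohort,
)
from .stats import pearson_chi2, t_from_summary

__all__ = [
    "recompute_demographics",
    "reference_optimal_combo",
    "window_majority_states",
    "state_recovery",
    "defn_recovery",
    "clinical_desk_partition",
    "planted_clinical_pairs",
    "planted_weights",
    "clinical_transfer_run",
    "permutation_null_loso",
    "permutation_null_nested",
    "confound_control_run",
]

CLINICAL_EFFECT_SIZE = 0.25
CLINICAL_N_PER_GROUP = 50


# --------------------------------------------------------------------------
# published-summary recomputations


def recompute_demographics():
    """Recompute every demographic test statistic from printed summaries.

    Returns {key: (computed, reported)} for the pooled t statistics and the
    sex-distribution chi-squares of both clinical cohorts.
    """
    out = {}
    for key, (g_ctrl, g_pat) in DEMOGRAPHIC_SUMMARIES.items():
        out[("t",) + key] = (t_from_summary(g_ctrl, g_pat).statistic, REPORTED_T[key])
    for cohort, table in SEX_TABLES.items():
        out[("chi2", "sex", cohort)] = (pearson_chi2(table).statistic, REPORTED_CHI2[cohort])
    return out


@dataclass(frozen=True)
class _Summary:
    mean_accuracy: float
    sd_accuracy: float


def reference_optimal_combo(accuracy_tolerance: float = 0.5):
    """Apply the optimal-model rule to the published decoder accuracy table."""
    results = {c: _Summary(m, s) for c, (m, s) in EMOTION_DECODER_ACCURACY.items()}
    return decoding.select_optimal_model(results, accuracy_tolerance)


# --------------------------------------------------------------------------
# stage-1 recovery


def window_majority_states(series_list, truth):
    """Majority latent state per window, the clustering recovery target."""
    maj = []
    for s in series_list:
        path = truth.state_sequences[(s.subject_id, s.episode_id)]
        w = s.config.window_length
        for st in s.window_start_indices:
            maj.append(int(np.bincount(path[st : st + w]).argmax()))
    return np.asarray(maj)


def state_recovery(seed: int, n_init: int = 8):
    """Cluster a generated desk-scale cohort at the true K and score the
    adjusted Rand index against window-majority latent states."""
    cfg = desk_scale_config(seed=seed)
    episodes, partition, truth = gen_healthy_cohort(cfg)
    series = [
        sliding_window_fc(ep["ts"], DfcConfig(), subject_id=ep["subject_id"],
                          episode_id=ep["episode_id"], condition=ep["condition"])
        for ep in episodes
    ]
    V = np.vstack([s.vectors() for s in series])
    model = states.cluster_states_two_step(V, cfg.K, n_init=n_init, max_iter=300, seed=seed + 1)
    ari = adjusted_rand_score(window_majority_states(series, truth), model.labels)
    return {"ari": float(ari), "K": cfg.K, "n_windows": int(V.shape[0]),
            "frequencies": states.state_frequencies(model).tolist()}


def defn_recovery(seed: int):
    """Full stage 1 on one seeded cohort; precision-at-k of the DEFN ranking
    against the planted divergent pairs (k = number planted)."""
    cfg = RunConfig(sim=desk_scale_config(seed=seed), k=3, n_init=8,
                    n_selected=200, seed=seed)
    s1 = stage1_decode(cfg)
    planted = set(_default_effect_pairs(s1["partition"]))
    ranked = transfer.rank_network_pairs(s1["defn_weights"])
    k = len(planted)
    topk = set(ranked[:k])
    return {
        "precision_at_k": len(topk & planted) / k,
        "k": k,
        "optimal_combo": s1["optimal_combo"],
        "optimal_accuracy": s1["decoding_results"][s1["optimal_combo"]].mean_accuracy,
        "n_stable": len(s1["stable_features"]),
    }


# --------------------------------------------------------------------------
# stage-2 transfer


def clinical_desk_partition() -> NetworkPartition:
    """96 ROIs in 12 equal networks: enough whole-brain edges (4560) for the
    baseline to face a realistic features-to-samples ratio."""
    return gen_network_partition((8,) * 12, tuple(f"N{i:02d}" for i in range(1, 13)))


def planted_clinical_pairs(partition=None):
    partition = partition or clinical_desk_partition()
    return _default_effect_pairs(partition)


def planted_weights(partition=None, pairs=None) -> DefnWeights:
    """DEFN weights with the planted pairs at the top of the ranking (the
    transfer experiments isolate the masking machinery from stage 1)."""
    partition = partition or clinical_desk_partition()
    pairs = tuple(pairs or planted_clinical_pairs(partition))
    w = {pr: (1.0 if pr in pairs else 0.0) for pr in partition.network_pairs()}
    return DefnWeights(w, {}, partition.pair_edge_counts())


def clinical_transfer_run(seed: int, effect_size: float = CLINICAL_EFFECT_SIZE,
                          confounds: bool = False, coupling=None):
    """Masked nested-CV vs whole-brain baseline on one clinical cohort."""
    partition = clinical_desk_partition()
    pairs = planted_clinical_pairs(partition)
    weights = planted_weights(partition, pairs)
    truth = ClinicalCohortTruth(pairs, effect_size, dict(coupling or {}))
    X, groups, phenotype = gen_clinical_cohort(
        CLINICAL_N_PER_GROUP, CLINICAL_N_PER_GROUP, partition, truth, seed=seed
    )
    conf = phenotype[["age", "sex"]] if confounds else None
    masked = transfer.nested_cv_classify(X, groups, weights, partition,
                                         confounds=conf, seed=seed)
    baseline = transfer.baseline_classify(X, groups, confounds=conf, seed=seed)
    chi2, p = transfer.mcnemar_compare(masked.predictions, baseline.predictions, groups)
    return {
        "masked_accuracy": masked.accuracy,
        "baseline_accuracy": baseline.accuracy,
        "gap": masked.accuracy - baseline.accuracy,
        "masked_auc": masked.auc,
        "baseline_auc": baseline.auc,
        "final_n_top": masked.final_n_top,
        "mcnemar_chi2": chi2,
        "mcnemar_p": p,
        "leakage_free": masked.leakage_free,
        "importance": masked.importance,
    }


# --------------------------------------------------------------------------
# permutation and confound nulls


@lru_cache(maxsize=1)
def _fixed_decoding_samples():
    """One desk-scale cohort's optimal-combo design matrix, reused across
    label permutations (the permutation null holds the data fixed)."""
    cfg = RunConfig(sim=desk_scale_config(seed=97), k=3, n_init=8,
                    n_selected=200, seed=97)
    s1 = stage1_decode(cfg)
    combo = s1["optimal_combo"]
    X, y, groups, _ = decoding.build_combo_samples(s1["cohort_state_fc"], combo)
    return X, y, groups


def permutation_null_loso(seed: int) -> float:
    """Mean LOSO accuracy of the emotion decoder under shuffled labels."""
    X, y, groups = _fixed_decoding_samples()
    rng = np.random.default_rng(seed)
    y_perm = rng.permutation(y)
    cfg = decoding.DecoderConfig(n_selected=200)
    res = decoding.loso_decode(X, y_perm, groups, cfg)
    return res.mean_accuracy


@lru_cache(maxsize=1)
def _fixed_clinical_cohort():
    partition = clinical_desk_partition()
    pairs = planted_clinical_pairs(partition)
    truth = ClinicalCohortTruth(pairs, CLINICAL_EFFECT_SIZE)
    X, groups, _ = gen_clinical_cohort(
        CLINICAL_N_PER_GROUP, CLINICAL_N_PER_GROUP, partition, truth, seed=97
    )
    return partition, X, groups


def permutation_null_nested(seed: int):
    """Pooled accuracy and AUC of the masked nested-CV classifier under
    shuffled group labels."""
    partition, X, groups = _fixed_clinical_cohort()
    rng = np.random.default_rng(seed)
    y_perm = rng.permutation(groups)
    rep = transfer.nested_cv_classify(X, y_perm, planted_weights(partition), partition, seed=seed)
    return rep.accuracy, rep.auc, rep.leakage_free


def confound_control_run(seed: int, age_slope: float = 0.01):
    """No group effect, but features coupled to age while the groups differ
    in age: the classifier can exceed chance via the confound alone, and
    in-fold confound regression must remove that shortcut."""
    partition = clinical_desk_partition()
    pairs = planted_clinical_pairs(partition)
    truth = ClinicalCohortTruth(pairs, 0.0, {"age": age_slope})
    X, groups, phenotype = gen_clinical_cohort(
        CLINICAL_N_PER_GROUP, CLINICAL_N_PER_GROUP, partition, truth, seed=seed
    )
    conf = phenotype[["age", "sex"]]
    before = transfer.baseline_classify(X, groups, seed=seed)
    after = transfer.baseline_classify(X, groups, confounds=conf, seed=seed)
    return before.auc, after.auc
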