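"""End-to-end two-stage pipeline on synthetic (or user-supplied) cohorts.

Stage 1 — emotion decoding in the healthy cohort: sliding-window dFC,
two-step L1 k-means brain states, per-episode state-averaged FC, the
2^K - 1 state-combination LOSO decoders, optimal-model selection, stable
features and DEFN network-pair weights.

Stage 2 — clinical transfer: a patient/control cohort with a group effect
planted in the same network pairs that diverge between emotions, DEFN-
masked nested-CV classification against a whole-brain baseline, McNemar
comparison and network importance.

A single root seed deterministically derives per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import decoding, states, transfer
from .dfc import DfcConfig, sliding_window_fc
from .partition import gen_network_partition
from .simulate import ClinicalCohortTruth, SimConfig, desk_scale_config, gen_clinical_cohort, gen_healthy_cohort

__all__ = ["RunConfig", "run_pipeline", "stage1_decode", "derive_seeds"]


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=desk_scale_config)
    window_length: int = 30
    step: int = 2
    n_init: int = 10
    max_iter: int = 300
    k: int | None = None  # None -> elbow selection over k_range
    k_range: tuple = (1, 2, 3, 4, 5)
    relief_neighbors: int = 10
    n_selected: int = 200
    svm_cost: float = 1.0
    n_controls: int = 50
    n_patients: int = 50
    clinical_effect_size: float = 1.0
    confound_coupling: dict = field(default_factory=dict)
    use_confounds: bool = True
    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0


def derive_seeds(root_seed: int, n: int = 6):
    """Per-stage child seeds (below 2^31) from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def stage1_decode(config: RunConfig, seeds=None):
    """Healthy-cohort stage: simulate, window, cluster, decode, DEFN."""
    seeds = seeds or derive_seeds(config.seed)
    sim = dataclasses.replace(config.sim, seed=seeds[0])
    episodes, partition, truth = gen_healthy_cohort(sim)
    dfc_cfg = DfcConfig(config.window_length, config.step)
    series = [
        sliding_window_fc(
            ep["ts"], dfc_cfg,
            subject_id=ep["subject_id"], episode_id=ep["episode_id"], condition=ep["condition"],
        )
        for ep in episodes
    ]
    vectors = np.vstack([s.vectors() for s in series])
    keys = [
        (s.subject_id, s.episode_id, int(w)) for s in series for w in range(s.n_windows)
    ]
    if config.k is None:
        K = states.elbow_select_k(
            vectors, list(config.k_range), seed=seeds[1], n_init=max(3, config.n_init // 3),
            max_iter=config.max_iter,
        )
    else:
        K = config.k
    model = states.cluster_states_two_step(
        vectors, K, n_init=config.n_init, max_iter=config.max_iter, seed=seeds[1], keys=keys
    )
    cohort = decoding.compute_cohort_state_fc(series, model)
    dec_cfg = decoding.DecoderConfig(
        svm_cost=config.svm_cost,
        relief_neighbors=config.relief_neighbors,
        n_selected=config.n_selected,
        seed=seeds[2],
    )
    results = {}
    for combo in decoding.enumerate_combos(K):
        try:
            X, y, groups, n_exc = decoding.build_combo_samples(cohort, combo)
            res = decoding.loso_decode(X, y, groups, dec_cfg, combo=combo)
            res.n_excluded_episodes = n_exc
            results[combo] = res
        except ValueError:
            continue  # combo unusable on this cohort (state too rare)
    optimal = decoding.select_optimal_model(results)
    stable = decoding.stable_features(results[optimal].selected_sets)
    weights = decoding.defn_weights(stable, optimal, partition)
    return {
        "partition": partition,
        "truth": truth,
        "series": series,
        "state_model": model,
        "K": K,
        "cohort_state_fc": cohort,
        "decoding_results": results,
        "optimal_combo": optimal,
        "stable_features": stable,
        "defn_weights": weights,
    }


def run_pipeline(config: RunConfig, out_dir=None):
    """Run both stages; returns a JSON-serializable results bundle (plus the
    in-memory stage objects under the ``objects`` key)."""
    seeds = derive_seeds(config.seed)
    s1 = stage1_decode(config, seeds)
    partition, weights = s1["partition"], s1["defn_weights"]

    clin_truth = ClinicalCohortTruth(
        effect_pairs=_effect_pairs_of(config, partition),
        effect_size=config.clinical_effect_size,
        confound_coupling=dict(config.confound_coupling),
    )
    X, groups, phenotype = gen_clinical_cohort(
        config.n_controls, config.n_patients, partition, clin_truth, seed=seeds[3]
    )
    conf = phenotype[["age", "sex"]] if config.use_confounds else None
    masked = transfer.nested_cv_classify(
        X, groups, weights, partition,
        outer_folds=config.outer_folds, inner_folds=config.inner_folds,
        confounds=conf, svm_cost=config.svm_cost, seed=seeds[4],
    )
    baseline = transfer.baseline_classify(
        X, groups, folds=config.outer_folds, confounds=conf,
        svm_cost=config.svm_cost, seed=seeds[4],
    )
    stat, p = transfer.mcnemar_compare(masked.predictions, baseline.predictions, groups)

    freq = states.state_frequencies(s1["state_model"])
    bundle = {
        "version": "defnpipe-0.1.0",
        "seed": config.seed,
        "stage1": {
            "K": s1["K"],
            "state_frequencies": freq.tolist(),
            "optimal_combo": list(s1["optimal_combo"]),
            "optimal_mean_accuracy": s1["decoding_results"][s1["optimal_combo"]].mean_accuracy,
            "optimal_sd_accuracy": s1["decoding_results"][s1["optimal_combo"]].sd_accuracy,
            "n_stable_features": len(s1["stable_features"]),
            "accuracy_table": {
                "".join(map(str, c)): [r.mean_accuracy, r.sd_accuracy]
                for c, r in s1["decoding_results"].items()
            },
        },
        "stage2": {
            "masked_accuracy": masked.accuracy,
            "masked_auc": masked.auc,
            "baseline_accuracy": baseline.accuracy,
            "baseline_auc": baseline.auc,
            "final_n_top": masked.final_n_top,
            "mcnemar_chi2": stat,
            "mcnemar_p": p,
            "leakage_free": bool(masked.leakage_free),
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "results.json", "w") as fh:
            json.dump(bundle, fh, indent=1, sort_keys=True)
    bundle["objects"] = {"stage1": s1, "masked": masked, "baseline": baseline,
                        "phenotype": phenotype}
    return bundle


def _effect_pairs_of(config: RunConfig, partition):
    from .simulate import _default_effect_pairs

    if config.sim.effect_pairs is not None:
        return tuple(tuple(pr) for pr in config.sim.effect_pairs)
    return _default_effect_pairs(partition)
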