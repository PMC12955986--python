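"""Synthetic cohorts with known ground truth.

Two generators back the pipeline's recovery tests:

* a healthy cohort watching alternating happy/sad episodes, whose ROI time
  series are drawn from latent recurring connectivity states — each state a
  network-block correlation template, visited along a per-condition Markov
  chain — with a condition effect planted on designated edges;
* clinical cohorts (patients vs controls) whose static-FC feature vectors
  carry a standardized group shift confined to designated network pairs,
  with age/sex covariates optionally coupled to the features.

All sampling is multivariate normal; templates are projected to the nearest
positive-definite correlation matrix before use, and that projected matrix
is what the truth record reports, so recovery tests compare against exactly
what was sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partition import NetworkPartition, gen_network_partition

__all__ = [
    "SimConfig",
    "HealthyCohortTruth",
    "ClinicalCohortTruth",
    "default_labels",
    "full_scale_config",
    "desk_scale_config",
    "nearest_pd_correlation",
    "gen_healthy_cohort",
    "gen_clinical_cohort",
]

logger = logging.getLogger(__name__)

#: 17 cortical network labels (two- or three-way splits of visual,
#: somatomotor, attention, limbic, frontoparietal and default-mode systems,
#: plus a temporoparietal network) and one subcortical network.
FULL_LABELS = (
    "VNa", "VNb", "SMNa", "SMNb", "DANa", "DANb", "VANa", "VANb",
    "LNa", "LNb", "FPNa", "FPNb", "FPNc", "DMNa", "DMNb", "DMNc",
    "TPN", "SN",
)
#: ROI counts per network: 400 cortical + 32 subcortical = 432.
FULL_SIZES = (24,) * 16 + (16, 32)


def default_labels(n: int):
    if n == len(FULL_LABELS):
        return FULL_LABELS
    return tuple(f"N{i + 1:02d}" for i in range(n))


@dataclass(frozen=True)
class SimConfig:
    """Healthy-cohort generator settings.

    Defaults describe the emulated study: 51 subjects, 3 episodes per
    condition (6 total), 600 time points per episode, 432 ROIs in 18
    networks, 4 latent states.  ``desk_scale_config`` gives the small
    configuration used in tests (40 ROIs / 6 networks / 12 subjects).
    """

    n_subjects: int = 51
    episodes_per_condition: int = 3
    n_timepoints: int = 600
    network_sizes: tuple = FULL_SIZES
    network_labels: tuple = FULL_LABELS
    K: int = 4
    noise_sd: float = 0.3
    r_active: float = 0.6
    r_base: float = 0.1
    effect_delta: float = 0.25
    effect_pairs: tuple | None = None  # None -> 3 default between-network pairs
    stay_prob: float = 0.98
    condition_bias: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if len(self.network_sizes) != len(self.network_labels):
            raise ValueError("network_sizes and network_labels must match")
        if min(self.network_sizes) <= 0 or self.n_subjects <= 0 or self.n_timepoints <= 0:
            raise ValueError("all counts must be positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def n_rois(self) -> int:
        return int(sum(self.network_sizes))


def full_scale_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


def desk_scale_config(**overrides) -> SimConfig:
    """Small configuration keeping test runs to seconds."""
    defaults = dict(
        n_subjects=12,
        episodes_per_condition=3,
        n_timepoints=200,
        network_sizes=(8, 8, 7, 7, 6, 4),
        network_labels=("VN", "SMN", "DAN", "LN", "DMN", "SN"),
        K=3,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class HealthyCohortTruth:
    """Ground truth behind a generated healthy cohort."""

    state_sequences: dict  # (subject_id, episode_id) -> per-timepoint state, 1..K
    true_centroid_fc: dict  # (state, condition) -> correlation matrix actually sampled
    condition_effect_edges: frozenset  # upper-triangle (i, j) ROI index pairs
    transition_matrices: dict  # condition -> K x K row-stochastic matrix
    stationary: dict  # condition -> length-K stationary distribution


@dataclass(frozen=True)
class ClinicalCohortTruth:
    """Planted group effect for a clinical cohort."""

    effect_pairs: tuple  # network-pair label tuples carrying the effect
    effect_size: float  # standardized mean shift per affected edge
    confound_coupling: dict = field(default_factory=dict)  # {"age": slope, "sex": slope}

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


# --------------------------------------------------------------------------
# positive-definite repair


def nearest_pd_correlation(A: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the nearest PD correlation matrix.

    Eigenvalues are clipped at ``eps`` and the result rescaled to unit
    diagonal.  A repair (any clipped eigenvalue) is logged.
    """
    A = (A + A.T) / 2
    w, V = np.linalg.eigh(A)
    if w.min() < eps:
        logger.info("nearest-PD repair: min eigenvalue %.3g clipped to %.1g", w.min(), eps)
        w = np.clip(w, eps, None)
        A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2


# --------------------------------------------------------------------------
# healthy cohort


def _state_template(config: SimConfig, partition: NetworkPartition, state: int) -> np.ndarray:
    """Correlation template of one latent state.

    Networks whose index is congruent to ``state`` (mod K) are "active":
    their within-block correlation is ``r_active``; other blocks sit at
    ``r_base``; between-block correlation is 0.  Distinct active sets make
    the K templates block-orthogonal, hence separable under L1 clustering.
    """
    idx = partition.roi_network_index
    p = partition.n_rois
    m = np.zeros((p, p))
    same = idx[:, None] == idx[None, :]
    active_nets = np.flatnonzero(np.arange(partition.n_networks) % config.K == state)
    is_active_roi = np.isin(idx, active_nets)
    active_block = same & is_active_roi[:, None]
    m[same] = config.r_base
    m[active_block] = config.r_active
    np.fill_diagonal(m, 1.0)
    return m


def _default_effect_pairs(partition: NetworkPartition, n_pairs: int = 3):
    """Deterministic default: the first few between-network pairs."""
    between = [pr for pr in partition.network_pairs() if pr[0] != pr[1]]
    return tuple(between[:n_pairs])


def _condition_chains(config: SimConfig):
    """Per-condition sticky Markov chains with distinct stationary weights.

    Off-diagonal mass is split in proportion to condition-specific weights
    (geometric ramp with ratio 1 + condition_bias, increasing across states
    for "happy" and decreasing for "sad"), so the two conditions occupy the
    states with different long-run frequencies.
    """
    K = config.K
    ratio = 1.0 + config.condition_bias
    w_happy = ratio ** np.arange(K)
    w_sad = w_happy[::-1].copy()
    chains = {}
    for cond, w in (("happy", w_happy), ("sad", w_sad)):
        T = np.zeros((K, K))
        for i in range(K):
            others = np.delete(np.arange(K), i)
            if others.size:
                ww = w[others] / w[others].sum()
                T[i, others] = (1 - config.stay_prob) * ww
            T[i, i] = config.stay_prob if others.size else 1.0
        chains[cond] = T
    return chains


def _stationary(T: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eig(T.T)
    v = np.real(V[:, np.argmin(np.abs(w - 1))])
    v = np.abs(v)
    return v / v.sum()


def gen_healthy_cohort(config: SimConfig, partition: NetworkPartition | None = None):
    """Generate a healthy cohort with latent state dynamics.

    Returns
    -------
    episodes : list of dict
        One per (subject, condition, episode): keys ``subject_id``,
        ``episode_id``, ``condition``, ``ts`` (n_timepoints x n_rois).
    partition : NetworkPartition
    truth : HealthyCohortTruth
    """
    if partition is None:
        partition = gen_network_partition(config.network_sizes, config.network_labels)
    if partition.n_rois != config.n_rois:
        raise ValueError("partition does not match config network sizes")
    rng = np.random.default_rng(config.seed)
    p = partition.n_rois

    if config.effect_pairs is None:
        effect_pairs = _default_effect_pairs(partition)
    else:
        effect_pairs = tuple(tuple(pr) for pr in config.effect_pairs)
    if any(pr not in set(partition.network_pairs()) for pr in effect_pairs):
        raise ValueError("effect pair not a valid network pair")
    pair_edges = partition.pair_edge_indices()
    iu, ju = np.triu_indices(p, k=1)
    effect_edge_idx = (
        np.unique(np.concatenate([pair_edges[pr] for pr in effect_pairs]))
        if effect_pairs
        else np.array([], dtype=int)
    )
    effect_edges = frozenset(zip(iu[effect_edge_idx].tolist(), ju[effect_edge_idx].tolist()))

    # per (state, condition) correlation: template (+ effect on happy),
    # blended with noise_sd^2 of white variance, PD-repaired; that final
    # matrix is the truth.
    true_fc = {}
    chols = {}
    for s in range(config.K):
        base = _state_template(config, partition, s)
        for cond in ("happy", "sad"):
            m = base.copy()
            if cond == "happy" and effect_edge_idx.size:
                m[iu[effect_edge_idx], ju[effect_edge_idx]] += config.effect_delta
                m[ju[effect_edge_idx], iu[effect_edge_idx]] += config.effect_delta
                m = np.clip(m, -0.99, 0.99)
                np.fill_diagonal(m, 1.0)
            cov = m + config.noise_sd**2 * np.eye(p)
            corr = nearest_pd_correlation(cov / (1 + config.noise_sd**2))
            true_fc[(s + 1, cond)] = corr
            chols[(s + 1, cond)] = np.linalg.cholesky(corr + 1e-10 * np.eye(p))

    chains = _condition_chains(config)
    stationary = {c: _stationary(T) for c, T in chains.items()}

    episodes = []
    state_sequences = {}
    for si in range(config.n_subjects):
        sid = f"sub{si + 1:03d}"
        for cond in ("happy", "sad"):
            T_mat = chains[cond]
            for ei in range(config.episodes_per_condition):
                eid = f"{cond}{ei + 1}"
                path = np.empty(config.n_timepoints, dtype=int)
                path[0] = rng.choice(config.K, p=stationary[cond])
                for t in range(1, config.n_timepoints):
                    path[t] = rng.choice(config.K, p=T_mat[path[t - 1]])
                z = rng.standard_normal((config.n_timepoints, p))
                ts = np.empty((config.n_timepoints, p))
                for s in range(config.K):
                    rows = path == s
                    if rows.any():
                        ts[rows] = z[rows] @ chols[(s + 1, cond)].T
                episodes.append(
                    {"subject_id": sid, "episode_id": eid, "condition": cond, "ts": ts}
                )
                state_sequences[(sid, eid)] = path + 1

    truth = HealthyCohortTruth(state_sequences, true_fc, effect_edges, chains, stationary)
    return episodes, partition, truth


# --------------------------------------------------------------------------
# clinical cohort


def gen_clinical_cohort(
    n_controls: int,
    n_patients: int,
    partition: NetworkPartition,
    truth: ClinicalCohortTruth,
    seed: int = 0,
    edge_sd: float = 0.2,
    age_means: tuple = (45.0, 40.0),
    age_sd: float = 10.0,
    sex_p: tuple = (0.4, 0.5),
    score_means: tuple = (8.0, 25.0),
    score_sd: float = 6.0,
):
    """Generate static-FC feature vectors for a patient/control cohort.

    Each subject's feature vector holds one Fisher-Z-scale value per
    upper-triangle edge, N(0, edge_sd) around a zero baseline; patient
    edges inside ``truth.effect_pairs`` are shifted by
    ``effect_size * edge_sd``.  Age (normal, per-group mean) and sex
    (Bernoulli, per-group proportion) are drawn, optionally coupled into
    every feature via ``truth.confound_coupling`` slopes (units: feature
    change per year of age / per sex unit).

    Returns (features, groups, phenotype) with groups 0 = control,
    1 = patient, and a phenotype table (subject_id, group, age, sex, score).
    """
    if n_controls <= 0 or n_patients <= 0:
        raise ValueError("group sizes must be positive")
    if truth.effect_size > 0 and not truth.effect_pairs:
        raise ValueError("nonzero effect_size requires non-empty effect_pairs")
    rng = np.random.default_rng(seed)
    p = partition.n_rois
    d = p * (p - 1) // 2
    n = n_controls + n_patients
    groups = np.r_[np.zeros(n_controls, dtype=int), np.ones(n_patients, dtype=int)]

    pair_edges = partition.pair_edge_indices()
    valid = set(partition.network_pairs())
    eff_idx = []
    for pr in truth.effect_pairs:
        pr = tuple(pr)
        if pr not in valid:
            raise ValueError(f"{pr} is not a valid network pair")
        eff_idx.append(pair_edges[pr])
    eff_idx = np.unique(np.concatenate(eff_idx)) if eff_idx else np.array([], dtype=int)

    X = rng.normal(0.0, edge_sd, size=(n, d))
    if eff_idx.size:
        X[np.ix_(groups == 1, eff_idx)] += truth.effect_size * edge_sd

    age = np.where(
        groups == 0,
        rng.normal(age_means[0], age_sd, size=n),
        rng.normal(age_means[1], age_sd, size=n),
    ).clip(18, 80)
    sex = (rng.random(n) < np.where(groups == 0, sex_p[0], sex_p[1])).astype(int)
    score = rng.normal(np.where(groups == 0, score_means[0], score_means[1]), score_sd).clip(0)

    a_slope = float(truth.confound_coupling.get("age", 0.0))
    s_slope = float(truth.confound_coupling.get("sex", 0.0))
    if a_slope or s_slope:
        X = X + np.outer(a_slope * (age - age.mean()) + s_slope * (sex - sex.mean()), np.ones(d))

    phenotype = pd.DataFrame(
        {
            "subject_id": [f"c{i + 1:03d}" for i in range(n)],
            "group": np.where(groups == 0, "control", "patient"),
            "age": np.round(age, 1),
            "sex": sex,
            "score": np.round(score, 1),
        }
    )
    return X, groups, phenotype
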