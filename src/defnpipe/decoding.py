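"""Emotion decoding from state-averaged connectivity and DEFN weights.

For K states there are 2^K - 1 state combinations; each defines a decoding
model whose feature vector is the concatenation, in ascending state order,
of the vectorized upper triangles of an episode's state-averaged FC
matrices.  Decoding is leave-one-subject-out: per fold the features are
standardized on the training episodes, ranked by ReliefF, the top
``n_selected`` retained, and a linear SVM fit.  Stable features are the
intersection of the per-fold selections; mapped back to ROI pairs and
pooled across state blocks (union of edge identities), they yield the
per-network-pair DEFN weights: the fraction of each pair's edges that are
stable discriminative features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .partition import NetworkPartition
from .states import StateModel, episode_state_fc
from .stats import fdr_bh, lilliefors, paired_t, wilcoxon_signed_rank
from .dfc import DynFCSeries, vectorize_upper

__all__ = [
    "DecoderConfig",
    "DecodingResult",
    "DefnWeights",
    "enumerate_combos",
    "compute_cohort_state_fc",
    "build_combo_samples",
    "relieff_scores",
    "loso_decode",
    "select_optimal_model",
    "stable_features",
    "defn_weights",
    "compare_models",
]


@dataclass(frozen=True)
class DecoderConfig:
    svm_cost: float = 1.0
    relief_neighbors: int = 10
    n_selected: int = 1000
    standardize: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.svm_cost <= 0 or self.relief_neighbors <= 0 or self.n_selected <= 0:
            raise ValueError("svm_cost, relief_neighbors and n_selected must be positive")


@dataclass
class DecodingResult:
    combo: tuple
    fold_accuracies: np.ndarray
    fold_subjects: list
    selected_sets: list  # per-fold frozenset of feature indices
    n_excluded_episodes: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1)) if self.fold_accuracies.size > 1 else 0.0


@dataclass
class DefnWeights:
    """Per-network-pair weight in [0, 1]: stable-edge count / pair edge count."""

    weights: dict  # (netA, netB) -> float
    stable_counts: dict
    pair_edge_counts: dict
    combo: tuple = ()

    def as_matrix(self, partition: NetworkPartition) -> np.ndarray:
        n = partition.n_networks
        m = np.zeros((n, n))
        for (a, b), w in self.weights.items():
            i = partition.network_labels.index(a)
            j = partition.network_labels.index(b)
            m[i, j] = m[j, i] = w
        return m


def enumerate_combos(K: int):
    """All non-empty subsets of {1..K}, ordered by size then lexicographically."""
    if K < 1:
        raise ValueError("K must be >= 1")
    out = []
    for size in range(1, K + 1):
        out.extend(tuple(c) for c in itertools.combinations(range(1, K + 1), size))
    return out


def compute_cohort_state_fc(episodes, model: StateModel):
    """Per-episode state-averaged FC vectors for a whole cohort.

    Parameters
    ----------
    episodes : sequence of DynFCSeries
        All episodes, each carrying subject/episode/condition metadata.
    model : StateModel
        Fitted state model with assignments covering every episode.

    Returns
    -------
    list of dict with keys subject_id, episode_id, condition, state_fc
    (state -> upper-triangle vector or None when the state is absent).
    """
    records = []
    for ep in episodes:
        labels = model.episode_labels(ep.subject_id, ep.episode_id)
        if labels.size != ep.n_windows:
            raise ValueError(f"missing assignments for episode {ep.subject_id}/{ep.episode_id}")
        state_fc = {}
        for s in range(1, model.K + 1):
            m = episode_state_fc(ep, labels, s)
            state_fc[s] = None if m is None else vectorize_upper(m)
        records.append(
            {
                "subject_id": ep.subject_id,
                "episode_id": ep.episode_id,
                "condition": ep.condition,
                "state_fc": state_fc,
            }
        )
    return records


def build_combo_samples(cohort, combo):
    """Assemble the decoding design matrix for one state combination.

    One sample per episode; features are the concatenated state-average
    upper-triangle vectors in ascending state order.  Episodes missing any
    state in the combo are excluded (and counted), mirroring the
    both-conditions inclusion rule of the contrast analysis.

    Returns (X, conditions, subject_ids, n_excluded).
    """
    combo = tuple(sorted(combo))
    if not combo:
        raise ValueError("combo must be non-empty")
    X, y, groups = [], [], []
    n_excluded = 0
    for rec in cohort:
        vecs = [rec["state_fc"].get(s) for s in combo]
        if any(v is None for v in vecs):
            n_excluded += 1
            continue
        X.append(np.concatenate(vecs))
        y.append(rec["condition"])
        groups.append(rec["subject_id"])
    if not X:
        raise ValueError(f"no episode retains all states in combo {combo}")
    return np.vstack(X), np.asarray(y), np.asarray(groups), n_excluded


def relieff_scores(X, y, n_neighbors: int = 10) -> np.ndarray:
    """ReliefF relevance scores for binary labels.

    For each sample, the k nearest same-class hits and k nearest
    other-class misses (L1 distance) contribute per-feature mean absolute
    differences; the score is (miss diff - hit diff) averaged over samples,
    so features separating the classes score high.  Meant to run on
    standardized features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("relieff_scores requires exactly two classes")
    n, d = X.shape
    D = cdist(X, X, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    W = np.zeros(d)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        other = np.flatnonzero(y != y[i])
        same = same[same != i]
        k_hit = min(n_neighbors, same.size)
        k_miss = min(n_neighbors, other.size)
        if k_hit == 0 or k_miss == 0:
            raise ValueError("each class needs at least 2 samples")
        hits = same[np.argsort(D[i, same], kind="stable")[:k_hit]]
        misses = other[np.argsort(D[i, other], kind="stable")[:k_miss]]
        W += np.abs(X[misses] - X[i]).mean(axis=0) - np.abs(X[hits] - X[i]).mean(axis=0)
    return W / n


def loso_decode(X, y, subject_ids, config: DecoderConfig | None = None, combo=()) -> DecodingResult:
    """Leave-one-subject-out relief + linear-SVM decoding.

    Per fold all episodes of one subject are held out; standardization
    statistics, ReliefF ranking and the SVM are computed on the training
    episodes only.  Fold accuracy is the fraction of the held-out subject's
    episodes classified correctly.
    """
    config = config or DecoderConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subject_ids = np.asarray(subject_ids)
    subjects = sorted(set(subject_ids.tolist()))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    accs, sel_sets = [], []
    for subj in subjects:
        test = subject_ids == subj
        train = ~test
        y_tr = y[train]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"training split lost a class when holding out {subj}")
        X_tr, X_te = X[train], X[test]
        if config.standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr = scaler.transform(X_tr)
            X_te = scaler.transform(X_te)
        scores = relieff_scores(X_tr, y_tr, config.relief_neighbors)
        k = min(config.n_selected, X.shape[1])
        sel = np.sort(np.argsort(-scores, kind="stable")[:k])
        clf = SVC(kernel="linear", C=config.svm_cost)
        clf.fit(X_tr[:, sel], y_tr)
        accs.append(float(np.mean(clf.predict(X_te[:, sel]) == y[test])))
        sel_sets.append(frozenset(int(i) for i in sel))
    return DecodingResult(tuple(combo), np.asarray(accs), subjects, sel_sets)


def select_optimal_model(results: dict, accuracy_tolerance: float = 0.5):
    """Pick the optimal state combination from per-combo accuracies.

    Among combos whose mean accuracy lies within ``accuracy_tolerance``
    percentage points of the maximum, return the one with the smallest SD
    (deterministic tie-break by combo order).  Accuracies may be on the 0-1
    or the percent scale; the tolerance is interpreted in percentage points
    either way.
    """
    if not results:
        raise ValueError("empty results")
    combos = list(results)
    means = np.array([results[c].mean_accuracy for c in combos])
    sds = np.array([results[c].sd_accuracy for c in combos])
    tol = accuracy_tolerance / 100.0 if means.max() <= 1.0 else accuracy_tolerance
    near = means >= means.max() - tol
    cand = np.flatnonzero(near)
    best = cand[np.argmin(sds[cand], )]
    return combos[int(best)]


def stable_features(selected_sets):
    """Intersection of the per-fold selected feature sets."""
    sets = list(selected_sets)
    if not sets:
        raise ValueError("need at least one fold")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return frozenset(out)


def defn_weights(stable, combo, partition: NetworkPartition) -> DefnWeights:
    """DEFN network-pair weights from stable decoding features.

    Stable indices live in the concatenated feature space of ``combo``
    (state blocks of length p(p-1)/2 each, ascending state order).  Each is
    mapped back to its state block and ROI-pair edge; ROI-pair identities
    are pooled across blocks (a union, deduplicated), and the weight of a
    network pair is the fraction of its edges present in that union.
    """
    combo = tuple(sorted(combo))
    p = partition.n_rois
    n_edges = p * (p - 1) // 2
    total = n_edges * len(combo)
    union_edges = set()
    for idx in stable:
        if not 0 <= idx < total:
            raise IndexError(f"feature index {idx} out of range for combo {combo}")
        union_edges.add(idx % n_edges)
    codes = partition.edge_net_pair_codes()
    pairs = partition.network_pairs()
    counts = partition.pair_edge_counts()
    stable_counts = {pair: 0 for pair in pairs}
    for e in union_edges:
        stable_counts[pairs[codes[e]]] += 1
    weights = {
        pair: (stable_counts[pair] / counts[pair]) if counts[pair] else 0.0 for pair in pairs
    }
    return DefnWeights(weights, stable_counts, counts, combo)


def compare_models(fold_accuracies: dict, reference, alpha: float = 0.05, seed=0):
    """Paired comparison of each combo against the reference combo.

    Per non-reference combo the paired fold-accuracy differences are tested
    for normality (Lilliefors at ``alpha``); normal differences get a paired
    t test, non-normal a Wilcoxon signed-rank.  P-values are BH-adjusted
    across combos.  All-zero differences report p = 1.
    """
    ref = np.asarray(fold_accuracies[reference], dtype=float)
    combos = [c for c in fold_accuracies if c != reference]
    raw, methods = [], []
    for c in combos:
        other = np.asarray(fold_accuracies[c], dtype=float)
        if other.size != ref.size:
            raise ValueError("fold counts must match (paired by subject)")
        d = ref - other
        if np.all(d == 0):
            raw.append(1.0)
            methods.append("degenerate")
            continue
        try:
            normal = lilliefors(d, seed=seed).p >= alpha
        except ValueError:  # zero-variance nonzero differences
            normal = True
        if normal:
            res = paired_t(d)
        else:
            try:
                res = wilcoxon_signed_rank(d)
            except ValueError:
                res = paired_t(d)
        raw.append(res.p)
        methods.append(res.method)
    q = fdr_bh(raw)
    return {c: {"p_raw": float(pr), "p_adj": float(qa), "method": m}
            for c, pr, qa, m in zip(combos, raw, q, methods)}
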