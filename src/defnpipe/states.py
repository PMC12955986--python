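"""Brain-state estimation from windowed FC vectors.

Recurring connectivity states are found by k-means with the L1 (cityblock)
metric: windows are assigned to the nearest centroid in L1 distance and
centroids are updated as coordinate-wise medians, which is the minimizer of
total L1 distance.  The clustering runs in two steps: many random starts
keep the best-inertia centroids, then a single long refinement re-clusters
all windows from those centroids.  The cluster count is chosen by the elbow
method, operationalized as the maximum discrete second difference of the
inertia curve.

Occupancy summaries (state frequencies, dwell times, transition matrices),
per-episode state-averaged FC, and paired happy-vs-sad edge contrasts with
Benjamini-Hochberg FDR live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .dfc import DynFCSeries, unvectorize_upper
from .partition import NetworkPartition
from .stats import fdr_bh

__all__ = [
    "L1KMedians",
    "StateModel",
    "cluster_states_two_step",
    "elbow_select_k",
    "state_frequencies",
    "dwell_time",
    "transition_matrix",
    "episode_state_fc",
    "EdgeContrast",
    "state_condition_contrast",
    "network_mean_t",
]

logger = logging.getLogger(__name__)


class L1KMedians(BaseEstimator, ClusterMixin):
    """K-means with L1 distance and coordinate-wise-median centroid update.

    Parameters
    ----------
    n_clusters : int
        Number of states K.
    n_init : int, default 100
        Number of random centroid initializations; the best-inertia run wins.
    max_iter : int, default 1000
        Maximum Lloyd iterations per run.
    tol : float, default 0.0
        Stop when total inertia improves by less than this between iterations.
    random_state : int or None
        Seed for the initializations.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (K, d)
    labels_ : ndarray of shape (N,)
    inertia_ : float
        Total L1 distance of every sample to its assigned centroid.
    n_iter_ : int
    """

    def __init__(self, n_clusters=4, n_init=100, max_iter=1000, tol=0.0, random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # Lloyd iterations for one start; returns (centers, labels, inertia, iters)
    def _run(self, X, centers):
        prev = np.inf
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d = cdist(X, centers, metric="cityblock")
            labels = d.argmin(axis=1)
            inertia = d[np.arange(X.shape[0]), labels].sum()
            new = centers.copy()
            for k in range(self.n_clusters):
                members = X[labels == k]
                if members.shape[0] == 0:
                    # empty-cluster repair: reseed at the point farthest from
                    # its currently assigned centroid (deterministic)
                    far = d[np.arange(X.shape[0]), labels].argmax()
                    new[k] = X[far]
                    logger.info("empty cluster %d reseeded at farthest point %d", k, far)
                else:
                    new[k] = np.median(members, axis=0)
            if np.array_equal(new, centers):
                break
            if self.tol > 0 and prev - inertia <= self.tol:
                centers = new
                break
            prev = inertia
            centers = new
        d = cdist(X, centers, metric="cityblock")
        labels = d.argmin(axis=1)
        inertia = d[np.arange(X.shape[0]), labels].sum()
        return centers, labels, float(inertia), n_iter

    def fit(self, X, y=None, init_centers=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_windows, n_edges)")
        N = X.shape[0]
        if N <= self.n_clusters:
            raise ValueError("need more samples than clusters")
        rng = np.random.default_rng(self.random_state)
        best = None
        if init_centers is not None:
            starts = [np.asarray(init_centers, dtype=float)]
        else:
            starts = [
                X[rng.choice(N, size=self.n_clusters, replace=False)].copy()
                for _ in range(self.n_init)
            ]
        for centers0 in starts:
            centers, labels, inertia, n_iter = self._run(X, centers0)
            if best is None or inertia < best[2]:
                best = (centers, labels, inertia, n_iter)
        self.cluster_centers_, self.labels_, self.inertia_, self.n_iter_ = best
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        d = cdist(np.asarray(X, dtype=float), self.cluster_centers_, metric="cityblock")
        return d.argmin(axis=1)

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_


@dataclass
class StateModel:
    """Fitted state clustering: centroids, window assignments, inertia.

    ``assignments`` maps (subject_id, episode_id, window index) to a state
    in 1..K; ``labels`` is the flat 1-based state vector in input row order.
    """

    K: int
    centroids: np.ndarray
    labels: np.ndarray  # 1-based states, flat over all input windows
    inertia: float
    assignments: dict = field(default_factory=dict)

    def episode_labels(self, subject_id, episode_id) -> np.ndarray:
        keys = sorted(
            (k for k in self.assignments if k[0] == subject_id and k[1] == episode_id),
            key=lambda k: k[2],
        )
        return np.array([self.assignments[k] for k in keys], dtype=int)


def cluster_states_two_step(
    window_vectors: np.ndarray,
    K: int,
    n_init: int = 100,
    max_iter: int = 1000,
    seed=None,
    keys=None,
) -> StateModel:
    """Two-step L1 k-means over concatenated window vectors.

    Step 1 draws ``n_init`` random centroid initializations and keeps the
    best-inertia centroids; step 2 re-clusters all windows starting from
    those centroids for up to ``max_iter`` iterations.  ``keys`` optionally
    supplies one (subject, episode, window) tuple per row for bookkeeping.
    """
    X = np.asarray(window_vectors, dtype=float)
    step1 = L1KMedians(
        n_clusters=K, n_init=n_init, max_iter=max(20, max_iter // 10), random_state=seed
    ).fit(X)
    step2 = L1KMedians(n_clusters=K, n_init=1, max_iter=max_iter, random_state=seed)
    step2.fit(X, init_centers=step1.cluster_centers_)
    if step2.inertia_ > step1.inertia_:  # refinement must never hurt
        step2 = step1
    labels = step2.labels_ + 1
    assignments = {}
    if keys is not None:
        if len(keys) != X.shape[0]:
            raise ValueError("keys must have one entry per window row")
        assignments = {tuple(k): int(s) for k, s in zip(keys, labels)}
    return StateModel(K, step2.cluster_centers_, labels, step2.inertia_, assignments)


def elbow_select_k(window_vectors, k_range, seed=None, n_init=10, max_iter=300):
    """Pick K by the elbow of the L1 inertia curve.

    Fits the clustering at each k in ``k_range`` and returns the interior k
    maximizing the discrete second difference J(k-1) - 2 J(k) + J(k+1),
    i.e. the sharpest drop in the rate of improvement.
    """
    k_range = list(k_range)
    if len(k_range) < 3:
        raise ValueError("k_range must contain at least 3 values")
    if sorted(k_range) != k_range:
        raise ValueError("k_range must be sorted ascending")
    X = np.asarray(window_vectors, dtype=float)
    inertias = []
    for k in k_range:
        if k == 1:
            med = np.median(X, axis=0)
            inertias.append(float(np.abs(X - med).sum()))
        else:
            m = L1KMedians(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed)
            inertias.append(m.fit(X).inertia_)
    return elbow_from_inertia(k_range, inertias)


def elbow_from_inertia(k_range, inertias) -> int:
    """Interior k maximizing J(k-1) - 2 J(k) + J(k+1)."""
    J = np.asarray(inertias, dtype=float)
    if J.size < 3:
        raise ValueError("need at least 3 inertia values")
    second = J[:-2] - 2 * J[1:-1] + J[2:]
    return int(k_range[1 + int(np.argmax(second))])


def state_frequencies(model: StateModel) -> np.ndarray:
    """Proportion of all windows assigned to each state (sums to 1)."""
    counts = np.bincount(model.labels - 1, minlength=model.K)
    return counts / counts.sum()


def dwell_time(labels) -> dict:
    """Mean consecutive run length (in windows) per state for one episode."""
    labels = np.asarray(labels, dtype=int)
    if labels.size < 1:
        raise ValueError("empty assignment sequence")
    runs = {}
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            runs.setdefault(int(labels[start]), []).append(i - start)
            start = i
    return {s: float(np.mean(r)) for s, r in runs.items()}


def transition_matrix(labels, K: int):
    """Row-stochastic K x K empirical transition matrix for one episode.

    States with no outgoing transitions get a uniform row and are flagged.
    Returns (matrix, flagged_states).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size < 2:
        raise ValueError("need at least 2 windows to estimate transitions")
    counts = np.zeros((K, K))
    for a, b in zip(labels[:-1], labels[1:]):
        counts[a - 1, b - 1] += 1
    rows = counts.sum(axis=1)
    flagged = [int(s + 1) for s in np.flatnonzero(rows == 0)]
    T = np.empty_like(counts)
    for i in range(K):
        T[i] = counts[i] / rows[i] if rows[i] > 0 else 1.0 / K
    return T, flagged


def episode_state_fc(series: DynFCSeries, labels, state: int):
    """Mean FC matrix of one episode's windows assigned to ``state``.

    Returns None (absent) when the episode never visits the state — absence
    is explicit, never silently zero.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != series.n_windows:
        raise ValueError("labels length must match window count")
    mask = labels == state
    if not mask.any():
        return None
    return series.windows[mask].mean(axis=0)


@dataclass
class EdgeContrast:
    """Edge-wise paired condition contrast for one state.

    Per upper-triangle edge: paired t statistic (condition A minus B, here
    happy minus sad), raw p, BH-adjusted q, and the sign of significant
    edges at the given alpha.  ``n_included`` counts subjects exhibiting the
    state under both conditions.
    """

    state: int
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    alpha: float
    n_included: int

    @property
    def significant(self) -> np.ndarray:
        return self.q < self.alpha

    @property
    def sign(self) -> np.ndarray:
        return np.where(self.significant, np.sign(self.t), 0.0)


def state_condition_contrast(subject_cond_fc: dict, state: int, alpha: float = 0.05) -> EdgeContrast:
    """Paired happy-vs-sad edge contrast for one state.

    Parameters
    ----------
    subject_cond_fc : dict
        Maps subject_id -> {condition: edge vector or None}; per subject the
        vectors are that subject's condition-wise mean state-FC (upper
        triangle).  Exactly two conditions are expected; the contrast sign is
        first-listed condition minus second (happy - sad by convention).
        Subjects lacking the state in either condition are excluded.
    """
    diffs = []
    for sid in sorted(subject_cond_fc):
        conds = subject_cond_fc[sid]
        if len(conds) != 2:
            raise ValueError("exactly two conditions required per subject")
        (_, a), (_, b) = sorted(conds.items())
        if a is None or b is None:
            continue
        diffs.append(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    if len(diffs) < 3:
        raise ValueError(
            f"only {len(diffs)} subjects exhibit state {state} in both conditions (need >= 3)"
        )
    D = np.vstack(diffs)
    n = D.shape[0]
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, 0.0, t)
    p = 2 * sps.t.sf(np.abs(t), df=n - 1)
    p = np.where(sd == 0, 1.0, p)
    return EdgeContrast(state, t, p, fdr_bh(p), alpha, n)


def state_condition_contrast_happy_sad(cohort_fc, state, alpha=0.05):
    """Convenience wrapper fixing the (happy, sad) condition order."""
    remapped = {}
    for sid, conds in cohort_fc.items():
        remapped[sid] = {"a_happy": conds.get("happy"), "b_sad": conds.get("sad")}
    return state_condition_contrast(remapped, state, alpha)


def network_mean_t(contrast: EdgeContrast, partition: NetworkPartition):
    """Per network pair, the mean t over edges significant after FDR.

    Pairs with no significant edge are NaN (null-flagged), never 0.
    Returned as an n_networks x n_networks symmetric matrix plus the pair
    dict keyed by label tuples.
    """
    codes = partition.edge_net_pair_codes()
    pairs = partition.network_pairs()
    sig = contrast.significant
    out = {}
    n = partition.n_networks
    mat = np.full((n, n), np.nan)
    for k, pair in enumerate(pairs):
        sel = sig & (codes == k)
        val = float(contrast.t[sel].mean()) if sel.any() else np.nan
        out[pair] = val
        i = partition.network_labels.index(pair[0])
        j = partition.network_labels.index(pair[1])
        mat[i, j] = mat[j, i] = val
    return mat, out
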