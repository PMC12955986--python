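"""Transfer of DEFN weights to patient-vs-control classification.

Network-pair weights learned from the emotion decoder are sorted in
descending order; the top-n pairs define a feature mask over static-FC
edges.  The mask size n is a hyperparameter chosen by nested stratified
10-fold cross-validation: per outer fold, an inner 10-fold CV over the
candidate grid picks the mask with the best inner accuracy, a linear SVM
with that mask is trained on the outer-train and scored on the outer-test,
and the modal mask size across outer folds is reported as final.  A
whole-brain baseline uses the same outer folds (paired predictions for
McNemar).  Age/sex confound regression, when requested, is fit on each
training partition only and applied to its validation/test partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .decoding import DefnWeights
from .dfc import static_fc  # noqa: F401  (re-exported: sFC lives with its consumers too)
from .partition import NetworkPartition
from .stats import mcnemar_compare  # noqa: F401  (re-export)

__all__ = [
    "MaskSpec",
    "ConfoundRegressor",
    "ClassificationReport",
    "static_fc",
    "rank_network_pairs",
    "build_mask",
    "nested_cv_classify",
    "baseline_classify",
    "network_importance",
    "roc_auc",
    "mcnemar_compare",
]


@dataclass(frozen=True)
class MaskSpec:
    """Top-n network-pair feature mask."""

    ranked_pairs: tuple
    n_top: int
    feature_indices: np.ndarray

    def __post_init__(self):
        if not 1 <= self.n_top <= len(self.ranked_pairs):
            raise ValueError("n_top out of range")
        if len(np.unique(self.feature_indices)) != len(self.feature_indices):
            raise ValueError("duplicate feature indices in mask")


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Per-feature OLS removal of age/sex effects, fit on training rows only.

    ``fit`` estimates intercept + slopes per feature; ``transform``
    subtracts the training-derived prediction, so validation/test rows are
    residualized with coefficients they never influenced.  Constant
    covariates are dropped with a warning (rank-deficient design).
    """

    def __init__(self):
        pass

    def fit(self, X, confounds):
        X = np.asarray(X, dtype=float)
        C = self._as_array(confounds)
        if X.shape[0] < 3:
            raise ValueError("need >= 3 training rows")
        keep = []
        for j in range(C.shape[1]):
            if np.ptp(C[:, j]) == 0:
                warnings.warn(f"constant confound column {j} dropped", RuntimeWarning)
            else:
                keep.append(j)
        self.columns_ = np.asarray(keep, dtype=int)
        design = np.column_stack([np.ones(X.shape[0]), C[:, self.columns_]])
        self.coef_, *_ = np.linalg.lstsq(design, X, rcond=None)
        return self

    def transform(self, X, confounds):
        X = np.asarray(X, dtype=float)
        C = self._as_array(confounds)
        design = np.column_stack([np.ones(X.shape[0]), C[:, self.columns_]])
        return X - design @ self.coef_

    @staticmethod
    def _as_array(confounds):
        if isinstance(confounds, pd.DataFrame):
            return confounds.to_numpy(dtype=float)
        C = np.asarray(confounds, dtype=float)
        return C[:, None] if C.ndim == 1 else C


@dataclass
class ClassificationReport:
    """Pooled nested-CV (or plain-CV) classification outcome."""

    fold_accuracies: np.ndarray
    predictions: np.ndarray  # aligned to input row order
    decision_scores: np.ndarray
    accuracy: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    selected_n_top: list = field(default_factory=list)
    final_n_top: int | None = None
    final_mask: MaskSpec | None = None
    importance: dict = field(default_factory=dict)
    leakage_free: bool = True
    meta: dict = field(default_factory=dict)


def rank_network_pairs(weights: DefnWeights):
    """Network pairs sorted by descending weight, ties and zeros by
    lexicographic pair order (zero-weight pairs stay at the tail)."""
    items = sorted(weights.weights.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(pair for pair, _ in items)


def build_mask(ranked, n_top: int, partition: NetworkPartition) -> MaskSpec:
    """Union of the edge sets of the first ``n_top`` ranked network pairs."""
    ranked = tuple(tuple(pr) for pr in ranked)
    if not 1 <= n_top <= len(ranked):
        raise ValueError(f"n_top={n_top} out of range 1..{len(ranked)}")
    pair_edges = partition.pair_edge_indices()
    idx = np.unique(np.concatenate([pair_edges[pr] for pr in ranked[:n_top]]))
    return MaskSpec(ranked, n_top, idx)


def _fit_predict(X_tr, y_tr, X_te, C):
    clf = SVC(kernel="linear", C=C)
    clf.fit(X_tr, y_tr)
    return clf, clf.predict(X_te), clf.decision_function(X_te)


def nested_cv_classify(
    features,
    labels,
    weights: DefnWeights,
    partition: NetworkPartition,
    outer_folds: int = 10,
    inner_folds: int = 10,
    confounds=None,
    grid=None,
    svm_cost: float = 1.0,
    seed: int = 0,
) -> ClassificationReport:
    """DEFN-masked nested stratified CV classification.

    ``grid`` defaults to n_top in 1..(number of pairs with nonzero weight),
    or all pairs when every weight is zero.  When ``confounds`` (n x 2
    age/sex array or DataFrame) is given, a :class:`ConfoundRegressor` is
    fit inside every training partition — inner-train for inner loops,
    outer-train for the outer model — and applied to the corresponding
    validation/test rows before masking.

    The report's ``leakage_free`` flag is the result of an instrumented
    assertion that no outer-test row index entered any inner-loop
    computation.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes")
    if X.shape[0] < 20:
        raise ValueError("need at least 20 subjects")
    conf = None if confounds is None else ConfoundRegressor._as_array(confounds)

    ranked = rank_network_pairs(weights)
    n_nonzero = sum(1 for pr in ranked if weights.weights[pr] > 0)
    if grid is None:
        grid = list(range(1, (n_nonzero or len(ranked)) + 1))
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise ValueError("empty candidate grid")
    masks = {n: build_mask(ranked, n, partition) for n in grid}

    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    preds = np.empty(X.shape[0], dtype=y.dtype)
    scores = np.empty(X.shape[0], dtype=float)
    fold_accs, chosen, fold_coefs, fold_masks = [], [], [], []
    leakage_free = True

    for tr_idx, te_idx in outer.split(X, y):
        inner_touched = set()
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed + 1)
        inner_acc = {}
        for itr, ival in inner.split(X[tr_idx], y[tr_idx]):
            itr_idx, ival_idx = tr_idx[itr], tr_idx[ival]
            inner_touched.update(itr_idx.tolist())
            inner_touched.update(ival_idx.tolist())
            Xi_tr, Xi_val = X[itr_idx], X[ival_idx]
            if np.unique(y[itr_idx]).size < 2:
                raise ValueError("inner split lost a class")
            if conf is not None:
                cr = ConfoundRegressor().fit(Xi_tr, conf[itr_idx])
                Xi_tr = cr.transform(Xi_tr, conf[itr_idx])
                Xi_val = cr.transform(Xi_val, conf[ival_idx])
            for n in grid:
                sel = masks[n].feature_indices
                _, pv, _ = _fit_predict(Xi_tr[:, sel], y[itr_idx], Xi_val[:, sel], svm_cost)
                inner_acc.setdefault(n, []).append(float(np.mean(pv == y[ival_idx])))
        # instrumented leakage check: inner loops saw only outer-train rows
        if inner_touched & set(te_idx.tolist()):
            leakage_free = False
        mean_acc = {n: float(np.mean(a)) for n, a in inner_acc.items()}
        best_n = max(grid, key=lambda n: (mean_acc[n], -n))  # tie -> smaller n
        chosen.append(best_n)

        X_tr, X_te = X[tr_idx], X[te_idx]
        if conf is not None:
            cr = ConfoundRegressor().fit(X_tr, conf[tr_idx])
            X_tr = cr.transform(X_tr, conf[tr_idx])
            X_te = cr.transform(X_te, conf[te_idx])
        sel = masks[best_n].feature_indices
        clf, pv, sc = _fit_predict(X_tr[:, sel], y[tr_idx], X_te[:, sel], svm_cost)
        preds[te_idx] = pv
        scores[te_idx] = sc
        fold_accs.append(float(np.mean(pv == y[te_idx])))
        fold_coefs.append(np.abs(np.ravel(clf.coef_)))
        fold_masks.append(sel)

    vals, counts = np.unique(chosen, return_counts=True)
    final_n = int(vals[counts == counts.max()].min())  # modal, smaller on tie
    fpr, tpr, auc = roc_auc(scores, y)
    acc = float(np.mean(preds == y))
    report = ClassificationReport(
        np.asarray(fold_accs), preds, scores, acc, fpr, tpr, auc,
        selected_n_top=chosen, final_n_top=final_n,
        final_mask=masks.get(final_n), leakage_free=leakage_free,
        meta={"grid": grid, "sex_coding": "0=female baseline, 1=male (as supplied)"},
    )
    report.importance = network_importance(fold_coefs, fold_masks, partition)
    return report


def baseline_classify(
    features, labels, folds: int = 10, confounds=None, svm_cost: float = 1.0, seed: int = 0
) -> ClassificationReport:
    """Whole-brain stratified-CV baseline with the same fold assignments as
    :func:`nested_cv_classify` for matching ``seed`` (paired for McNemar)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes")
    conf = None if confounds is None else ConfoundRegressor._as_array(confounds)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty(X.shape[0], dtype=y.dtype)
    scores = np.empty(X.shape[0], dtype=float)
    fold_accs = []
    for tr_idx, te_idx in cv.split(X, y):
        X_tr, X_te = X[tr_idx], X[te_idx]
        if conf is not None:
            cr = ConfoundRegressor().fit(X_tr, conf[tr_idx])
            X_tr = cr.transform(X_tr, conf[tr_idx])
            X_te = cr.transform(X_te, conf[te_idx])
        _, pv, sc = _fit_predict(X_tr, y[tr_idx], X_te, svm_cost)
        preds[te_idx] = pv
        scores[te_idx] = sc
        fold_accs.append(float(np.mean(pv == y[te_idx])))
    fpr, tpr, auc = roc_auc(scores, y)
    return ClassificationReport(
        np.asarray(fold_accs), preds, scores, float(np.mean(preds == y)), fpr, tpr, auc
    )


def network_importance(fold_coefs, fold_masks, partition: NetworkPartition) -> dict:
    """Mean absolute SVM coefficient per network pair, averaged across outer
    folds and max-normalized to [0, 1]; never-masked pairs are NaN."""
    codes = partition.edge_net_pair_codes()
    pairs = partition.network_pairs()
    sums = {pr: [] for pr in pairs}
    for coefs, mask in zip(fold_coefs, fold_masks):
        mask_codes = codes[mask]
        for k, pr in enumerate(pairs):
            sel = mask_codes == k
            if sel.any():
                sums[pr].append(float(np.abs(coefs[sel]).mean()))
    imp = {pr: (float(np.mean(v)) if v else np.nan) for pr, v in sums.items()}
    finite = [v for v in imp.values() if np.isfinite(v)]
    top = max(finite) if finite else 0.0
    if top > 0:
        imp = {pr: (v / top if np.isfinite(v) else v) for pr, v in imp.items()}
    return imp


def roc_auc(scores, labels):
    """ROC points and AUC (probability a random positive outscores a random
    negative, ties counted half) from pooled decision scores."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need both classes present")
    y01 = (y == classes[1]).astype(int)
    fpr, tpr, _ = roc_curve(y01, scores)
    return fpr, tpr, float(roc_auc_score(y01, scores))
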