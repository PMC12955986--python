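"""Sliding-window dynamic functional connectivity.

Windows are 0-based half-open intervals ``[start, start + window_length)``
advanced by a fixed step, giving ``floor((T - w) / s) + 1`` windows for a
series of T time points.  Each window yields a Pearson correlation matrix
across ROIs, optionally Fisher-Z transformed (``arctanh`` with |r| clipped
at ``1 - 1e-7`` so degenerate, perfectly correlated windows stay finite).
The diagonal is stored as 0 on the Z scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DfcConfig",
    "DynFCSeries",
    "sliding_window_fc",
    "fisher_z",
    "vectorize_upper",
    "unvectorize_upper",
    "n_windows",
    "static_fc",
]

_R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class DfcConfig:
    window_length: int = 30
    step: int = 2
    fisher_z: bool = True

    def __post_init__(self):
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class DynFCSeries:
    """Per-episode sequence of windowed FC matrices (Fisher-Z scale)."""

    windows: np.ndarray  # (n_windows, p, p)
    window_start_indices: np.ndarray
    subject_id: str = ""
    episode_id: str = ""
    condition: str = ""
    config: DfcConfig = field(default_factory=DfcConfig)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_rois(self) -> int:
        return self.windows.shape[1]

    def vectors(self) -> np.ndarray:
        """(n_windows, p(p-1)/2) matrix of upper-triangle window vectors."""
        iu, ju = np.triu_indices(self.n_rois, k=1)
        return self.windows[:, iu, ju]


def n_windows(T: int, window_length: int, step: int) -> int:
    """Number of sliding windows: floor((T - w) / s) + 1, requiring T >= w."""
    if T < window_length:
        raise ValueError(f"series length {T} shorter than window {window_length}")
    return (T - window_length) // step + 1


def fisher_z(r):
    """Variance-stabilizing arctanh transform of a correlation.

    |r| is clipped to 1 - 1e-7 first so boundary correlations map to a
    large finite Z rather than infinity.
    """
    r = np.clip(np.asarray(r, dtype=float), -_R_CLIP, _R_CLIP)
    return np.arctanh(r)


def _corr(block: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns; zero-variance columns give NaN edges."""
    sd = block.std(axis=0, ddof=1)
    bad = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(block, rowvar=False)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance ROI(s) in window; "
            "their edges are NaN and must be rejected downstream",
            RuntimeWarning,
            stacklevel=3,
        )
        c[bad, :] = np.nan
        c[:, bad] = np.nan
    np.fill_diagonal(c, 1.0)
    return c


def sliding_window_fc(ts: np.ndarray, config: DfcConfig | None = None, **meta) -> DynFCSeries:
    """Windowed Pearson-correlation FC of a T x p ROI time-series matrix.

    Returns a :class:`DynFCSeries` whose matrices are on the Fisher-Z scale
    when ``config.fisher_z`` is enabled (the default), with zero diagonal.
    """
    config = config or DfcConfig()
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a T x p matrix")
    if not np.isfinite(ts).all():
        raise ValueError("time series contains non-finite values")
    T, p = ts.shape
    nw = n_windows(T, config.window_length, config.step)
    starts = np.arange(nw) * config.step
    mats = np.empty((nw, p, p))
    for k, s in enumerate(starts):
        c = _corr(ts[s : s + config.window_length])
        if config.fisher_z:
            with np.errstate(invalid="ignore"):
                c = fisher_z(c)
        np.fill_diagonal(c, 0.0)
        mats[k] = c
    return DynFCSeries(mats, starts, config=config, **meta)


def static_fc(ts: np.ndarray) -> np.ndarray:
    """Whole-scan Pearson correlation matrix, Fisher-Z, zero diagonal."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a T x p matrix with T >= 3")
    if not np.isfinite(ts).all():
        raise ValueError("time series contains non-finite values")
    c = _corr(ts)
    z = fisher_z(c)
    np.fill_diagonal(z, 0.0)
    return z


def vectorize_upper(m: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (diagonal excluded) of a square matrix.

    Position ``k`` maps back to ROI pair ``(i, j)`` via
    :func:`numpy.triu_indices`; the same ordering underlies
    :meth:`defnpipe.partition.NetworkPartition.edge_index_map`.
    """
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju]


def unvectorize_upper(v: np.ndarray, p: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: rebuild the symmetric p x p matrix."""
    v = np.asarray(v)
    if v.size != p * (p - 1) // 2:
        raise ValueError("vector length does not match p(p-1)/2")
    m = np.full((p, p), float(diag))
    iu, ju = np.triu_indices(p, k=1)
    m[iu, ju] = v
    m[ju, iu] = v
    return m
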