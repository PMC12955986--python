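"""Statistical kernel used throughout the pipeline.

Pooled two-sample t (from raw data or printed group summaries), Pearson
chi-square without continuity correction, paired t, Wilcoxon signed-rank,
Lilliefors normality, Benjamini-Hochberg FDR, and McNemar's paired
chi-square.  Conventions follow the demographic-table usage: sample SD with
n-1 denominator, Student (pooled-variance) t rather than Welch, chi-square
without the Yates correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "StatResult",
    "t_from_summary",
    "t_two_sample",
    "pearson_chi2",
    "paired_t",
    "wilcoxon_signed_rank",
    "lilliefors",
    "fdr_bh",
    "mcnemar_compare",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed group summary: mean, sample SD (n-1 denominator), n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: float
    p: float
    method: str
    flag: str = ""


def t_from_summary(g1: GroupSummary, g2: GroupSummary) -> StatResult:
    """Pooled two-sample Student t from group summaries (group1 - group2)."""
    if g1.n + g2.n < 4:
        raise ValueError("need n1 + n2 >= 4")
    t, p = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    return StatResult(float(t), float(g1.n + g2.n - 2), float(p), "two-sample t (pooled)")


def t_two_sample(x, y) -> StatResult:
    """Pooled two-sample Student t on raw data; equals ``t_from_summary`` of
    the groups' means/SDs/ns exactly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return StatResult(float(t), float(x.size + y.size - 2), float(p), "two-sample t (pooled)")


def pearson_chi2(table) -> StatResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return StatResult(float(chi2), float(df), float(p), "Pearson chi-square")


def paired_t(d) -> StatResult:
    """One-sample t on paired differences, df = n - 1.

    Zero-variance differences are degenerate: all-zero differences report
    p = 1 ("no evidence of difference"); constant nonzero differences have
    an unbounded statistic and are reported capped with a flag.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise ValueError("need n >= 2 paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return StatResult(0.0, float(d.size - 1), 1.0, "paired t", flag="all-zero")
        stat = np.inf if d.mean() > 0 else -np.inf
        return StatResult(stat, float(d.size - 1), 0.0, "paired t", flag="zero-variance")
    t, p = sps.ttest_1samp(d, 0.0)
    return StatResult(float(t), float(d.size - 1), float(p), "paired t")


def wilcoxon_signed_rank(d) -> StatResult:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; ties get mid-ranks.  The p-value is exact for
    n <= 25 without ties, otherwise a normal approximation with tie
    correction is used.
    """
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all differences are zero")
    if nz.size < 5:
        raise ValueError("need n >= 5 nonzero differences")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=False, method=method)
    return StatResult(
        float(res.statistic), float(nz.size), float(res.pvalue), f"wilcoxon ({method})"
    )


def lilliefors(x, seed: int | None = None) -> StatResult:
    """Lilliefors normality test (KS distance against a normal with
    estimated mean/SD); table p-values with Monte-Carlo fallback for small n."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance input")
    if x.size >= 20:
        stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    else:
        rng_state = np.random.get_state()
        np.random.seed(0 if seed is None else seed % (2**31))
        try:
            stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="approx")
        finally:
            np.random.set_state(rng_state)
    return StatResult(float(stat), float(x.size), float(p), "lilliefors")


def fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def mcnemar_compare(pred_a, pred_b, truth, correction: bool = False):
    """McNemar's paired chi-square on two classifiers' predictions.

    Builds the discordant counts b (a correct, b wrong) and c (a wrong,
    b correct); statistic = (|b - c| - 1)^2/(b + c) with continuity
    correction, else (b - c)^2/(b + c); p from chi-square with 1 df.
    Returns (statistic, p); b + c = 0 reports (0, 1).
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    truth = np.asarray(truth)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("predictions and truth must be aligned, equal length")
    a_ok = pred_a == truth
    b_ok = pred_b == truth
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        return 0.0, 1.0
    diff = abs(b - c) - 1 if correction else b - c
    stat = diff**2 / (b + c)
    return float(stat), float(sps.chi2.sf(stat, df=1))
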