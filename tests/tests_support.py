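"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def wilcoxon_enumeration_oracle(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors.

    Zeros dropped, mid-ranks for ties; two-sided p = 2 * min(P(W <= w),
    P(W >= w)) capped at 1, with W the positive-rank sum.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [np.dot(ranks, bits) for bits in itertools.product([0.0, 1.0], repeat=n)]
    )
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))
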