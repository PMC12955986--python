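"""ROI-to-network partition and edge-index bookkeeping.

A :class:`NetworkPartition` fixes the ROI order (hence the row/column order
of every connectivity matrix) and assigns each ROI to exactly one named
network.  All vectorized feature indexing — upper-triangle edge positions,
network-pair edge blocks — is derived from it, so any feature index can be
mapped back to an (ROI_i, ROI_j) pair and to an unordered network pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NetworkPartition", "gen_network_partition"]


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of ordered ROIs to named networks.

    Parameters
    ----------
    roi_ids : tuple of str
        ROI identifiers in fixed matrix order.
    network_of : dict
        Map from ROI id to its network label.
    network_labels : tuple of str
        Distinct network labels, in fixed order.
    """

    roi_ids: tuple
    network_of: dict
    network_labels: tuple
    _roi_net_idx: np.ndarray = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("duplicate ROI ids")
        if len(set(self.network_labels)) != len(self.network_labels):
            raise ValueError("duplicate network labels")
        missing = [r for r in self.roi_ids if r not in self.network_of]
        if missing:
            raise ValueError(f"ROIs without network assignment: {missing[:5]}")
        used = set(self.network_of[r] for r in self.roi_ids)
        if not used <= set(self.network_labels):
            raise ValueError("network_of uses labels absent from network_labels")
        lab_idx = {l: i for i, l in enumerate(self.network_labels)}
        idx = np.array([lab_idx[self.network_of[r]] for r in self.roi_ids], dtype=np.intp)
        object.__setattr__(self, "_roi_net_idx", idx)

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_networks(self) -> int:
        return len(self.network_labels)

    @property
    def roi_network_index(self) -> np.ndarray:
        """Integer network index per ROI, in ROI order."""
        return self._roi_net_idx

    # ---- edge indexing -------------------------------------------------

    def edge_index_map(self) -> pd.DataFrame:
        """Table mapping upper-triangle vector position -> edge -> network pair.

        Columns: ``index``, ``roi_i``, ``roi_j`` (ROI ids), ``net_i``,
        ``net_j`` (network labels, ordered so net_i <= net_j in label order).
        Row order is the row-major upper triangle excluding the diagonal,
        matching :func:`defnpipe.dfc.vectorize_upper`.
        """
        p = self.n_rois
        iu, ju = np.triu_indices(p, k=1)
        ni = self._roi_net_idx[iu]
        nj = self._roi_net_idx[ju]
        lo = np.minimum(ni, nj)
        hi = np.maximum(ni, nj)
        labels = np.asarray(self.network_labels, dtype=object)
        rois = np.asarray(self.roi_ids, dtype=object)
        return pd.DataFrame(
            {
                "index": np.arange(iu.size),
                "roi_i": rois[iu],
                "roi_j": rois[ju],
                "net_i": labels[lo],
                "net_j": labels[hi],
            }
        )

    def network_pairs(self) -> list:
        """All unordered network pairs (including within-network), in
        lexicographic order of (label-index_i, label-index_j)."""
        n = self.n_networks
        return [
            (self.network_labels[i], self.network_labels[j])
            for i, j in itertools.combinations_with_replacement(range(n), 2)
        ]

    def edge_net_pair_codes(self) -> np.ndarray:
        """Per upper-triangle edge, an integer code identifying its network
        pair (code = position in :meth:`network_pairs`)."""
        p = self.n_rois
        iu, ju = np.triu_indices(p, k=1)
        ni = self._roi_net_idx[iu]
        nj = self._roi_net_idx[ju]
        lo = np.minimum(ni, nj)
        hi = np.maximum(ni, nj)
        n = self.n_networks
        # code of pair (lo, hi), lo<=hi, in combinations_with_replacement order
        return (lo * (2 * n - lo + 1)) // 2 + (hi - lo)

    def pair_edge_indices(self) -> dict:
        """Map network-pair label tuple -> array of upper-triangle edge indices."""
        codes = self.edge_net_pair_codes()
        pairs = self.network_pairs()
        out = {}
        order = np.argsort(codes, kind="stable")
        sorted_codes = codes[order]
        bounds = np.searchsorted(sorted_codes, np.arange(len(pairs) + 1))
        for k, pair in enumerate(pairs):
            out[pair] = np.sort(order[bounds[k] : bounds[k + 1]])
        return out

    def pair_edge_counts(self) -> dict:
        """Map network-pair -> number of ROI-pair edges it spans.

        For a network A with n_A ROIs, (A, A) has n_A(n_A-1)/2 edges and
        (A, B) with A != B has n_A * n_B.
        """
        sizes = np.bincount(self._roi_net_idx, minlength=self.n_networks)
        out = {}
        for pair in self.network_pairs():
            i = self.network_labels.index(pair[0])
            j = self.network_labels.index(pair[1])
            if i == j:
                out[pair] = int(sizes[i] * (sizes[i] - 1) // 2)
            else:
                out[pair] = int(sizes[i] * sizes[j])
        return out


def gen_network_partition(network_sizes, labels) -> NetworkPartition:
    """Build a partition of contiguous ROI blocks, one block per label.

    Parameters
    ----------
    network_sizes : sequence of positive int
        Number of ROIs in each network, in order.
    labels : sequence of str
        Network labels; must match ``network_sizes`` in length and be unique.
    """
    if len(network_sizes) != len(labels):
        raise ValueError("network_sizes and labels must have equal length")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if any(s <= 0 for s in network_sizes):
        raise ValueError("network sizes must be positive")
    roi_ids = []
    network_of = {}
    for size, lab in zip(network_sizes, labels):
        for k in range(size):
            rid = f"{lab}_{k + 1:03d}"
            roi_ids.append(rid)
            network_of[rid] = lab
    return NetworkPartition(tuple(roi_ids), network_of, tuple(labels))
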