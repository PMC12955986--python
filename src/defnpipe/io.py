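"""File formats: tab-separated matrices and tables, JSON manifests.

Everything on disk is diff-able text: ROI time series as TSV with a header
row of ROI ids, atlas label tables and phenotype tables as TSV, manifests
and result bundles as JSON.  Writers are locale-independent (dot decimal
separator, fixed column order) and stamp the package version and the
resolved seed into manifests.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .partition import NetworkPartition

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_partition",
    "write_partition",
    "read_phenotype",
    "write_phenotype",
    "write_manifest",
    "read_manifest",
    "write_matrix",
]

PACKAGE_VERSION = "defnpipe-0.1.0"


def write_timeseries(path, ts: np.ndarray, roi_ids) -> None:
    ts = np.asarray(ts)
    if ts.shape[1] != len(roi_ids):
        raise ValueError("column count does not match roi_ids")
    pd.DataFrame(ts, columns=list(roi_ids)).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_timeseries(path, partition: NetworkPartition | None = None) -> tuple:
    """Read a T x p TSV with an ROI-id header row; returns (matrix, roi_ids).

    Ragged rows and non-numeric cells raise with the offending line number;
    a supplied partition is checked against the header ROI order.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if any(_is_number(h) for h in header):
            raise ValueError(f"{path}: missing header row (first line looks numeric)")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {len(header)})"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    mat = np.asarray(rows, dtype=float)
    if partition is not None and tuple(header) != tuple(partition.roi_ids):
        bad = next(
            (h for h, r in zip(header, partition.roi_ids) if h != r),
            "column count" if len(header) != partition.n_rois else "?",
        )
        raise ValueError(f"{path}: header does not match partition (first mismatch: {bad})")
    return mat, header


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_partition(path, partition: NetworkPartition) -> None:
    pd.DataFrame(
        {"roi_id": partition.roi_ids, "network": [partition.network_of[r] for r in partition.roi_ids]}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path) -> NetworkPartition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("roi_id", "network"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if df["roi_id"].duplicated().any():
        dup = df.loc[df["roi_id"].duplicated(), "roi_id"].iloc[0]
        raise ValueError(f"{path}: duplicate roi_id '{dup}'")
    labels = tuple(dict.fromkeys(df["network"]))
    return NetworkPartition(
        tuple(df["roi_id"]), dict(zip(df["roi_id"], df["network"])), labels
    )


def write_phenotype(path, phenotype: pd.DataFrame) -> None:
    phenotype.to_csv(path, sep="\t", index=False)


def read_phenotype(path, allowed_groups=("control", "patient")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["subject_id", "group", "age", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = set(df["group"].dropna()) - set(allowed_groups)
    if unknown:
        raise ValueError(f"{path}: unknown group labels {sorted(unknown)}")
    bad = df[["age", "sex"]].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"{path}: {int(bad.sum())} row(s) with missing age/sex rejected", RuntimeWarning
        )
        df = df[~bad].reset_index(drop=True)
    return df


def write_manifest(path, records, n_rois: int, atlas_path: str, seed: int) -> None:
    """Manifest: per-episode record list plus dataset-level metadata."""
    payload = {
        "version": PACKAGE_VERSION,
        "seed": int(seed),
        "n_rois": int(n_rois),
        "atlas": str(atlas_path),
        "records": [
            {
                "subject_id": r["subject_id"],
                "episode_id": r["episode_id"],
                "condition": r["condition"],
                "path": str(r["path"]),
            }
            for r in records
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_manifest(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        m = json.load(fh)
    seen = set()
    for rec in m["records"]:
        key = (rec["subject_id"], rec["episode_id"])
        if key in seen:
            raise ValueError(f"{path}: duplicate (subject, episode) {key}")
        seen.add(key)
        p = Path(rec["path"])
        if not p.is_absolute():
            p = path.parent / p
            rec["path"] = str(p)
        if not p.exists():
            raise ValueError(f"{path}: referenced file missing: {p}")
    return m


def write_matrix(path, m: np.ndarray, labels=None) -> None:
    """Square matrix as TSV, optionally with row/column labels."""
    m = np.asarray(m)
    if labels is not None:
        pd.DataFrame(m, index=list(labels), columns=list(labels)).to_csv(
            path, sep="\t", float_format="%.6g"
        )
    else:
        pd.DataFrame(m).to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
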