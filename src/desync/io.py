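"""Tab-separated on-disk formats for scans, metadata, parcels and matrices.

Everything is plain TSV (UTF-8, '.' decimal): one parcels × frames matrix
file per scan with a header row of frame indices and parcel ids as the
index column; a cohort metadata table; a parcel-geometry table plus an
adjacency edge list; labelled square matrices for FC/distance output.
Round trips are lossless to 1e-12 and malformed input is rejected with the
offending row or column named.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix

from .cohort import ParcelSet

__all__ = [
    "write_scan_matrix",
    "read_scan_matrix",
    "write_metadata_table",
    "read_metadata_table",
    "write_parcel_table",
    "read_parcel_table",
    "write_labeled_matrix",
    "read_labeled_matrix",
]

METADATA_COLUMNS = [
    "scan_id",
    "participant",
    "session",
    "day",
    "condition",
    "task",
    "mean_fd",
    "scan_path",
]


def write_scan_matrix(path: str | Path, signals: np.ndarray, parcel_ids=None):
    signals = np.asarray(signals)
    if parcel_ids is None:
        parcel_ids = np.arange(signals.shape[0])
    df = pd.DataFrame(
        signals, index=pd.Index(parcel_ids, name="parcel_id"),
        columns=np.arange(signals.shape[1]),
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_scan_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (signals, parcel_ids); rejects ragged rows naming the row."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        rows, ids = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path.name}: row {lineno} has {len(parts)} fields, "
                    f"expected {n_cols}"
                )
            ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}: row {lineno}: non-numeric value ({exc})"
                ) from None
    return np.array(rows), np.array(ids)


def write_metadata_table(path: str | Path, meta: pd.DataFrame):
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table missing columns {missing}")
    meta.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing metadata columns {missing}")
    if meta["scan_id"].duplicated().any():
        dup = meta.loc[meta["scan_id"].duplicated(), "scan_id"].iloc[0]
        raise ValueError(f"{Path(path).name}: duplicate scan id {dup!r}")
    meta["task"] = meta["task"].astype(bool)
    return meta


def write_parcel_table(dirpath: str | Path, parcels: ParcelSet):
    dirpath = Path(dirpath)
    df = parcels.to_dataframe()
    df.to_csv(dirpath / "parcels.tsv", sep="\t", index=False,
              float_format="%.17g")
    edges = parcels.edge_list()
    pd.DataFrame(edges, columns=["parcel_a", "parcel_b"]).to_csv(
        dirpath / "parcel_edges.tsv", sep="\t", index=False
    )


def read_parcel_table(dirpath: str | Path) -> ParcelSet:
    dirpath = Path(dirpath)
    df = pd.read_csv(dirpath / "parcels.tsv", sep="\t")
    required = ["parcel_id", "network", "hemisphere", "x", "y", "z", "medial_wall"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"parcels.tsv: missing columns {missing}")
    edges = pd.read_csv(dirpath / "parcel_edges.tsv", sep="\t")
    n = len(df)
    rows = np.concatenate([edges["parcel_a"], edges["parcel_b"]])
    cols = np.concatenate([edges["parcel_b"], edges["parcel_a"]])
    adj = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return ParcelSet(
        parcel_ids=df["parcel_id"].to_numpy(),
        network_labels=df["network"].to_numpy(),
        hemisphere=df["hemisphere"].to_numpy(),
        centroids=df[["x", "y", "z"]].to_numpy(),
        adjacency=adj,
        medial_wall=df["medial_wall"].to_numpy().astype(bool),
    )


def write_labeled_matrix(path: str | Path, values: np.ndarray, labels):
    pd.DataFrame(values, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_labeled_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{Path(path).name}: matrix is {df.shape[0]}x{df.shape[1]}, not square"
        )
    return df.to_numpy(), list(df.index.astype(str))
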