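"""Plain-text I/O for the pipeline's tabular formats.

Time series: one CSV per subject, header row of ROI ids, T data rows.
Matrices: square CSV with the roi_id list as header and index.
Metrics: tidy long CSV (subject_id, cost, metric, roi_id, value).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import AdjacencyMatrix, ConnectivityMatrix, RoiTimeSeries

__all__ = [
    "write_timeseries", "read_timeseries", "read_timeseries_dir",
    "write_matrix", "read_connectivity", "read_adjacency",
    "write_metrics", "read_metrics", "write_json",
]


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    pd.DataFrame(ts.values, columns=ts.roi_ids).to_csv(path, index=False)


def read_timeseries(path, subject_id: str | None = None) -> RoiTimeSeries:
    path = Path(path)
    df = pd.read_csv(path)
    sid = subject_id or path.stem
    return RoiTimeSeries(sid, df.to_numpy(dtype=float), [str(c) for c in df.columns])


def read_timeseries_dir(directory) -> list[RoiTimeSeries]:
    paths = sorted(Path(directory).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no timeseries CSVs in {directory}")
    return [read_timeseries(p) for p in paths]


def write_matrix(mat, path) -> None:
    values = mat.z_values if isinstance(mat, ConnectivityMatrix) else mat.edges
    pd.DataFrame(values, index=mat.roi_ids, columns=mat.roi_ids).to_csv(path)


def read_connectivity(path, subject_id: str | None = None) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        subject_id or path.stem, df.to_numpy(dtype=float), [str(c) for c in df.columns]
    )


def read_adjacency(path, cost: float, subject_id: str | None = None) -> AdjacencyMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{path}: adjacency entries must be 0/1")
    return AdjacencyMatrix(
        subject_id or path.stem, cost, values.astype(np.int8),
        [str(c) for c in df.columns],
    )


def write_metrics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["cost"] = df["cost"].astype(float)
    df["value"] = df["value"].astype(float)
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
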