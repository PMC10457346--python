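"""Subject-level connectivity matrices and cost-based binarization.

The processing contract starts from denoised ROI BOLD time series (one
T x N table per subject). Pairwise Pearson correlations are Fisher
r-to-z transformed into a symmetric, zero-diagonal connectivity matrix;
binary graphs are then obtained by keeping the top ``cost`` fraction of
possible edges, sweeping cost from 5% to 35% in 5% steps (seven levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "AdjacencyMatrix",
    "DEFAULT_COSTS",
    "CLIP",
    "compute_connectivity",
    "include_rois",
    "binarize_at_cost",
    "cost_sweep",
    "target_edge_count",
]

#: Default proportional-threshold sweep: 5% .. 35% in 5% steps.
DEFAULT_COSTS: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)

#: Correlations of magnitude 1 are clipped to +/-(1 - CLIP) before atanh
#: so edge weights stay finite and rankable.
CLIP = 1e-7


class DegenerateInputError(ValueError):
    """Raised for inputs the model cannot represent (constant ROI, empty graph)."""


@dataclass
class RoiTimeSeries:
    """BOLD time series for one subject: T timepoints x N ROIs."""

    subject_id: str
    values: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        t, n = self.values.shape
        if t < 3:
            raise DegenerateInputError(
                f"subject {self.subject_id}: need at least 3 timepoints, got {t}"
            )
        if n < 3:
            raise ValueError(f"subject {self.subject_id}: need at least 3 ROIs, got {n}")
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length does not match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"subject {self.subject_id}: non-finite or missing entries")


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Fisher-z connectivity matrix with zero diagonal."""

    subject_id: str
    z_values: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        n = self.z_values.shape[0]
        if self.z_values.shape != (n, n):
            raise ValueError("z_values must be square")
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length does not match matrix size")
        if not np.allclose(self.z_values, self.z_values.T):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.diag(self.z_values) == 0):
            raise ValueError("diagonal must be exactly zero")
        if not np.all(np.isfinite(self.z_values)):
            raise ValueError("connectivity values must be finite")

    @property
    def n_rois(self) -> int:
        return self.z_values.shape[0]


@dataclass
class AdjacencyMatrix:
    """Binary undirected graph at one cost level of the sweep."""

    subject_id: str
    cost: float
    edges: np.ndarray
    roi_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges)
        if self.edges.dtype != np.int8:
            e = self.edges.astype(np.int8)
            if not np.array_equal(e, self.edges):
                raise ValueError("edges must be binary")
            self.edges = e
        if not np.all((self.edges == 0) | (self.edges == 1)):
            raise ValueError("edges must be binary")
        if not np.array_equal(self.edges, self.edges.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(self.edges) != 0):
            raise ValueError("self-loops are not allowed")
        if not self.roi_ids:
            self.roi_ids = [f"n{i}" for i in range(self.edges.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.edges.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.edges.sum()) // 2


def compute_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Fisher-z connectivity from a subject's ROI time series.

    Off-diagonal entries are ``atanh(clip(r_ij))`` for the pairwise Pearson
    correlation ``r_ij``; perfect (anti)correlations are clipped to
    ``+/-(1 - 1e-7)`` so every weight is finite. The diagonal is set to
    exactly zero and symmetry holds by construction.

    Raises
    ------
    DegenerateInputError
        If any ROI column is constant (its correlation is undefined).
    """
    x = ts.values
    sd = x.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = ", ".join(ts.roi_ids[i] for i in constant[:5])
        raise DegenerateInputError(
            f"subject {ts.subject_id}: constant time series for ROI(s) {names}"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0 + CLIP, 1.0 - CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(ts.subject_id, z, list(ts.roi_ids))


def include_rois(meta) -> list[str]:
    """Apply the ROI-inclusion rule: keep ROIs with >= 50% mask retention.

    ``meta`` is an iterable of records with ``roi_id``, ``voxels_total`` and
    ``voxels_in_mask`` attributes (or a pandas DataFrame with those columns).
    ROIs retaining strictly less than half their voxels inside the field-of-
    view mask are dropped; exactly 50% is kept. Input order is preserved.
    """
    rows: Sequence
    if hasattr(meta, "itertuples"):
        rows = list(meta.itertuples(index=False))
    else:
        rows = list(meta)
    kept: list[str] = []
    for row in rows:
        total = int(row.voxels_total)
        in_mask = int(row.voxels_in_mask)
        if total <= 0:
            raise ValueError(f"ROI {row.roi_id}: voxels_total must be positive")
        if in_mask < 0 or in_mask > total:
            raise ValueError(f"ROI {row.roi_id}: invalid voxel counts")
        if in_mask / total >= 0.5:
            kept.append(str(row.roi_id))
    return kept


def target_edge_count(n: int, cost: float) -> int:
    """Edges to keep at ``cost``: round-half-away-from-zero of cost * N(N-1)/2."""
    m = n * (n - 1) // 2
    return int(np.floor(cost * m + 0.5))


def _ranked_pairs(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by descending signed z.

    Ties are broken by ascending lexicographic (i, j) pair index so the
    ranking — and hence every thresholded graph — is deterministic and the
    sweep's edge sets are nested.
    """
    iu, ju = np.triu_indices(z.shape[0], k=1)
    w = z[iu, ju]
    order = np.lexsort((np.arange(w.size), -w))  # stable: -w primary, index secondary
    return iu[order], ju[order]


def binarize_at_cost(cm: ConnectivityMatrix, cost: float) -> AdjacencyMatrix:
    """Binarize a connectivity matrix keeping the top ``cost`` fraction of edges.

    Edges are ranked by signed Fisher-z (most positive first); the target
    count is round-half-away-from-zero of ``cost * N(N-1)/2``.
    """
    if not 0 < cost <= 1:
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    n = cm.n_rois
    k = target_edge_count(n, cost)
    if k == 0:
        raise DegenerateInputError(
            f"cost {cost} keeps zero edges for N={n}; graph would be empty"
        )
    iu, ju = _ranked_pairs(cm.z_values)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[:k], ju[:k]] = 1
    adj |= adj.T
    return AdjacencyMatrix(cm.subject_id, cost, adj, list(cm.roi_ids))


def cost_sweep(
    cm: ConnectivityMatrix, costs: Sequence[float] = DEFAULT_COSTS
) -> list[AdjacencyMatrix]:
    """Binarize across a strictly increasing cost sweep (default: 7 levels).

    With the fixed tie-break order the edge sets are nested: every edge
    present at a lower cost is present at every higher cost.
    """
    costs = list(costs)
    if not costs:
        raise ValueError("costs must be nonempty")
    if any(b <= a for a, b in zip(costs, costs[1:])):
        raise ValueError("costs must be strictly increasing")
    out = []
    for c in costs:
        try:
            out.append(binarize_at_cost(cm, c))
        except Exception as exc:
            raise type(exc)(f"cost {c}: {exc}") from exc
    return out
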