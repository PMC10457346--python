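"""Binary undirected graph metrics, written from scratch.

Implements the metric set used for cost-thresholded functional
connectomes: breadth-first all-pairs hop distances, characteristic path
length, clustering coefficient, nodal local efficiency, Newman
modularity with Louvain optimisation, degree-preserving rewiring nulls,
and small-worldness sigma = (C/C0) / (L/L0).

All routines take an :class:`~amynet.connectome.AdjacencyMatrix` (or a
raw binary numpy array where noted) and are deterministic under an
explicit seed wherever randomness is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import AdjacencyMatrix

__all__ = [
    "ModularityResult",
    "NullDistribution",
    "SmallWorldResult",
    "shortest_paths",
    "characteristic_path_length",
    "clustering_coefficient",
    "local_efficiency",
    "modularity_Q",
    "louvain",
    "rewire_degree_preserving",
    "null_distribution",
    "small_worldness",
    "metric_sweep",
]


@dataclass
class ModularityResult:
    partition: np.ndarray  # community label per node, 0..K-1
    Q: float
    gamma: float
    seed: int


@dataclass
class NullDistribution:
    """Mean clustering (C0) and path length (L0) over rewired null graphs."""

    n_iter: int
    C0: float
    L0: float
    seed: int
    cost: float | None = None


@dataclass
class SmallWorldResult:
    C: float
    L: float
    sigma: float
    null: NullDistribution


def _as_bool(adj) -> np.ndarray:
    a = adj.edges if isinstance(adj, AdjacencyMatrix) else np.asarray(adj)
    return a.astype(bool)


def shortest_paths(adj) -> np.ndarray:
    """All-pairs minimum hop counts via simultaneous BFS (frontier expansion).

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    a = _as_bool(adj).astype(np.uint8)
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    hops = 0
    while frontier.any():
        hops += 1
        nxt = (frontier.astype(np.uint8) @ a) > 0
        nxt &= ~reached
        d[nxt] = hops
        reached |= nxt
        frontier = nxt
    return d


def characteristic_path_length(adj) -> float:
    """Mean hop distance over reachable ordered pairs i != j.

    Infinite (cross-component) distances are excluded from the mean, the
    common convention for possibly-disconnected binary connectomes.
    """
    d = shortest_paths(adj)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        raise ValueError("graph has no reachable pairs; path length undefined")
    return float(d[finite].mean())


def clustering_coefficient(adj) -> tuple[np.ndarray, float]:
    """Per-node clustering C_i = 2 t_i / (k_i (k_i - 1)) and the network mean.

    Nodes with degree < 2 get C_i = 0. The mean is over all nodes.
    """
    a = _as_bool(adj).astype(np.int64)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / np.maximum(denom, 1), 0.0)
    return c, float(c.mean())


def local_efficiency(adj) -> np.ndarray:
    """Nodal local efficiency on the subgraph induced by each neighborhood.

    E_loc(i) = mean over ordered pairs (j, h) of distinct neighbors of i of
    1 / d_jh, with d computed inside the induced neighborhood subgraph and
    1/inf = 0. Nodes with fewer than two neighbors get 0.
    """
    a = _as_bool(adj)
    n = a.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        g = nbrs.size
        if g < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = shortest_paths(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        eloc[i] = inv.sum() / (g * (g - 1))
    return eloc


def modularity_Q(adj, partition, gamma: float = 1.0) -> float:
    """Newman modularity of a partition at resolution ``gamma``.

    Q = (1/2m) sum_ij [A_ij - gamma k_i k_j / (2m)] delta(c_i, c_j).
    """
    a = _as_bool(adj).astype(float)
    part = np.asarray(partition)
    if part.shape[0] != a.shape[0]:
        raise ValueError("partition must label every node")
    m2 = a.sum()
    if m2 == 0:
        raise ValueError("modularity undefined for an empty graph")
    k = a.sum(axis=1)
    q = 0.0
    for c in np.unique(part):
        idx = part == c
        q += a[np.ix_(idx, idx)].sum() - gamma * k[idx].sum() ** 2 / m2
    return float(q / m2)


def _louvain_one_level(
    w: np.ndarray, gamma: float, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """One local-moving phase on a weighted graph; returns (labels, moved_any)."""
    n = w.shape[0]
    m2 = w.sum()
    k = w.sum(axis=1)
    labels = np.arange(n)
    sigma_tot = k.copy()
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = labels[i]
            sigma_tot[ci] -= k[i]
            # weight from i to each neighboring community (excluding self-edge)
            wi = w[i].copy()
            wi[i] = 0.0
            nbr = np.flatnonzero(wi)
            links: dict[int, float] = {}
            for j in nbr:
                links[labels[j]] = links.get(labels[j], 0.0) + wi[j]
            best_c, best_gain = ci, links.get(ci, 0.0) - gamma * k[i] * sigma_tot[ci] / m2
            for c, wc in links.items():
                if c == ci:
                    continue
                gain = wc - gamma * k[i] * sigma_tot[c] / m2
                # strict improvement required; ties keep the current community
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            labels[i] = best_c
            sigma_tot[best_c] += k[i]
            if best_c != ci:
                improved = True
                moved_any = True
    return labels, moved_any


def _aggregate(w: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse communities into super-nodes; self-loops carry internal weight."""
    uniq, dense = np.unique(labels, return_inverse=True)
    k = uniq.size
    ind = np.zeros((w.shape[0], k))
    ind[np.arange(w.shape[0]), dense] = 1.0
    return ind.T @ w @ ind, dense


def louvain(adj, gamma: float = 1.0, seed: int = 0, restarts: int = 1) -> ModularityResult:
    """Two-phase Louvain community detection with seeded node-visit order.

    Identical seeds give identical partitions. ``restarts`` > 1 reruns the
    greedy search from different seeded visit orders and keeps the best-Q
    partition; the default is a single run (no consensus clustering). The
    returned Q is recomputed from the final partition with
    :func:`modularity_Q`, so the pair is always internally consistent.
    """
    if restarts > 1:
        runs = [louvain(adj, gamma, seed + i, restarts=1) for i in range(restarts)]
        return max(runs, key=lambda r: r.Q)
    a = _as_bool(adj).astype(float)
    if a.sum() == 0:
        raise ValueError("Louvain requires at least one edge")
    rng = np.random.default_rng(seed)
    w = a.copy()
    node_labels = np.arange(a.shape[0])
    while True:
        labels, moved = _louvain_one_level(w, gamma, rng)
        if not moved:
            break
        w, dense = _aggregate(w, labels)
        # dense[i] is the new super-node of old super-node i
        node_labels = dense[node_labels]
    # relabel communities 0..K-1 in order of first appearance
    _, partition = np.unique(node_labels, return_inverse=True)
    q = modularity_Q(a, partition, gamma)
    return ModularityResult(partition, q, gamma, seed)


def rewire_degree_preserving(
    adj, seed: int = 0, swap_factor: float = 10.0
) -> AdjacencyMatrix:
    """Degree-preserving randomization by repeated double-edge swaps.

    Attempts ``swap_factor * m`` swaps of edge pairs (a, b), (c, d) ->
    (a, d), (c, b), rejecting any swap that would create a self-loop or a
    duplicate edge. The degree sequence is invariant. Emits a warning if no
    swap succeeded within the attempt budget (e.g. a triangle, which admits
    none) and returns the graph as rewired so far.
    """
    a = _as_bool(adj).copy()
    iu, ju = np.nonzero(np.triu(a, k=1))
    m = iu.size
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    edges = np.stack([iu, ju], axis=1)
    rng = np.random.default_rng(seed)
    attempts = int(np.ceil(swap_factor * m))
    successes = 0
    pair_idx = rng.integers(0, m, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        e1, e2 = pair_idx[t]
        if e1 == e2:
            continue
        x1, y1 = edges[e1]
        x2, y2 = edges[e2]
        if flips[t]:
            x2, y2 = y2, x2
        # propose (x1, y2) and (x2, y1)
        if x1 == y2 or x2 == y1:
            continue
        if a[x1, y2] or a[x2, y1]:
            continue
        if len({x1, y1, x2, y2}) < 4:
            continue
        a[x1, y1] = a[y1, x1] = False
        a[x2, y2] = a[y2, x2] = False
        a[x1, y2] = a[y2, x1] = True
        a[x2, y1] = a[y1, x2] = True
        edges[e1] = (min(x1, y2), max(x1, y2))
        edges[e2] = (min(x2, y1), max(x2, y1))
        successes += 1
    if successes == 0:
        warnings.warn(
            "no valid double-edge swap found within the attempt budget; "
            "graph returned unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
    subject = adj.subject_id if isinstance(adj, AdjacencyMatrix) else "null"
    cost = adj.cost if isinstance(adj, AdjacencyMatrix) else float("nan")
    roi_ids = list(adj.roi_ids) if isinstance(adj, AdjacencyMatrix) else []
    return AdjacencyMatrix(subject, cost, a.astype(np.int8), roi_ids)


def _er_null(adj, seed: int) -> AdjacencyMatrix:
    """Edge-count-preserving null: m edges sampled uniformly at random."""
    a = _as_bool(adj)
    n = a.shape[0]
    m = int(a.sum()) // 2
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.choice(iu.size, size=m, replace=False)
    out = np.zeros((n, n), dtype=np.int8)
    out[iu[pick], ju[pick]] = 1
    out |= out.T
    subject = adj.subject_id if isinstance(adj, AdjacencyMatrix) else "null"
    cost = adj.cost if isinstance(adj, AdjacencyMatrix) else float("nan")
    return AdjacencyMatrix(subject, cost, out)


def null_distribution(
    adj, n_iter: int = 10_000, seed: int = 0, model: str = "degree"
) -> NullDistribution:
    """Mean null clustering C0 and path length L0 over randomized copies.

    The default ``model='degree'`` independently rewires the observed graph
    by double-edge swaps, preserving every node's degree; ``model='er'``
    instead draws Erdos-Renyi-style graphs with only the edge count
    preserved. C0 and L0 are the means over ``n_iter`` iterates.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if model not in ("degree", "er"):
        raise ValueError(f"unknown null model {model!r}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_iter)
    cs = np.empty(n_iter)
    ls = np.empty(n_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for t in range(n_iter):
            s = int(child_seeds[t])
            if model == "degree":
                null = rewire_degree_preserving(adj, seed=s)
            else:
                null = _er_null(adj, seed=s)
            _, cs[t] = clustering_coefficient(null)
            ls[t] = characteristic_path_length(null)
    cost = adj.cost if isinstance(adj, AdjacencyMatrix) else None
    return NullDistribution(n_iter, float(cs.mean()), float(ls.mean()), seed, cost)


def small_worldness(adj, null: NullDistribution) -> SmallWorldResult:
    """Small-worldness sigma = (C/C0) / (L/L0) against a rewired null."""
    if null.C0 <= 0:
        raise ValueError("null clustering C0 is zero; sigma undefined")
    if null.L0 <= 0:
        raise ValueError("null path length L0 is zero; sigma undefined")
    _, c = clustering_coefficient(adj)
    length = characteristic_path_length(adj)
    sigma = (c / null.C0) / (length / null.L0)
    return SmallWorldResult(c, length, sigma, null)


def metric_sweep(
    adjs: list[AdjacencyMatrix],
    n_iter: int = 10_000,
    seed: int = 0,
    gamma: float = 1.0,
) -> pd.DataFrame:
    """All graph metrics for one subject's cost sweep, as a tidy table.

    Returns rows (subject_id, cost, metric, roi_id, value) where ``roi_id``
    is empty for network-level metrics (local_efficiency mean, clustering,
    path_length, modularity, sigma, C0, L0) and set for the per-node
    local_efficiency and clustering values.
    """
    rows: list[dict] = []
    children = np.random.SeedSequence(seed).spawn(len(adjs))
    for adj, child in zip(adjs, children):
        s_louvain, s_null = (int(s.generate_state(1)[0] % 2**31) for s in child.spawn(2))
        cost = adj.cost
        sid = adj.subject_id
        try:
            eloc = local_efficiency(adj)
            cvec, c_mean = clustering_coefficient(adj)
            length = characteristic_path_length(adj)
            mod = louvain(adj, gamma=gamma, seed=s_louvain)
            null = null_distribution(adj, n_iter=n_iter, seed=s_null)
            sw = small_worldness(adj, null)
        except Exception as exc:
            raise type(exc)(f"subject {sid}, cost {cost}: {exc}") from exc

        def put(metric: str, value: float, roi: str = "") -> None:
            rows.append(
                {"subject_id": sid, "cost": cost, "metric": metric,
                 "roi_id": roi, "value": float(value)}
            )

        for roi, v in zip(adj.roi_ids, eloc):
            put("local_efficiency", v, roi)
        for roi, v in zip(adj.roi_ids, cvec):
            put("clustering", v, roi)
        put("local_efficiency", eloc.mean())
        put("clustering", c_mean)
        put("path_length", length)
        put("modularity", mod.Q)
        put("small_worldness", sw.sigma)
        put("null_C0", null.C0)
        put("null_L0", null.L0)
    return pd.DataFrame(rows, columns=["subject_id", "cost", "metric", "roi_id", "value"])
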