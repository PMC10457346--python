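"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study conditions end to end: ~65 cognitively
normal older adults of whom ~32% are amyloid-positive, modular ROI BOLD
time series (a latent factor model) whose thresholded graphs are
small-world across the 5-35% cost sweep, and a planted metric-memory
association present only in the amyloid-positive group.

Each ROI's series is ``lambda_s * (its module's latent Gaussian signal)
+ sqrt(1 - lambda_s^2) * independent Gaussian noise``; the per-subject
coupling ``lambda_s`` controls how modular and locally efficient the
subject's graph is, and memory is linked to ``lambda_s`` (not to a
computed graph metric), avoiding circularity while guaranteeing a
recoverable association.

Two modes exist: the full mode emits time series so the connectome stage
is exercised end to end, and a fast mode (:func:`generate_metric_table`)
draws per-cost metric values directly from the same latent model for
inference-layer simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import AdjacencyMatrix, RoiTimeSeries, DEFAULT_COSTS
from .summaries import SUVR_THRESHOLD

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_cohort",
           "generate_metric_table", "planted_partial_r", "fixture_graphs"]


@dataclass
class SyntheticConfig:
    """Cohort-generator parameters; defaults are the emulated study conditions.

    ``beta_interaction`` is the slope of memory on the standardized latent
    coupling within the amyloid-positive group only; the default, together
    with ``memory_noise_sd`` and the fast-mode metric noise, places the
    planted within-group partial correlation near 0.65 (mid-range of the
    correlations the analysis is designed to detect).
    """

    n_total: int = 65
    frac_positive: float = 0.32
    n_rois: int = 135
    n_modules: int = 5
    within_loading: float = 0.55   # mean subject coupling lambda_s
    loading_sd: float = 0.12
    noise_sd: float = 1.0          # overall BOLD scale (arbitrary units)
    t_points: int = 84
    beta_interaction: float = 1.06  # memory ~ z(lambda_s) slope, Abeta+ only
    hippocampal_boost: float = 0.0
    memory_intercept: float = 12.7  # word-list immediate free recall items
    memory_noise_sd: float = 1.0
    metric_loading: float = 1.0     # fast mode: metric ~ z(lambda_s) slope
    metric_noise_sd: float = 0.5    # fast mode: per-cost idiosyncratic noise
    covariate_effects: dict = field(
        default_factory=lambda: {"age": -0.05, "sex": 0.3, "education": 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.frac_positive < 1:
            raise ValueError("frac_positive must be in (0, 1)")
        if not 0 < self.within_loading < 1:
            raise ValueError("within_loading must be in (0, 1)")
        if self.n_modules > self.n_rois:
            raise ValueError("cannot have more modules than ROIs")
        for name in ("loading_sd", "noise_sd", "memory_noise_sd", "metric_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_positive(self) -> int:
        return int(round(self.frac_positive * self.n_total))


@dataclass
class SyntheticCohort:
    timeseries: list[RoiTimeSeries]
    pheno: pd.DataFrame
    truth: dict


def _truncnorm(rng, loc, scale, lower, upper, size):
    a, b = (lower - loc) / scale, (upper - loc) / scale
    return sps.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _phenotypes(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics, SUVR consistent with the classification threshold,
    and group labels. Covariate distributions loosely track a cognitively
    normal aging cohort and exist only to make adjustment non-trivial."""
    n, n_pos = cfg.n_total, cfg.n_positive
    abeta = np.zeros(n, dtype=int)
    abeta[rng.permutation(n)[:n_pos]] = 1
    suvr = np.where(
        abeta == 1,
        _truncnorm(rng, 1.32, 0.15, SUVR_THRESHOLD + 1e-6, 2.5, n),
        _truncnorm(rng, 1.00, 0.07, 0.6, SUVR_THRESHOLD, n),
    )
    age = _truncnorm(rng, 72.3, 6.2, 60.0, 95.0, n)
    education = np.clip(rng.normal(16.2, 2.3, n), 8, None)
    # group-dependent female rates; redraw if a group comes out single-sex,
    # since a constant covariate would make within-group adjustment degenerate
    rates = np.where(abeta == 1, 0.81, 0.41)
    for _ in range(100):
        sex = (rng.uniform(size=n) < rates).astype(int)
        if all(0 < sex[abeta == g].sum() < (abeta == g).sum() for g in (0, 1)):
            break
    icv = rng.normal(1.45e6, 1.2e5, n)
    hippo = rng.normal(7300, 700, n) - 40.0 * (age - 72.3)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education": education,
            "global_suvr": suvr,
            "abeta_positive": abeta,
            "hippocampal_volume": hippo,
            "icv": icv,
        }
    )


def _memory(cfg, rng, pheno, lam_z):
    ce = cfg.covariate_effects
    mem = (
        cfg.memory_intercept
        + ce.get("age", 0.0) * (pheno["age"] - pheno["age"].mean())
        + ce.get("sex", 0.0) * pheno["sex"]
        + ce.get("education", 0.0) * (pheno["education"] - pheno["education"].mean())
        + cfg.beta_interaction * lam_z * pheno["abeta_positive"]
        + rng.normal(0, cfg.memory_noise_sd, cfg.n_total)
    )
    return mem.to_numpy()


def _latent_couplings(cfg, rng):
    lam = np.clip(
        rng.normal(cfg.within_loading, cfg.loading_sd, cfg.n_total), 0.15, 0.90
    )
    lam_z = (lam - lam.mean()) / lam.std()
    return lam, lam_z


def module_assignment(n_rois: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal module blocks over the ROI ordering."""
    return (np.arange(n_rois) * n_modules // n_rois).astype(int)


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Full-mode cohort: ROI time series + phenotypes + planted truth.

    Reproducible under ``cfg.seed``; the amyloid-positive count equals
    ``round(frac_positive * n_total)`` exactly (21 of 65 by default).
    """
    rng = np.random.default_rng(cfg.seed)
    pheno = _phenotypes(cfg, rng)
    lam, lam_z = _latent_couplings(cfg, rng)
    pheno["memory"] = _memory(cfg, rng, pheno, lam_z)

    modules = module_assignment(cfg.n_rois, cfg.n_modules)
    roi_ids = [f"ROI{k + 1:03d}" for k in range(cfg.n_rois)]
    hippo_mask = np.zeros(cfg.n_rois, dtype=bool)
    hippo_mask[:4] = True  # by convention the first four ROIs are hippocampal

    series = []
    for s in range(cfg.n_total):
        lam_s = np.full(cfg.n_rois, lam[s])
        if cfg.hippocampal_boost and pheno.loc[s, "abeta_positive"] == 1:
            lam_s[hippo_mask] = np.clip(lam_s[hippo_mask] + cfg.hippocampal_boost, 0, 0.98)
        g = rng.normal(size=(cfg.t_points, cfg.n_modules))
        eps = rng.normal(size=(cfg.t_points, cfg.n_rois))
        x = cfg.noise_sd * (
            lam_s * g[:, modules] + np.sqrt(1.0 - lam_s**2) * eps
        )
        series.append(RoiTimeSeries(pheno.loc[s, "subject_id"], x, list(roi_ids)))

    truth = {
        "module_assignment": modules.tolist(),
        "lambda_s": lam.tolist(),
        "beta_interaction": cfg.beta_interaction,
        "config": asdict(cfg),
    }
    return SyntheticCohort(series, pheno, truth)


def generate_metric_table(
    cfg: SyntheticConfig, costs=DEFAULT_COSTS
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fast mode: per-cost metric values drawn directly from the latent model.

    metric(s, c) = mu_c + metric_loading * z(lambda_s) + noise(s, c), with
    independent per-cost noise, giving a compound-symmetric within-subject
    covariance. Returns (metric_wide indexed by subject, pheno, truth).
    Used for inference-layer simulation studies where running the graph
    pipeline per replicate would add nothing but runtime.
    """
    rng = np.random.default_rng(cfg.seed)
    pheno = _phenotypes(cfg, rng)
    lam, lam_z = _latent_couplings(cfg, rng)
    pheno["memory"] = _memory(cfg, rng, pheno, lam_z)
    costs = list(costs)
    mu = 0.4 + 0.8 * np.asarray(costs)  # level rises with cost, as observed metrics do
    vals = (
        mu[None, :]
        + cfg.metric_loading * lam_z[:, None]
        + rng.normal(0, cfg.metric_noise_sd, (cfg.n_total, len(costs)))
    )
    wide = pd.DataFrame(vals, index=pheno["subject_id"], columns=costs)
    truth = {"lambda_s": lam.tolist(), "beta_interaction": cfg.beta_interaction}
    return wide, pheno, truth


def planted_partial_r(cfg: SyntheticConfig) -> float:
    """Population partial correlation (metric vs memory, given covariates)
    planted within the amyloid-positive group by the fast-mode model.

    Both metric and memory load on the standardized latent coupling z:
    metric = a*z + noise(sd_m), memory = b*z + noise(sd_e) (after covariate
    adjustment), so r = a*b / sqrt((a^2 + sd_m^2)(b^2 + sd_e^2)). With the
    defaults this is ~0.65, in the range of within-group correlations the
    analysis is designed to detect.
    """
    a, b = cfg.metric_loading, cfg.beta_interaction
    return float(
        a * b / np.sqrt((a**2 + cfg.metric_noise_sd**2) * (b**2 + cfg.memory_noise_sd**2))
    )


# ---------------------------------------------------------------------------
# named fixture graphs with analytically known metric values


def _adj(name: str, a: np.ndarray) -> AdjacencyMatrix:
    return AdjacencyMatrix(name, float("nan"), np.asarray(a, dtype=np.int8))


def _complete(n: int) -> np.ndarray:
    a = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(a, 0)
    return a


def _ws_ring(n: int, k: int, p: float, seed: int) -> np.ndarray:
    """Watts-Strogatz ring: n nodes, k nearest neighbors, rewire prob p."""
    rng = np.random.default_rng(seed)
    a = np.zeros((n, n), dtype=np.int8)
    for j in range(1, k // 2 + 1):
        idx = np.arange(n)
        a[idx, (idx + j) % n] = 1
        a[(idx + j) % n, idx] = 1
    for j in range(1, k // 2 + 1):
        for u in range(n):
            if rng.uniform() < p:
                v = (u + j) % n
                if not a[u, v]:
                    continue
                choices = np.flatnonzero((a[u] == 0) & (np.arange(n) != u))
                if choices.size == 0:
                    continue
                w = int(rng.choice(choices))
                a[u, v] = a[v, u] = 0
                a[u, w] = a[w, u] = 1
    return a


def _er(n: int, p: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    a = (rng.uniform(size=(n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    return (a + a.T).astype(np.int8)


def _two_block(n: int, seed: int) -> np.ndarray:
    """Planted two-block graph: dense within blocks, one cross edge."""
    rng = np.random.default_rng(seed)
    half = n // 2
    a = np.zeros((n, n), dtype=np.int8)
    for lo, hi in ((0, half), (half, n)):
        blk = (rng.uniform(size=(hi - lo, hi - lo)) < 0.9).astype(np.int8)
        blk = np.triu(blk, k=1)
        a[lo:hi, lo:hi] = blk + blk.T
    a[0, half] = a[half, 0] = 1
    return a


def fixture_graphs(seed: int = 0) -> dict[str, AdjacencyMatrix]:
    """Named benchmark graphs with documented expected metric values.

    K3/K4: complete graphs (clustering and local efficiency 1, L = 1).
    P3: path 0-1-2 (L = 4/3; middle-node clustering 0). star3: 3-leaf star
    (local efficiency 0 everywhere). two_K3: two disconnected triangles
    (Louvain recovers the components, Q = 0.5). two_block: planted 8-node
    two-community graph. ws_ring: Watts-Strogatz(100, 6, 0.1), small-world
    (sigma > 1). dense_er: Erdos-Renyi(100, 0.3), sigma ~ 1.
    """
    p3 = np.zeros((3, 3), dtype=np.int8)
    p3[0, 1] = p3[1, 0] = p3[1, 2] = p3[2, 1] = 1
    star = np.zeros((4, 4), dtype=np.int8)
    star[0, 1:] = star[1:, 0] = 1
    two_k3 = np.zeros((6, 6), dtype=np.int8)
    two_k3[:3, :3] = _complete(3)
    two_k3[3:, 3:] = _complete(3)
    return {
        "K3": _adj("K3", _complete(3)),
        "K4": _adj("K4", _complete(4)),
        "P3": _adj("P3", p3),
        "star3": _adj("star3", star),
        "two_K3": _adj("two_K3", two_k3),
        "two_block": _adj("two_block", _two_block(8, seed)),
        "ws_ring": _adj("ws_ring", _ws_ring(100, 6, 0.1, seed)),
        "dense_er": _adj("dense_er", _er(100, 0.3, seed)),
    }
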