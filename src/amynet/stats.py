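"""Inference layer: repeated-measures ANCOVA across the cost sweep,
per-cost interaction scans, covariate-adjusted partial correlations per
amyloid group, Fisher r-to-z comparison of group correlations,
multiplicity handling and group comparisons.

The repeated-measures model treats the graph metric at each cost as a
within-subject factor (7 levels by default), amyloid status as a
between-subject factor, an optional continuous predictor (memory or
hippocampal volume ratio), and covariates of no interest. Between
effects use Type-III sums of squares with effects-coded factors and
mean-centered continuous regressors. Within-subject (x cost) terms use
the univariate mixed-model F on orthonormal polynomial contrasts, with
Mauchly's sphericity test and conditional Greenhouse-Geisser scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RmAncovaResult",
    "rm_ancova",
    "mauchly_test",
    "gg_epsilon",
    "within_contrasts",
    "per_cost_interaction",
    "interaction_scan",
    "partial_correlation",
    "group_partial_correlations",
    "compare_correlations",
    "adjust_pvalues",
    "group_compare",
    "pooled_t_from_summary",
]


@dataclass
class RmAncovaResult:
    """One tested effect of the repeated-measures ANCOVA.

    Between-subject effects carry NaN in the sphericity fields; within
    (x cost) effects always report both the uncorrected and the
    Greenhouse-Geisser p, with ``p`` equal to the corrected value only
    when Mauchly's test rejected sphericity (p < .05).
    """

    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    p_uncorrected: float = np.nan
    p_gg: float = np.nan
    gg_epsilon: float = np.nan
    mauchly_W: float = np.nan
    mauchly_p: float = np.nan
    corrected: bool = False


def within_contrasts(p: int) -> np.ndarray:
    """Orthonormal polynomial contrast matrix, p x (p-1), M'M = I."""
    if p < 2:
        raise ValueError("need at least 2 within-subject levels")
    levels = np.arange(p, dtype=float)
    V = np.vander(levels, p, increasing=True)  # columns 1, t, t^2, ...
    Q, _ = np.linalg.qr(V)
    M = Q[:, 1:]
    return M


def gg_epsilon(S: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the contrast covariance S = M' Sigma M.

    S must be computed with orthonormal contrasts. epsilon is clipped to
    [1/(p-1), 1]; under exact sphericity (S proportional to the identity)
    epsilon equals 1.
    """
    S = np.asarray(S, dtype=float)
    d = S.shape[0]
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    if tr2 <= 0:
        raise ValueError("singular contrast covariance")
    eps = tr**2 / (d * tr2)
    return float(np.clip(eps, 1.0 / d, 1.0))


def mauchly_test(S: np.ndarray, df_error: int) -> tuple[float, float]:
    """Mauchly's sphericity test on the contrast covariance S.

    Returns (W, p) with W = det(S) / (tr(S)/d)^d and the standard
    chi-square approximation on f = d(d+1)/2 - 1 degrees of freedom.
    With only 2 within levels (d = 1) sphericity is vacuous: W = 1, p = 1.
    """
    S = np.asarray(S, dtype=float)
    d = S.shape[0]
    if d == 1:
        return 1.0, 1.0
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("singular contrast covariance; Mauchly W undefined")
    logw = logdet - d * np.log(np.trace(S) / d)
    W = float(np.exp(logw))
    f = d * (d + 1) / 2 - 1
    rho = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * df_error)
    chi2 = -df_error * rho * logw
    p = float(sps.chi2.sf(chi2, f))
    return W, p


def _build_design(
    pheno: pd.DataFrame,
    between: str | None,
    predictor: str | None,
    covariates: list[str],
) -> tuple[np.ndarray, list[str]]:
    """Type-III design: intercept, effects-coded factor (+1/-1), centered
    continuous predictor, their product, centered covariates."""
    n = len(pheno)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    g = None
    if between is not None:
        raw = pheno[between].to_numpy(dtype=float)
        if set(np.unique(raw)) - {0.0, 1.0}:
            raise ValueError(f"between factor {between!r} must be binary 0/1")
        g = 2.0 * raw - 1.0  # effects coding: -1 / +1
        cols.append(g)
        names.append(between)
    x = None
    if predictor is not None:
        x = pheno[predictor].to_numpy(dtype=float)
        x = x - x.mean()
        cols.append(x)
        names.append(predictor)
    if between is not None and predictor is not None:
        cols.append(g * x)
        names.append(f"{between}_x_{predictor}")
    for c in covariates:
        v = pheno[c].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via rank-revealing QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, names


def rm_ancova(
    metric_wide: pd.DataFrame,
    pheno: pd.DataFrame,
    between: str | None = "abeta_positive",
    predictor: str | None = None,
    covariates: list[str] = ("age", "sex", "education"),
) -> list[RmAncovaResult]:
    """Cost-repeated ANCOVA on a subjects x costs metric table.

    ``metric_wide`` is indexed by subject_id with one column per cost level;
    ``pheno`` is indexed (or indexable) by subject_id and supplies the
    between factor, predictor, and covariates. Subjects with any missing
    value are dropped listwise (logged).

    Between-subject effects are F-tests on the subject-mean metric;
    effect-by-cost terms are univariate repeated-measures F-tests on
    orthonormal cost contrasts, with Greenhouse-Geisser correction applied
    when Mauchly's p < .05 (both p-values always reported).
    """
    covariates = list(covariates)
    ph = pheno.set_index("subject_id") if "subject_id" in pheno.columns else pheno
    common = metric_wide.index.intersection(ph.index)
    need = [c for c in ([between, predictor] + covariates) if c is not None]
    ph = ph.loc[common, need]
    Y = metric_wide.loc[common].to_numpy(dtype=float)
    keep = ~(ph.isna().any(axis=1).to_numpy() | np.isnan(Y).any(axis=1))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("rm_ancova: listwise deletion dropped %d subject(s)", dropped)
    ph, Y = ph.loc[keep], Y[keep]
    n, p = Y.shape
    X, names = _build_design(ph, between, predictor, covariates)
    r = X.shape[1]
    if n <= r + 1:
        raise ValueError("too few subjects for the requested design")
    XtX_inv = np.linalg.inv(X.T @ X)
    df_e = n - r

    results: list[RmAncovaResult] = []

    # ---- between-subject effects: OLS on the subject-mean metric ----
    y_mean = Y.mean(axis=1)
    b = XtX_inv @ X.T @ y_mean
    resid = y_mean - X @ b
    mse = resid @ resid / df_e
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        Fj = b[j] ** 2 / (XtX_inv[j, j] * mse)
        results.append(
            RmAncovaResult(name, float(Fj), 1.0, float(df_e), float(sps.f.sf(Fj, 1, df_e)))
        )

    if p >= 2:
        # ---- within-subject (x cost) effects on orthonormal contrasts ----
        M = within_contrasts(p)
        Z = Y @ M
        Bz = XtX_inv @ X.T @ Z
        E = Z.T @ Z - Bz.T @ (X.T @ X) @ Bz
        S = E / df_e
        W, mauchly_p = mauchly_test(S, df_e)
        eps = gg_epsilon(S)
        corrected = mauchly_p < 0.05
        d = p - 1
        for j, name in enumerate(names):
            hz = Bz[j]
            H = np.outer(hz, hz) / XtX_inv[j, j]
            F = (np.trace(H) / d) / (np.trace(E) / (df_e * d))
            df1, df2 = float(d), float(df_e * d)
            p_unc = float(sps.f.sf(F, df1, df2))
            p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps))
            label = "cost" if name == "intercept" else f"{name}_x_cost"
            results.append(
                RmAncovaResult(
                    effect=label,
                    F=float(F),
                    df_num=df1 * eps if corrected else df1,
                    df_den=df2 * eps if corrected else df2,
                    p=p_gg if corrected else p_unc,
                    p_uncorrected=p_unc,
                    p_gg=p_gg,
                    gg_epsilon=eps,
                    mauchly_W=W,
                    mauchly_p=mauchly_p,
                    corrected=bool(corrected),
                )
            )
    return results


def per_cost_interaction(
    y: np.ndarray,
    pheno: pd.DataFrame,
    between: str = "abeta_positive",
    predictor: str = "memory",
    covariates: list[str] = ("age", "sex", "education"),
) -> tuple[float, float]:
    """Interaction t-test from the per-cost follow-up linear regression.

    Fits metric ~ group + predictor + group:predictor + covariates by OLS
    and returns (t, p) for the interaction coefficient. The group is the
    0/1 amyloid indicator and the predictor is centered, so the test is
    invariant to factor coding.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("metric is constant at this cost; no model can be fit")
    g = pheno[between].to_numpy(dtype=float)
    x = pheno[predictor].to_numpy(dtype=float)
    x = x - x.mean()
    cols = [np.ones_like(y), g, x, g * x] + [
        pheno[c].to_numpy(dtype=float) for c in covariates
    ]
    X = np.column_stack(cols)
    n, r = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    b = XtX_inv @ X.T @ y
    resid = y - X @ b
    df = n - r
    se = np.sqrt(XtX_inv[3, 3] * (resid @ resid) / df)
    t = b[3] / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def interaction_scan(
    metric_wide: pd.DataFrame,
    pheno: pd.DataFrame,
    between: str = "abeta_positive",
    predictor: str = "memory",
    covariates: list[str] = ("age", "sex", "education"),
    method: str = "bonferroni_threshold",
) -> pd.DataFrame:
    """Per-cost interaction t and p, with raw and adjusted significance flags."""
    ph = pheno.set_index("subject_id") if "subject_id" in pheno.columns else pheno
    ph = ph.loc[metric_wide.index]
    rows = []
    for cost in metric_wide.columns:
        t, p = per_cost_interaction(
            metric_wide[cost].to_numpy(), ph, between, predictor, list(covariates)
        )
        rows.append({"cost": cost, "t": t, "p": p})
    scan = pd.DataFrame(rows)
    scan["significant_unadjusted"] = scan["p"] < 0.05
    scan["significant_adjusted"] = adjust_pvalues(scan["p"].to_numpy(), method)
    return scan


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int, int]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by least squares and
    the residuals correlated; p comes from t = r sqrt((n-2-k)/(1-r^2)) on
    n-2-k degrees of freedom. With no covariates this is the plain Pearson
    correlation. Returns (r, p, n, k).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        C = np.ones((n, 1))
        k = 0
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        k = C.shape[1] - 1
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("collinear covariates")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is exactly linear in the covariates")
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 2 - k
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(df / (1 - r_**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p, n, k


def group_partial_correlations(
    metric: np.ndarray,
    pheno: pd.DataFrame,
    predictor: str = "memory",
    between: str = "abeta_positive",
    covariates: list[str] = ("age", "sex", "education"),
) -> pd.DataFrame:
    """Within-group partial correlations (metric vs predictor) and their
    Fisher r-to-z comparison across the two amyloid groups."""
    metric = np.asarray(metric, dtype=float)
    cov = pheno[list(covariates)].to_numpy(dtype=float)
    g = pheno[between].to_numpy(dtype=float)
    rows = {}
    for label, mask in (("abeta_neg", g == 0), ("abeta_pos", g == 1)):
        r, p, n, k = partial_correlation(
            metric[mask], pheno[predictor].to_numpy(dtype=float)[mask], cov[mask]
        )
        rows[label] = {"group": label, "partial_r": r, "p": p, "n": n, "k": k}
    z, pz = compare_correlations(
        rows["abeta_pos"]["partial_r"], rows["abeta_pos"]["n"],
        rows["abeta_neg"]["partial_r"], rows["abeta_neg"]["n"],
        k=rows["abeta_pos"]["k"],
    )
    out = pd.DataFrame([rows["abeta_neg"], rows["abeta_pos"]])
    out["comparison_z"] = z
    out["comparison_p"] = pz
    return out


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int, k: int = 0
) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent (partial) correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3-k) + 1/(n2-3-k)); two-sided
    normal p. ``k`` adjusts the degrees of freedom for partial correlations
    with k covariates.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
        if n - 3 - k <= 0:
            raise ValueError(f"group too small: need n > k + 3, got n={n}, k={k}")
    se = np.sqrt(1.0 / (n1 - 3 - k) + 1.0 / (n2 - 3 - k))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def adjust_pvalues(pvals, method: str = "bh", alpha: float = 0.05) -> np.ndarray:
    """Multiplicity decision flags across the cost family.

    ``bh``: Benjamini-Hochberg step-up at q = alpha. ``bonferroni_threshold``:
    fixed per-test threshold alpha/m (the figure-style cutoff, 0.05/7 = 0.0071
    for the default sweep).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni_threshold":
        return p < alpha / m
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        below = ranked <= alpha * (np.arange(1, m + 1) / m)
        flags = np.zeros(m, dtype=bool)
        if below.any():
            cutoff = np.max(np.flatnonzero(below))
            flags[order[: cutoff + 1]] = True
        return flags
    raise ValueError(f"unknown method {method!r}")


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from (mean, SD, n) summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def group_compare(
    pheno: pd.DataFrame, variable: str, between: str = "abeta_positive"
) -> tuple[float, float]:
    """Two-group comparison of a phenotype variable (negative minus positive).

    Continuous variables: pooled-variance independent-samples t. Categorical
    (two distinct values): Pearson chi-square without continuity correction.
    """
    g = pheno[between].to_numpy(dtype=float)
    v = pheno[variable]
    if v.dtype == object or v.nunique() == 2 and set(v.unique()) <= {0, 1}:
        tab = pd.crosstab(v, g).to_numpy()
        if tab.shape != (2, 2) or (tab == 0).any():
            raise ValueError("need a complete 2x2 table for the chi-square test")
        chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
        return float(chi2), float(p)
    a = v.to_numpy(dtype=float)[g == 0]
    b = v.to_numpy(dtype=float)[g == 1]
    return pooled_t_from_summary(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)
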