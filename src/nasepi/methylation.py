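"""Methylation-scale transforms, winsorization, ReFACTor and the meQTL screen.

M-values are the logit2 transform of Beta proportions; regression is run
on the M scale and effect sizes are converted back to Beta differences
with the M-model-M-mean rule (logistic difference at the CpG's mean M).
ReFACTor provides reference-free surrogate cell-composition components.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .containers import GenotypeGroupScreen, MethylationMatrix, RefactorComponents


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)); accepts scalars, arrays or DataFrames."""
    arr = np.asarray(beta, dtype=float)
    if arr.size and (arr.min() <= 0 or arr.max() >= 1):
        raise ValueError("beta values must lie strictly in (0, 1)")
    out = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out


def m_to_beta(m):
    """beta = 2^M / (1 + 2^M), the inverse of :func:`beta_to_m`."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    return out


def as_m_matrix(mm: MethylationMatrix) -> MethylationMatrix:
    if mm.scale == "m":
        return mm
    return MethylationMatrix(beta_to_m(mm.values), "m", mm.annotation)


def as_beta_matrix(mm: MethylationMatrix) -> MethylationMatrix:
    if mm.scale == "beta":
        return mm
    return MethylationMatrix(m_to_beta(mm.values), "beta", mm.annotation)


def winsorize_m(
    m: pd.DataFrame | np.ndarray, lower: float = 0.05, upper: float = 0.95
) -> pd.DataFrame | np.ndarray:
    """Per-CpG winsorization to the next observed value inside the quantiles.

    For each row, values below the ``lower`` linear-interpolation quantile
    are replaced by the smallest observed value at or above it, and values
    above the ``upper`` quantile by the largest observed value at or below
    it — replacement "with the next closest value" rather than the
    quantile itself.
    """
    arr = np.asarray(m, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
        squeeze = True
    else:
        squeeze = False
    if arr.shape[1] < 3:
        raise ValueError("winsorization needs at least 3 samples")
    qL = np.quantile(arr, lower, axis=1, method="linear")
    qU = np.quantile(arr, upper, axis=1, method="linear")
    out = arr.copy()
    for i in range(arr.shape[0]):
        row = arr[i]
        lo_mask = row < qL[i]
        hi_mask = row > qU[i]
        if lo_mask.any():
            out[i, lo_mask] = row[~lo_mask].min()
        if hi_mask.any():
            out[i, hi_mask] = row[~hi_mask].max()
    if squeeze:
        out = out[0]
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    return out


def refactor_components(
    beta: pd.DataFrame, k: int = 10, t: int = 500
) -> RefactorComponents:
    """Reference-free cell-composition surrogates (ReFACTor).

    Standardize each CpG row, score rows by the distance between the
    standardized row and its rank-k principal-component reconstruction,
    keep the ``t`` best-reconstructed (most 'cell-composition-like')
    sites, and return the first k principal-component scores of that
    submatrix as per-sample components.
    """
    n_cpgs, n_samples = beta.shape
    if k >= n_samples:
        raise ValueError("k must be smaller than the number of samples")
    if t < k or t > n_cpgs:
        raise ValueError("need k <= t <= n_cpgs")
    X = beta.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    # rank-k reconstruction via SVD of the standardized matrix
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    recon = (U[:, :k] * s[:k]) @ Vt[:k]
    score = np.linalg.norm(Z - recon, axis=1)
    order = np.argsort(score, kind="stable")[:t]
    sites = beta.index[np.sort(order)]

    Zs = Z[np.sort(order)]
    Us, ss, Vts = np.linalg.svd(Zs - Zs.mean(axis=0, keepdims=True), full_matrices=False)
    comps = (Vts[:k] * ss[:k, None]).T  # samples x k PC scores
    comps -= comps.mean(axis=0, keepdims=True)
    scores = pd.DataFrame(
        comps, index=beta.columns, columns=[f"RC{i+1}" for i in range(k)]
    )
    return RefactorComponents(scores, sites, k, t)


def delta_m_to_delta_beta(mean_m, delta_m):
    """Convert an M-scale effect to a Beta difference at the CpG's mean M.

    delta_beta = sigma(mean_m + delta_m) - sigma(mean_m) with
    sigma(m) = 2^m / (1 + 2^m): the logistic one-sided difference taken
    at the overall mean M (the reference level).
    """
    mean_m = np.asarray(mean_m, dtype=float)
    delta_m = np.asarray(delta_m, dtype=float)
    return m_to_beta(mean_m + delta_m) - m_to_beta(mean_m)


def kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact, deterministic 1-D k-means.

    In one dimension the optimal k-means clusters are intervals of the
    sorted values, so the global optimum is found exactly by dynamic
    programming over cut points (no initialisation or iteration — this
    is where Lloyd's algorithm would converge from its best start).
    Returns (assignments, centers) with centers sorted ascending.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if k < 1 or k > n:
        raise ValueError("need 1 <= k <= n")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    c1 = np.concatenate([[0.0], np.cumsum(xs)])
    c2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def sse(i: int, j: int) -> float:  # segment [i, j)
        m = j - i
        s = c1[j] - c1[i]
        return (c2[j] - c2[i]) - s * s / m

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            best, arg = INF, g - 1
            for i in range(g - 1, j):
                v = cost[g - 1, i] + sse(i, j)
                if v < best - 1e-15:
                    best, arg = v, i
            cost[g, j] = best
            cut[g, j] = arg

    bounds = [n]
    j = n
    for g in range(k, 0, -1):
        j = cut[g, j]
        bounds.append(j)
    bounds = bounds[::-1]

    assign_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for g in range(k):
        lo, hi = bounds[g], bounds[g + 1]
        assign_sorted[lo:hi] = g
        centers[g] = xs[lo:hi].mean()
    assign = np.empty(n, dtype=int)
    assign[order] = assign_sorted
    return assign, centers


def genotype_group_screen(
    beta_values: np.ndarray | pd.Series,
    cluster_labels: np.ndarray,
    k_groups: int = 2,
) -> GenotypeGroupScreen:
    """Screen a CpG for meQTL-like discrete methylation groups.

    Beta values are grouped by deterministic 1-D k-means; the group x
    microbiome-cluster contingency table is tested for independence with
    a Pearson chi-squared test (no continuity correction). A warning
    flag is raised when any expected cell count is below 5, and the
    screen is skipped for degenerate (constant) input.
    """
    if k_groups not in (2, 3):
        raise ValueError("k_groups must be 2 or 3")
    x = np.asarray(beta_values, dtype=float)
    labels = np.asarray(cluster_labels)
    if x.shape[0] != labels.shape[0]:
        raise ValueError("beta values and cluster labels must align")
    if x.shape[0] < 3 * k_groups:
        raise ValueError("too few samples for the group screen")
    if np.ptp(x) == 0:
        return GenotypeGroupScreen(None, None, None, None, None, skipped=True)
    groups, centers = kmeans_1d(x, k_groups)
    table = pd.crosstab(groups, labels).to_numpy()
    if (table.sum(axis=1) == 0).any() or table.shape[0] < 2:
        return GenotypeGroupScreen(groups, centers, None, None, None, skipped=True)
    chi2, p, df, expected = chi2_contingency(table, correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn("chi-squared screen has expected cell counts < 5")
    return GenotypeGroupScreen(groups, centers, float(chi2), int(df), float(p), low)
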