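"""Beta-diversity distances, PAM clustering, k selection and LOO stability.

The clustering follows the enterotyping recipe: Jensen-Shannon divergence
between relative-abundance profiles, partitioning around medoids, the
number of clusters chosen by the mean silhouette over k = 2..10, and
leave-one-out stability quantified by the adjusted Rand index against
the full-data partition.

PAM here is the classical BUILD + SWAP algorithm made fully
deterministic: all ties break toward the smallest sample index, so no
seed is involved and repeated runs are identical.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from .containers import ClusterSolution, DistanceMatrix, KSelectionReport, StabilityReport

_METRICS = ("jsd", "jsd_sqrt", "bray_curtis", "jaccard")


def _entropy_cols(p: np.ndarray) -> np.ndarray:
    """Column-wise Shannon entropy in nats with the 0*log0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=0)


def pairwise_distance(ra: pd.DataFrame, metric: str = "jsd") -> DistanceMatrix:
    """All-pairs dissimilarity between samples (columns of ``ra``).

    jsd uses natural log: JSD(P,Q) = H((P+Q)/2) - (H(P)+H(Q))/2, bounded
    by ln 2. jsd_sqrt is its square root (a metric). bray_curtis and
    jaccard (on presence/absence) come from scipy.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
    X = ra.to_numpy(dtype=float)
    if X.min() < -1e-12:
        raise ValueError("relative abundances must be non-negative")
    colsums = X.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-8):
        raise ValueError("columns must sum to one (relative abundances)")

    if metric in ("jsd", "jsd_sqrt"):
        h = _entropy_cols(X)
        n = X.shape[1]
        # mixture entropies for all pairs: H((P+Q)/2), taxa x n x n tensor
        mix = 0.5 * (X[:, :, None] + X[:, None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            mlogm = np.where(mix > 0, mix * np.log(mix), 0.0)
        hmix = -mlogm.sum(axis=0)
        d = hmix - 0.5 * (h[:, None] + h[None, :])
        d = np.clip(d, 0.0, np.log(2.0))
        np.fill_diagonal(d, 0.0)
        d = 0.5 * (d + d.T)
        if metric == "jsd_sqrt":
            d = np.sqrt(d)
    elif metric == "bray_curtis":
        d = squareform(pdist(X.T, metric="braycurtis"))
    else:  # jaccard on presence/absence
        d = squareform(pdist((X.T > 0), metric="jaccard"))
    return DistanceMatrix(d, metric, ra.columns)


def pam_cluster(d: DistanceMatrix, k: int) -> ClusterSolution:
    """Partitioning around medoids with deterministic BUILD + SWAP.

    BUILD greedily picks the k medoids that most reduce the total cost;
    SWAP repeatedly applies the single best strictly-improving
    medoid/non-medoid exchange. Ties always resolve to the smallest
    sample index, and points equidistant from several medoids join the
    medoid with the smallest index.
    """
    D = d.values
    n = d.n
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n (= {n}); got {k}")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[:, medoids[0]].copy()
    while len(medoids) < k:
        cand_cost = np.minimum(dnear[:, None], D).sum(axis=0)
        cand_cost[medoids] = np.inf
        new = int(np.argmin(cand_cost))
        medoids.append(new)
        dnear = np.minimum(dnear, D[:, new])
    medoids = sorted(medoids)

    # SWAP: apply the best strictly improving exchange until none exists
    for _ in range(10_000):
        med = np.array(medoids)
        sub = D[:, med]
        order = np.argsort(sub, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = sub[np.arange(n), nearest]
        d2 = sub[np.arange(n), order[:, 1]] if k >= 2 else np.full(n, np.inf)
        cost = d1.sum()

        nonmed = np.setdiff1d(np.arange(n), med)
        if nonmed.size == 0:
            break
        best = (cost, None)
        for mi, m in enumerate(med):
            base = np.where(nearest == mi, d2, d1)
            newcosts = np.minimum(base[:, None], D[:, nonmed]).sum(axis=0)
            j = int(np.argmin(newcosts))
            if newcosts[j] < best[0] - 1e-12:
                best = (newcosts[j], (mi, nonmed[j]))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = int(h)
        medoids = sorted(medoids)

    med = np.array(sorted(medoids))
    sub = D[:, med]
    nearest = np.argmin(sub, axis=1)  # ties -> smallest medoid index
    labels = nearest + 1
    total = float(sub[np.arange(n), nearest].sum())
    return ClusterSolution(labels, med, k, d.metric, total, d.sample_ids)


def mean_silhouette(d: DistanceMatrix, labels: np.ndarray) -> float:
    """Mean silhouette width on a precomputed dissimilarity.

    Singletons contribute s = 0, and the degenerate 0/0 case (duplicate
    points split across clusters) is defined as 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two clusters")
    D = d.values
    n = d.n
    s = np.zeros(n)
    masks = {u: labels == u for u in uniq}
    sizes = {u: int(m.sum()) for u, m in masks.items()}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            s[i] = 0.0
            continue
        a = D[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(D[i, masks[u]].mean() for u in uniq if u != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def pcoa_embedding(d: DistanceMatrix, tol: float = 1e-9) -> np.ndarray:
    """Classical principal-coordinate embedding of a dissimilarity.

    Double-centers the squared-distance Gram matrix and keeps axes with
    positive eigenvalues; Euclidean inputs are recovered exactly up to
    rotation.
    """
    D2 = d.values**2
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    keep = vals > tol * max(vals.max(), 1.0)
    return vecs[:, keep] * np.sqrt(vals[keep])


def calinski_harabasz(d: DistanceMatrix, labels: np.ndarray) -> float:
    """CHI = [B/(k-1)] / [W/(n-k)] on the principal-coordinate embedding."""
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("CHI needs at least two clusters")
    if k >= d.n:
        raise ValueError("CHI undefined when every sample is its own cluster")
    coords = pcoa_embedding(d)
    return float(calinski_harabasz_score(coords, labels))


def select_k(d: DistanceMatrix, k_range: range | None = None) -> KSelectionReport:
    """Scan k, computing silhouette and CHI; pick the silhouette argmax.

    Ties go to the smaller k. CHI is reported alongside for inspection.
    """
    if k_range is None:
        k_range = range(2, 11)
    ks = np.array([k for k in k_range if 2 <= k < d.n])
    if ks.size == 0:
        raise ValueError("k_range contains no admissible k")
    sil = np.empty(ks.size)
    chi = np.empty(ks.size)
    for i, k in enumerate(ks):
        sol = pam_cluster(d, int(k))
        sil[i] = mean_silhouette(d, sol.labels)
        chi[i] = calinski_harabasz(d, sol.labels)
    chosen = int(ks[int(np.argmax(sil))])
    return KSelectionReport(ks, sil, chi, chosen)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two samples")
    return float(adjusted_rand_score(a, b))


def assign_to_medoid(d_row: np.ndarray, medoid_positions: np.ndarray) -> int:
    """Nearest-medoid assignment (0-based cluster id); ties -> smallest index."""
    return int(np.argmin(d_row[medoid_positions]))


def loo_stability(
    d: DistanceMatrix,
    full: ClusterSolution,
    k_range: range | None = None,
) -> StabilityReport:
    """Leave-one-out stability of the clustering.

    For each held-out sample: re-select k by silhouette, re-run PAM,
    assign the held-out sample to its nearest medoid, and compare the
    resulting full-length labelling against the all-samples solution by
    the adjusted Rand index.
    """
    if d.n < 4:
        raise ValueError("leave-one-out stability needs n >= 4")
    if k_range is None:
        k_range = range(2, 11)
    n = d.n
    sel_k = np.empty(n, dtype=int)
    aris = np.empty(n)
    heldout = np.empty(n, dtype=int)
    for i in range(n):
        d_sub = d.drop(i)
        rep = select_k(d_sub, k_range)
        sol = pam_cluster(d_sub, rep.chosen_k)
        # positions of the medoids in the original indexing
        keep = np.delete(np.arange(n), i)
        med_orig = keep[sol.medoid_indices]
        lab_i = assign_to_medoid(d.values[i], med_orig) + 1
        labels_iter = np.empty(n, dtype=int)
        labels_iter[keep] = sol.labels
        labels_iter[i] = lab_i
        sel_k[i] = rep.chosen_k
        heldout[i] = lab_i
        aris[i] = adjusted_rand_index(full.labels, labels_iter)
    return StabilityReport(sel_k, aris, heldout, d.sample_ids)


def rename_by_size(sol: ClusterSolution) -> ClusterSolution:
    """Re-index clusters so cluster 1 is the largest.

    Equal sizes are ordered by the smallest original medoid index.
    """
    sizes = sol.sizes()
    order = sorted(range(sol.k), key=lambda c: (-sizes[c], sol.medoid_indices[c]))
    remap = np.empty(sol.k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    labels = remap[sol.labels - 1]
    medoids = sol.medoid_indices[order]
    return ClusterSolution(
        labels, medoids, sol.k, sol.metric, sol.total_cost, sol.sample_ids
    )


def pam_exhaustive(d: DistanceMatrix, k: int) -> tuple[tuple[int, ...], float]:
    """Exact minimiser over all medoid subsets (test oracle; small n only)."""
    from itertools import combinations

    if d.n > 12:
        raise ValueError("exhaustive search is for small instances only")
    best = (None, np.inf)
    for med in combinations(range(d.n), k):
        cost = d.values[:, med].min(axis=1).sum()
        if cost < best[1] - 1e-15:
            best = (med, cost)
    return best[0], float(best[1])
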