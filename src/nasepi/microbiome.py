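"""Count-table QC, genus aggregation, iterated rarefaction and alpha diversity.

The QC mirrors a standard 16S amplicon workflow: drop shallow libraries,
zero per-cell low-abundance counts, merge OTUs at the genus level, then
rarefy to the minimum library size by iterated subsampling without
replacement and average the resampled tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import AlphaDiversity, CountMatrix, TAXONOMY_RANKS


def filter_samples_by_depth(cm: CountMatrix, min_reads: int = 10_000) -> CountMatrix:
    """Retain samples whose library size is at least ``min_reads``."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    keep = cm.library_sizes() >= min_reads
    if not keep.any():
        warnings.warn("all samples fall below the read-depth threshold")
    return CountMatrix(cm.counts.loc[:, keep[keep].index], cm.taxonomy)


def zero_low_abundance(cm: CountMatrix, min_copies: int = 10) -> CountMatrix:
    """Zero cells with 0 < count < ``min_copies``; drop taxa left all-zero.

    The low-abundance rule is applied per cell (per sample), the only
    reading under which "in individual samples" is meaningful.
    """
    vals = cm.counts.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("low-abundance zeroing requires integer counts")
    out = cm.counts.copy()
    out[(out > 0) & (out < min_copies)] = 0
    nonzero = out.sum(axis=1) > 0
    out = out.loc[nonzero]
    tax = None if cm.taxonomy is None else cm.taxonomy.loc[out.index]
    return CountMatrix(out, tax)


def drop_low_abundance_taxa(cm: CountMatrix, min_copies: int = 10) -> CountMatrix:
    """Alternative reading of the low-abundance rule: drop whole taxa whose
    maximum per-sample count is below ``min_copies``."""
    keep = (cm.counts >= min_copies).any(axis=1)
    out = cm.counts.loc[keep]
    tax = None if cm.taxonomy is None else cm.taxonomy.loc[out.index]
    return CountMatrix(out, tax)


def genus_labels(taxonomy: pd.DataFrame) -> pd.Series:
    """Per-taxon genus label, falling back to 'unclassified <rank>'.

    A genus entry that is missing/empty is replaced by ``unclassified``
    plus the lowest resolved higher rank (family, then order, ...).
    """
    ranks = [r for r in TAXONOMY_RANKS if r in taxonomy.columns]
    if "genus" not in ranks:
        raise ValueError("taxonomy must include a genus column")

    def _label(row: pd.Series) -> str:
        g = row.get("genus")
        if isinstance(g, str) and g.strip():
            return g
        for rank in reversed(ranks[:-1]):
            v = row.get(rank)
            if isinstance(v, str) and v.strip():
                return f"unclassified {v}"
        return "unclassified"

    return taxonomy.apply(_label, axis=1)


def merge_to_genus(cm: CountMatrix) -> CountMatrix:
    """Sum OTU rows sharing a genus label; column sums are unchanged."""
    if cm.taxonomy is None:
        raise ValueError("merge_to_genus requires taxonomy")
    labels = genus_labels(cm.taxonomy.loc[cm.counts.index])
    merged = cm.counts.groupby(labels, sort=False).sum()
    merged.index.name = cm.counts.index.name

    tax = cm.taxonomy.loc[cm.counts.index].copy()
    tax["__genus__"] = labels.values
    agg = tax.groupby("__genus__", sort=False).first()
    agg = agg.loc[merged.index]
    agg["genus"] = agg.index
    return CountMatrix(merged, agg[[c for c in tax.columns if c != "__genus__"]])


def iterated_rarefaction(
    cm: CountMatrix, iterations: int = 1000, seed: int | None = None
) -> CountMatrix:
    """Rarefy every sample to the minimum library size, ``iterations`` times,
    and return the per-cell mean of the resampled tables.

    Each iteration draws L reads without replacement from each sample
    (multivariate hypergeometric), where L is the smallest library size.
    The averaged table is real-valued; every column sums to L exactly.
    """
    if cm.n_samples == 0:
        raise ValueError("cannot rarefy an empty matrix")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    vals = cm.counts.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("rarefaction requires integer counts")
    vals = np.round(vals).astype(np.int64)
    depths = vals.sum(axis=0)
    L = int(depths.min())
    if L == 0:
        raise ValueError("minimum library size is zero")

    rng = np.random.default_rng(seed)
    out = np.empty(vals.shape, dtype=float)
    for j in range(cm.n_samples):
        col = vals[:, j]
        if depths[j] == L:
            # drawing all reads without replacement returns the sample as-is
            out[:, j] = col
            continue
        draws = rng.multivariate_hypergeometric(col, L, size=iterations)
        out[:, j] = draws.mean(axis=0)
    rare = pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)
    return CountMatrix(rare, cm.taxonomy)


def to_relative_abundance(cm: CountMatrix) -> pd.DataFrame:
    """Taxa x samples proportions; every column sums to one."""
    sums = cm.counts.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    return cm.counts / sums


def alpha_diversity(cm: CountMatrix) -> AlphaDiversity:
    """Observed richness, Shannon entropy in nats, and Gini-Simpson index.

    Computed on the raw (pre-rarefaction) counts, as in the source
    workflow. Shannon is reported in natural-log units.
    """
    vals = cm.counts.to_numpy(dtype=float)
    sums = vals.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("all-zero sample in alpha diversity input")
    p = vals / sums
    richness = (vals > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0)
    simpson = 1.0 - (p**2).sum(axis=0)
    return AlphaDiversity(
        pd.DataFrame(
            {"richness": richness, "shannon": shannon, "simpson": simpson},
            index=cm.sample_ids,
        )
    )


def prevalence_filter(cm: CountMatrix, min_prevalence: float = 0.15) -> CountMatrix:
    """Retain taxa observed in at least ceil(min_prevalence * n) samples."""
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    n = cm.n_samples
    need = int(np.ceil(min_prevalence * n))
    present = (cm.counts > 0).sum(axis=1)
    keep = present >= max(need, 1)
    out = cm.counts.loc[keep]
    tax = None if cm.taxonomy is None else cm.taxonomy.loc[out.index]
    return CountMatrix(out, tax)


def cluster_profile_summary(
    ra: pd.DataFrame,
    labels: np.ndarray,
    taxonomy: pd.DataFrame | None = None,
    rank: str = "phylum",
) -> dict[str, pd.DataFrame]:
    """Per-cluster median relative abundance by genus and by a higher rank."""
    if len(labels) != ra.shape[1]:
        raise ValueError("labels must align with samples")
    labels = np.asarray(labels)
    by_genus = {}
    for lab in np.unique(labels):
        sub = ra.loc[:, np.asarray(labels == lab)]
        by_genus[lab] = sub.median(axis=1)
    genus_table = pd.DataFrame(by_genus)
    out = {"genus": genus_table}
    if taxonomy is not None and rank in taxonomy.columns:
        grp = ra.groupby(taxonomy.loc[ra.index, rank]).sum()
        by_rank = {}
        for lab in np.unique(labels):
            sub = grp.loc[:, np.asarray(labels == lab)]
            by_rank[lab] = sub.median(axis=1)
        out[rank] = pd.DataFrame(by_rank)
    return out
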