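"""Core data containers shared across the pipeline.

Light dataclass wrappers around pandas objects: a taxa-by-sample count
table with taxonomy (:class:`CountMatrix`), a CpG-by-sample methylation
matrix on the Beta or M scale (:class:`MethylationMatrix`), and the
result records produced by clustering and the EWAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TAXONOMY_RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]


@dataclass
class CountMatrix:
    """Taxa x samples abundance table with optional taxonomy.

    ``counts`` rows are taxa, columns are samples. Entries are integers
    before rarefaction and reals after iterated-rarefaction averaging.
    ``taxonomy`` (when present) is indexed by taxon id with the rank
    columns kingdom..genus; an unresolved genus is written
    ``"unclassified <lowest resolved rank>"``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("taxon ids must be unique")
        if self.counts.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        if self.taxonomy is not None:
            missing = self.counts.index.difference(self.taxonomy.index)
            if len(missing):
                raise ValueError(f"taxa missing from taxonomy: {list(missing)[:5]}")

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)], self.taxonomy)

    def copy(self) -> "CountMatrix":
        tax = None if self.taxonomy is None else self.taxonomy.copy()
        return CountMatrix(self.counts.copy(), tax)


@dataclass
class MethylationMatrix:
    """CpG x samples methylation values on the ``beta`` or ``m`` scale.

    Beta values must lie strictly inside (0, 1). ``annotation`` is
    indexed by CpG id with columns chromosome / position (1-based) /
    gene where available.
    """

    values: pd.DataFrame
    scale: str = "beta"
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "m"):
            raise ValueError(f"scale must be 'beta' or 'm', got {self.scale!r}")
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("methylation matrix contains missing values")
        if self.scale == "beta" and vals.size:
            if vals.min() <= 0.0 or vals.max() >= 1.0:
                bad = np.argwhere((vals <= 0) | (vals >= 1))[0]
                raise ValueError(
                    "beta values must lie strictly in (0,1); offending cell "
                    f"({self.values.index[bad[0]]}, {self.values.columns[bad[1]]})"
                )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[0]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(
            self.values.loc[:, list(sample_ids)], self.scale, self.annotation
        )


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix."""

    values: np.ndarray
    metric: str
    sample_ids: pd.Index

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) > 1e-10) or d.min() < -1e-12:
            raise ValueError("distances must be non-negative with zero diagonal")
        self.values = d

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def drop(self, i: int) -> "DistanceMatrix":
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return DistanceMatrix(
            self.values[np.ix_(keep, keep)], self.metric, self.sample_ids[keep]
        )


@dataclass
class ClusterSolution:
    """PAM output: labels in 1..k, medoid positions, and total cost."""

    labels: np.ndarray  # int array, values in 1..k, aligned with sample_ids
    medoid_indices: np.ndarray  # positions into sample_ids, one per cluster
    k: int
    metric: str
    total_cost: float
    sample_ids: pd.Index

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


@dataclass
class KSelectionReport:
    """Silhouette and CHI over a scanned k range, plus the chosen k."""

    k_values: np.ndarray
    silhouette: np.ndarray
    chi: np.ndarray
    chosen_k: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k_values, "silhouette": self.silhouette, "chi": self.chi}
        )


@dataclass
class StabilityReport:
    """Leave-one-out cluster stability: per-iteration k, ARI, assignment."""

    selected_k: np.ndarray
    ari: np.ndarray
    heldout_label: np.ndarray
    sample_ids: pd.Index

    @property
    def min_ari(self) -> float:
        return float(np.min(self.ari))

    @property
    def median_ari(self) -> float:
        return float(np.median(self.ari))

    def k_agreement(self, k: int) -> float:
        return float(np.mean(self.selected_k == k))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "selected_k": self.selected_k,
                "ari": self.ari,
                "heldout_label": self.heldout_label,
            }
        )


@dataclass
class RefactorComponents:
    """Sparse-PCA surrogate cell-composition scores (samples x k)."""

    scores: pd.DataFrame  # samples x k, columns RC1..RCk
    selected_sites: pd.Index
    k: int
    t: int


@dataclass
class AlphaDiversity:
    """Per-sample richness, Shannon entropy (nats) and Gini-Simpson index."""

    table: pd.DataFrame  # columns: richness, shannon, simpson

    def __post_init__(self) -> None:
        t = self.table
        if (t["shannon"] < -1e-12).any() or (t["simpson"] < -1e-12).any():
            raise ValueError("diversity indices must be non-negative")


@dataclass
class PermutationResult:
    """Permutation empirical null for the genome-wide DMP count."""

    n_permutations: int
    observed_dmps: int
    permuted_dmps: np.ndarray
    empirical_p: float


@dataclass
class GenotypeGroupScreen:
    """1-D k-means methylation grouping with a chi-squared independence test."""

    groups: np.ndarray | None
    centers: np.ndarray | None
    chi2: float | None
    df: int | None
    p: float | None
    low_expected: bool = False
    skipped: bool = False


@dataclass
class RunManifest:
    """Machine-readable record of a pipeline run."""

    config: dict = field(default_factory=dict)
    version: str = ""
    seeds: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def log_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})
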