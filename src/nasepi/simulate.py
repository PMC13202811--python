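"""Synthetic nasal microbiome + methylome cohorts with known ground truth.

The generator emulates the data structure the analysis assumes: six
community archetypes (Dirichlet-multinomial at genus level, with the
dominant-genus relative abundances and cluster proportions of the study
population), a CpG Beta matrix with planted cluster effects on the M
scale, taxon-linked CpGs, a latent cell-composition factor, and a linear
epigenetic clock constructed so that applying it to the generated Beta
matrix returns chronological age plus controlled noise and a planted
taxon effect on age deviation. Planted effects are recorded in a
:class:`SyntheticTruth` record for parameter-recovery tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .clock import ClockDefinition, age_transform
from .containers import CountMatrix, MethylationMatrix, TAXONOMY_RANKS
from .methylation import delta_m_to_delta_beta, m_to_beta

# genus -> (phylum, class, order, family); genus "" means unresolved,
# labelled "unclassified <family>" downstream
_TAXA: dict[str, tuple[str, str, str, str, str]] = {
    "Corynebacterium": ("Actinobacteria", "Actinomycetia", "Corynebacteriales", "Corynebacteriaceae", "Corynebacterium"),
    "Propionibacterium": ("Actinobacteria", "Actinomycetia", "Propionibacteriales", "Propionibacteriaceae", "Propionibacterium"),
    "unclassified Actinomycetales": ("Actinobacteria", "Actinomycetia", "Actinomycetales", "", ""),
    "Staphylococcus": ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    "Streptococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    "Dolosigranulum": ("Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae", "Dolosigranulum"),
    "Gemella": ("Firmicutes", "Bacilli", "Bacillales", "Gemellaceae", "Gemella"),
    "Lactobacillus": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    "Anaerococcus": ("Firmicutes", "Clostridia", "Tissierellales", "Peptoniphilaceae", "Anaerococcus"),
    "Peptoniphilus": ("Firmicutes", "Clostridia", "Tissierellales", "Peptoniphilaceae", "Peptoniphilus"),
    "Finegoldia": ("Firmicutes", "Clostridia", "Tissierellales", "Peptoniphilaceae", "Finegoldia"),
    "unclassified Neisseriaceae": ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", ""),
    "Moraxella": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Moraxella"),
    "Haemophilus": ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Haemophilus"),
    "Prevotella": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    "Fusobacterium": ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
    # low-abundance background flora shared across archetypes
    "Rothia": ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Rothia"),
    "Actinomyces": ("Actinobacteria", "Actinomycetia", "Actinomycetales", "Actinomycetaceae", "Actinomyces"),
    "Micrococcus": ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Micrococcus"),
    "Kocuria": ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Kocuria"),
    "Bifidobacterium": ("Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
    "Veillonella": ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella"),
    "Granulicatella": ("Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae", "Granulicatella"),
    "Abiotrophia": ("Firmicutes", "Bacilli", "Lactobacillales", "Aerococcaceae", "Abiotrophia"),
    "Enterococcus": ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae", "Enterococcus"),
    "Bacillus": ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus"),
    "Clostridium": ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    "Blautia": ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Blautia"),
    "Neisseria": ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "Neisseria"),
    "Acinetobacter": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Acinetobacter"),
    "Pseudomonas": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"),
    "Klebsiella": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Klebsiella"),
    "Escherichia": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia"),
    "Serratia": ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Yersiniaceae", "Serratia"),
    "Campylobacter": ("Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Campylobacteraceae", "Campylobacter"),
    "Porphyromonas": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Porphyromonas"),
    "Capnocytophaga": ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Capnocytophaga"),
    "Chryseobacterium": ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Weeksellaceae", "Chryseobacterium"),
    "Leptotrichia": ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Leptotrichiaceae", "Leptotrichia"),
}

GENERA = list(_TAXA)

# every archetype reserves this fraction of its mass as a uniform
# background over the genera it does not list, so each sample carries a
# rare biosphere deep enough to survive the <10-copies QC rule and the
# prevalence-filtered analysis family has the size the genus-level
# workflow expects (~39 genera).
BACKGROUND_FRACTION = 0.06

# six community archetypes: mean genus relative abundances.
# dominant-genus means follow the reported cluster profiles
# (Corynebacterium 0.67 / Propionibacterium 0.50 / Staphylococcus 0.65 /
# Staph 0.14 + Strep 0.16 / unclassified Neisseriaceae 0.38 /
# Moraxella 0.57); the remaining mass is spread over minor genera.
DEFAULT_ARCHETYPES: tuple[dict[str, float], ...] = (
    {"Corynebacterium": 0.67, "Staphylococcus": 0.08, "Propionibacterium": 0.07,
     "Dolosigranulum": 0.05, "Streptococcus": 0.03, "Moraxella": 0.02,
     "Anaerococcus": 0.02, "Peptoniphilus": 0.02, "unclassified Actinomycetales": 0.02,
     "Gemella": 0.01, "Haemophilus": 0.01},
    {"Propionibacterium": 0.50, "Corynebacterium": 0.15, "Staphylococcus": 0.12,
     "Anaerococcus": 0.05, "Peptoniphilus": 0.05, "unclassified Actinomycetales": 0.04,
     "Finegoldia": 0.03, "Streptococcus": 0.03, "Dolosigranulum": 0.02,
     "Moraxella": 0.01},
    {"Staphylococcus": 0.65, "Corynebacterium": 0.10, "Propionibacterium": 0.07,
     "Streptococcus": 0.05, "Anaerococcus": 0.03, "Gemella": 0.03,
     "Dolosigranulum": 0.02, "Peptoniphilus": 0.02, "Haemophilus": 0.02,
     "Moraxella": 0.01},
    {"Streptococcus": 0.16, "Staphylococcus": 0.14, "Prevotella": 0.09,
     "Corynebacterium": 0.07, "Gemella": 0.07, "Haemophilus": 0.07,
     "Propionibacterium": 0.06, "Dolosigranulum": 0.05, "Fusobacterium": 0.05,
     "Anaerococcus": 0.05, "Peptoniphilus": 0.05, "Lactobacillus": 0.04,
     "Finegoldia": 0.04, "unclassified Neisseriaceae": 0.03,
     "unclassified Actinomycetales": 0.03},
    {"unclassified Neisseriaceae": 0.38, "Streptococcus": 0.12, "Moraxella": 0.08,
     "Haemophilus": 0.08, "Staphylococcus": 0.07, "Corynebacterium": 0.06,
     "Prevotella": 0.06, "Propionibacterium": 0.05, "Gemella": 0.04,
     "Fusobacterium": 0.03, "Dolosigranulum": 0.03},
    {"Moraxella": 0.57, "Corynebacterium": 0.10, "Staphylococcus": 0.08,
     "Streptococcus": 0.05, "Dolosigranulum": 0.05, "Haemophilus": 0.05,
     "Propionibacterium": 0.04, "Gemella": 0.03, "unclassified Neisseriaceae": 0.03},
)

# cohort cluster proportions: sizes 120/83/79/41/33/16 of 372
DEFAULT_CLUSTER_WEIGHTS = (
    120 / 372, 83 / 372, 79 / 372, 41 / 372, 33 / 372, 16 / 372,
)

RACE_LEVELS = ("Asian", "Black", "Hispanic", "White", "Other")
RACE_PROPS = (0.019, 0.153, 0.094, 0.669, 0.065)

LOG_RA_FLOOR = 1e-6  # pseudo relative abundance to avoid log(0)


def default_planted_dmps(n_cpgs: int) -> list[tuple[int, tuple[int, int], float]]:
    """Cluster-linked CpG effects: (cpg index, (cluster a, cluster b), dM).

    M-scale shifts of ~0.3-0.8 at hemi-methylated CpGs give Beta
    differences of ~5-13 percentage points, the upper range of reported
    cluster effects.
    """
    if n_cpgs < 120:
        return []
    return [
        (10, (2, 6), 0.5), (25, (1, 2), 0.6), (40, (2, 3), -0.5),
        (55, (3, 6), 0.8), (70, (1, 6), -0.6), (85, (2, 5), 0.4),
        (100, (4, 6), 0.7), (115, (1, 3), -0.4),
    ]


def default_taxon_links(n_cpgs: int) -> list[tuple[int, str, float]]:
    """Taxon-methylation links: (cpg index, genus, slope per centered log RA)."""
    if n_cpgs < 260:
        return []
    return [
        (130, "Propionibacterium", -0.4), (150, "Propionibacterium", -0.35),
        (170, "Propionibacterium", -0.3), (190, "Moraxella", 0.3),
        (210, "Peptoniphilus", -0.25), (230, "Corynebacterium", -0.3),
    ]


@dataclass
class CohortParams:
    """All knobs of the synthetic cohort.

    The microbiome side defaults to the six-archetype structure above at
    Dirichlet concentration 50 (within-cluster dispersion is a modelling
    choice; the source tables report none) and library depths log-uniform
    on 10k-50k reads. The methylation side plants cluster effects, taxon
    links, one latent cell factor loading on 20% of CpGs, and a linear
    clock over ``clock_sites`` dedicated CpGs.
    """

    n_samples: int = 372
    cluster_weights: tuple[float, ...] = DEFAULT_CLUSTER_WEIGHTS
    dominant_ra: tuple[dict[str, float], ...] = DEFAULT_ARCHETYPES
    dirichlet_concentration: float = 50.0
    depth_range: tuple[int, int] = (10_000, 50_000)
    n_cpgs: int = 2000
    planted_dmps: list[tuple[int, tuple[int, int], float]] | None = None
    taxon_links: list[tuple[int, str, float]] | None = None
    clock_sites: int = 30
    ead_taxon_effect: tuple[str, float] | None = ("Corynebacterium", -0.5)
    seed: int = 0
    # noise / nuisance structure
    background_fraction: float = BACKGROUND_FRACTION
    m_noise_sd: float = 0.3
    cell_factor_fraction: float = 0.2
    cell_factor_sd: float = 0.4
    ead_noise_sd: float = 3.5

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        w = np.asarray(self.cluster_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("cluster_weights must be non-negative and sum to 1")
        if len(self.dominant_ra) != len(self.cluster_weights):
            raise ValueError("one archetype profile per cluster weight required")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth_range")
        if self.planted_dmps is None:
            self.planted_dmps = default_planted_dmps(self.n_cpgs)
        if self.taxon_links is None:
            self.taxon_links = default_taxon_links(self.n_cpgs)
        for idx, pair, dm in self.planted_dmps:
            if not 0 <= idx < self.n_cpgs:
                raise ValueError(f"planted CpG index {idx} out of range")
            if not np.isfinite(dm):
                raise ValueError("planted delta-M must be finite")
            if len(pair) != 2:
                raise ValueError("contrast pair must have two cluster ids")
        for idx, genus, slope in self.taxon_links:
            if not 0 <= idx < self.n_cpgs:
                raise ValueError(f"taxon-link CpG index {idx} out of range")
        if self.clock_sites > self.n_cpgs:
            raise ValueError("clock_sites exceeds n_cpgs")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_weights)

    def child_seeds(self) -> dict[str, np.random.SeedSequence]:
        """Deterministic per-stage seed streams derived from the cohort seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("covariates", "labels", "counts", "methylation", "clock")
        return dict(zip(names, ss.spawn(len(names))))


@dataclass
class SyntheticTruth:
    """Planted-effect record: the oracle for recovery tests."""

    true_labels: np.ndarray
    dmp_table: pd.DataFrame  # cpg, cluster_a, cluster_b, delta_m, delta_beta
    taxon_link_table: pd.DataFrame  # cpg, genus, slope
    clock: ClockDefinition | None = None
    ead_effects: tuple[str, float] | None = None
    cell_factor: pd.Series | None = None


@dataclass
class SyntheticCohort:
    covariates: pd.DataFrame
    counts: CountMatrix
    meth: MethylationMatrix
    clock: ClockDefinition
    truth: SyntheticTruth
    params: CohortParams


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="sample_id")


def _cpg_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:07d}" for i in range(1, n + 1)], name="cpg_id")


def generate_covariates(params: CohortParams,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample-level covariates matching the cohort's descriptive moments.

    sex ~ Bernoulli(0.51); age ~ Normal(13.0, 0.7) years; BMI z-score ~
    Normal(0.44, 1.10); race/ethnicity categorical at the reported
    proportions; maternal education (college+) ~ Bernoulli(0.69);
    collection day-of-year uniform on 1..365; 16S batch categorical with
    4 levels.
    """
    if rng is None:
        rng = np.random.default_rng(params.child_seeds()["covariates"])
    n = params.n_samples
    cov = pd.DataFrame(
        {
            "sex": rng.binomial(1, 0.51, n),
            "age": rng.normal(13.0, 0.7, n),
            "bmi_z": rng.normal(0.44, 1.10, n),
            "race": rng.choice(RACE_LEVELS, size=n, p=RACE_PROPS),
            "education": rng.binomial(1, 0.69, n),
            "day_of_year": rng.integers(1, 366, n),
            "batch": rng.choice([f"B{i}" for i in range(1, 5)], size=n),
        },
        index=_sample_ids(n),
    )
    return cov


def _taxonomy_frame() -> pd.DataFrame:
    rows = {}
    for name, (phylum, cls, order, family, genus) in _TAXA.items():
        rows[name] = {
            "kingdom": "Bacteria", "phylum": phylum, "class": cls,
            "order": order, "family": family, "genus": genus,
        }
    tax = pd.DataFrame(rows).T[TAXONOMY_RANKS]
    tax.index.name = "taxon_id"
    return tax


def generate_otu_counts(
    cov: pd.DataFrame,
    params: CohortParams,
    rng: np.random.Generator | None = None,
    label_rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, np.ndarray]:
    """Dirichlet-multinomial genus counts with archetype-driven clusters.

    Each sample draws a cluster per the cohort weights, genus proportions
    from Dirichlet(concentration x archetype), a library depth log-
    uniformly from ``depth_range``, and counts from the multinomial.
    """
    seeds = params.child_seeds()
    if rng is None:
        rng = np.random.default_rng(seeds["counts"])
    if label_rng is None:
        label_rng = np.random.default_rng(seeds["labels"])
    n = len(cov)
    k = params.n_clusters
    labels = label_rng.choice(np.arange(1, k + 1), size=n,
                              p=np.asarray(params.cluster_weights))

    profiles = np.zeros((k, len(GENERA)))
    for c, arch in enumerate(params.dominant_ra):
        for g, v in arch.items():
            profiles[c, GENERA.index(g)] = v
        total = profiles[c].sum()
        if total <= 0:
            raise ValueError("archetype profile must have positive mass")
        profiles[c] /= total
        unlisted = profiles[c] == 0
        if params.background_fraction > 0 and unlisted.any():
            profiles[c] *= 1.0 - params.background_fraction
            profiles[c, unlisted] = params.background_fraction / unlisted.sum()

    lo, hi = params.depth_range
    depths = np.exp(rng.uniform(np.log(lo), np.log(hi + 1), size=n)).astype(int)
    depths = np.clip(depths, lo, hi)

    counts = np.zeros((len(GENERA), n), dtype=np.int64)
    conc = params.dirichlet_concentration
    for j in range(n):
        alpha = conc * profiles[labels[j] - 1]
        gam = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
        gam[alpha <= 0] = 0.0
        props = gam / gam.sum()
        counts[:, j] = rng.multinomial(depths[j], props)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(GENERA, name="taxon_id"),
                     columns=cov.index),
        _taxonomy_frame(),
    )
    return cm, labels


def _centered_log_ra(counts: CountMatrix, genus: str) -> np.ndarray:
    ra = counts.counts.loc[genus] / counts.library_sizes()
    x = np.log(ra.to_numpy(dtype=float) + LOG_RA_FLOOR)
    return x - x.mean()


def generate_methylation(
    cov: pd.DataFrame,
    labels: np.ndarray,
    counts: CountMatrix,
    params: CohortParams,
    rng: np.random.Generator | None = None,
) -> tuple[MethylationMatrix, SyntheticTruth]:
    """Beta matrix with planted cluster / taxon / cell-factor structure.

    Per-CpG baseline mean M comes from a hypo/hemi/hyper mixture; each
    sample's M adds the planted cluster shift (applied to the first
    cluster of its contrast pair), taxon-link slopes times centered log
    relative abundance, a latent cell-composition factor loading on a
    random 20% of CpGs, and Normal noise. Beta = logistic2(M) is strictly
    inside (0,1). Planted and clock CpGs are forced hemi-methylated
    (baseline M = 0) so Beta-scale effects are interpretable.
    """
    if rng is None:
        rng = np.random.default_rng(params.child_seeds()["methylation"])
    n = len(cov)
    if len(labels) != n:
        raise ValueError("labels must align with covariates")
    c = params.n_cpgs
    clock_idx = np.arange(c - params.clock_sites, c)
    special = {idx for idx, _, _ in params.planted_dmps}
    special |= {idx for idx, _, _ in params.taxon_links}
    if special & set(clock_idx.tolist()):
        raise ValueError("planted effects collide with clock CpGs")

    comp = rng.choice(3, size=c, p=(0.35, 0.20, 0.45))
    means = np.array([-3.0, 0.0, 3.0])[comp] + rng.normal(0, 0.4, c)
    for idx, _, _ in params.planted_dmps:
        means[idx] = 0.0
    for idx, _, _ in params.taxon_links:
        means[idx] = 0.0

    M = means[:, None] + rng.normal(0.0, params.m_noise_sd, (c, n))

    dmp_rows = []
    for idx, (a, b), dm in params.planted_dmps:
        M[idx, labels == a] += dm
        dmp_rows.append(
            {"cpg": idx, "cluster_a": a, "cluster_b": b, "delta_m": dm,
             "delta_beta": float(delta_m_to_delta_beta(means[idx], dm))}
        )

    link_rows = []
    for idx, genus, slope in params.taxon_links:
        if genus not in counts.taxon_ids:
            raise ValueError(f"linked genus {genus!r} absent from counts")
        x = _centered_log_ra(counts, genus)
        M[idx] += slope * x
        link_rows.append({"cpg": idx, "genus": genus, "slope": slope})

    factor = rng.normal(0.0, 1.0, n)
    n_loaded = int(round(params.cell_factor_fraction * c))
    loaded = rng.choice(c, size=n_loaded, replace=False)
    loadings = np.zeros(c)
    loadings[loaded] = rng.normal(0.0, params.cell_factor_sd, n_loaded)
    M += loadings[:, None] * factor[None, :]

    M = np.clip(M, -50.0, 50.0)
    cpgs = _cpg_ids(c)
    beta = pd.DataFrame(m_to_beta(M), index=cpgs, columns=cov.index)
    ann = pd.DataFrame(
        {
            "chromosome": rng.integers(1, 23, c).astype(str),
            "position": rng.integers(1, 240_000_000, c),
            "gene": "",
        },
        index=cpgs,
    )
    dmp_table = pd.DataFrame(dmp_rows, columns=["cpg", "cluster_a", "cluster_b",
                                                "delta_m", "delta_beta"])
    if len(dmp_table):
        dmp_table["cpg"] = cpgs[dmp_table["cpg"].to_numpy(dtype=int)]
    link_table = pd.DataFrame(link_rows, columns=["cpg", "genus", "slope"])
    if len(link_table):
        link_table["cpg"] = cpgs[link_table["cpg"].to_numpy(dtype=int)]
    truth = SyntheticTruth(
        true_labels=np.asarray(labels),
        dmp_table=dmp_table,
        taxon_link_table=link_table,
        ead_effects=params.ead_taxon_effect,
        cell_factor=pd.Series(factor, index=cov.index, name="cell_factor"),
    )
    return MethylationMatrix(beta, "beta", ann), truth


def generate_clock_definition(
    cov: pd.DataFrame,
    counts: CountMatrix,
    meth: MethylationMatrix,
    params: CohortParams,
    rng: np.random.Generator | None = None,
) -> tuple[ClockDefinition, MethylationMatrix]:
    """Build a linear clock and inject consistent signal into the Beta matrix.

    Target epigenetic ages are chronological age + Normal(0, ead_noise_sd)
    + the planted taxon effect (slope x centered log relative abundance of
    the named genus). The dedicated clock CpGs are overwritten with Beta
    profiles linear in the transformed target age, and weights/intercept
    are solved so that applying the clock reproduces the targets exactly.
    """
    if params.clock_sites < 0:
        raise ValueError("clock_sites must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.child_seeds()["clock"])
    n = len(cov)
    age = cov["age"].to_numpy(dtype=float)
    target = age + rng.normal(0.0, params.ead_noise_sd, n)
    if params.ead_taxon_effect is not None:
        genus, slope = params.ead_taxon_effect
        if genus not in counts.taxon_ids:
            raise ValueError(f"EAD-effect genus {genus!r} absent from counts")
        target = target + slope * _centered_log_ra(counts, genus)
    target = np.maximum(target, 0.1)  # ages must be positive for the transform
    L = age_transform(target, adult_age=20.0)

    beta = meth.values.copy()
    s = params.clock_sites
    if s == 0:
        clock = ClockDefinition(float(L.mean()), pd.Series(dtype=float))
        return clock, MethylationMatrix(beta, "beta", meth.annotation)

    sites = beta.index[-s:]
    b0 = float(np.ptp(L))
    if b0 == 0:  # constant target: intercept-only clock
        clock = ClockDefinition(float(L[0]), pd.Series(0.0, index=sites))
        return clock, MethylationMatrix(beta, "beta", meth.annotation)
    t = (L - L.min()) / b0  # in [0, 1]

    c_i = rng.uniform(0.35, 0.60, s)
    r_i = rng.uniform(0.05, 0.25, s)
    w = rng.uniform(0.5, 1.5, s)
    w *= b0 / float(w @ r_i)
    intercept = float(L.min() - w @ c_i)

    beta.loc[sites] = c_i[:, None] + r_i[:, None] * t[None, :]
    clock = ClockDefinition(intercept, pd.Series(w, index=sites), adult_age=20.0)
    return clock, MethylationMatrix(beta, "beta", meth.annotation)


def generate_cohort(params: CohortParams | None = None, **kwargs) -> SyntheticCohort:
    """End-to-end cohort: covariates, counts, methylation, clock, truth."""
    if params is None:
        params = CohortParams(**kwargs)
    elif kwargs:
        params = replace(params, **kwargs)
    cov = generate_covariates(params)
    counts, labels = generate_otu_counts(cov, params)
    meth, truth = generate_methylation(cov, labels, counts, params)
    clock, meth = generate_clock_definition(cov, counts, meth, params)
    truth.clock = clock
    return SyntheticCohort(cov, counts, meth, clock, truth, params)


def write_fixture_bundle(cohort: SyntheticCohort, path: str) -> dict[str, str]:
    """Write the cohort as the plain-text bundle the pipeline readers accept.

    counts.tsv / taxonomy.tsv / beta.tsv (TSV, first column id), plus
    covariates.csv, clock.csv and truth.tsv. Floats round-trip through
    the readers to better than 1e-12; integers exactly.
    """
    if cohort.counts.n_samples == 0:
        raise ValueError("refusing to write an empty cohort")
    os.makedirs(path, exist_ok=True)
    files = {}

    def _p(name: str) -> str:
        files[name] = os.path.join(path, name)
        return files[name]

    cohort.counts.counts.to_csv(_p("counts.tsv"), sep="\t", float_format="%.17g")
    cohort.counts.taxonomy.to_csv(_p("taxonomy.tsv"), sep="\t")
    cohort.meth.values.to_csv(_p("beta.tsv"), sep="\t", float_format="%.17g")
    cohort.meth.annotation.to_csv(_p("annotation.tsv"), sep="\t")
    cohort.covariates.to_csv(_p("covariates.csv"))

    clock_rows = [("(intercept)", cohort.clock.intercept),
                  ("(adult_age)", cohort.clock.adult_age)]
    clock_rows += list(cohort.clock.weights.items())
    pd.DataFrame(clock_rows, columns=["cpg_id", "weight"]).to_csv(
        _p("clock.csv"), index=False, float_format="%.17g"
    )

    truth = cohort.truth
    with open(_p("truth.tsv"), "w") as fh:
        fh.write("record\tkey\tvalue\n")
        for sid, lab in zip(cohort.covariates.index, truth.true_labels):
            fh.write(f"label\t{sid}\t{lab}\n")
        for _, row in truth.dmp_table.iterrows():
            fh.write(
                f"dmp\t{row['cpg']}\t{row['cluster_a']}|{row['cluster_b']}|"
                f"{row['delta_m']!r}|{row['delta_beta']!r}\n"
            )
        for _, row in truth.taxon_link_table.iterrows():
            fh.write(f"taxon_link\t{row['cpg']}\t{row['genus']}|{row['slope']!r}\n")
        if truth.ead_effects is not None:
            fh.write(f"ead_effect\t{truth.ead_effects[0]}\t{truth.ead_effects[1]!r}\n")
    return files
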