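"""End-to-end orchestration: QC -> clustering -> EWAS -> DA -> epigenetic age.

``run_pipeline`` wires the stages together in the study's order and
writes plain-text result tables plus a JSON manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .abundance import DifferentialAbundanceModel
from .clock import EpigeneticClockModel
from .clustering import loo_stability, pairwise_distance, pam_cluster, rename_by_size, select_k
from .containers import RunManifest
from .ewas import ClusterEwas
from .io import (
    intersect_samples,
    read_beta,
    read_clock,
    read_counts,
    read_covariates,
    write_table,
)
from .methylation import as_m_matrix, genotype_group_screen, refactor_components
from .microbiome import (
    alpha_diversity,
    filter_samples_by_depth,
    iterated_rarefaction,
    merge_to_genus,
    prevalence_filter,
    to_relative_abundance,
    zero_low_abundance,
)

log = logging.getLogger("nasepi")


@dataclass
class PipelineConfig:
    """Paths, switches and the single seed that drives every random stage."""

    counts: str = ""
    taxonomy: str = ""
    beta: str = ""
    annotation: str = ""
    covariates: str = ""
    clock: str = ""
    output_dir: str = "results"
    # analysis switches
    metric: str = "jsd"
    k: int | None = 6
    k_range: tuple[int, int] = (2, 10)
    min_reads: int = 10_000
    min_copies: int = 10
    rarefaction_iterations: int = 1000
    min_prevalence: float = 0.15
    refactor_k: int = 10
    refactor_t: int = 500
    winsorize: bool = False
    moderate: bool = True
    robust: bool = True
    alpha: float = 0.05
    n_permutations: int = 500
    run_permutations: bool = True
    run_loo: bool = True
    pseudo_counts: tuple[float, ...] = (0.1, 0.5, 1.0)
    extra_covariates: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        cfg = cls(**raw)
        for key in ("k_range", "pseudo_counts", "extra_covariates"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


def run_pipeline(config: PipelineConfig) -> tuple[dict, RunManifest]:
    """Execute the full analysis and write all result tables.

    Stage order: sample/OTU QC -> alpha diversity (pre-rarefaction) ->
    iterated rarefaction -> genus merge -> beta-diversity distance ->
    PAM (k from config, or silhouette selection) -> size renaming ->
    leave-one-out stability -> ReFACTor -> EWAS with all pairwise
    contrasts and inflation -> winsorized sensitivity re-run ->
    permutation null -> differential abundance for the DMPs ->
    clock / EAD -> EAD cluster contrasts and taxa associations.
    """
    manifest = RunManifest(config=asdict(config), version=__version__,
                           seeds={"root": config.seed})
    ss = np.random.SeedSequence(config.seed)
    rare_seed, perm_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    manifest.seeds.update({"rarefaction": rare_seed, "permutation": perm_seed})

    if config.clock and not os.path.exists(config.clock):
        raise FileNotFoundError(f"clock file not found: {config.clock}")

    counts = read_counts(config.counts, config.taxonomy or None)
    meth = read_beta(config.beta, config.annotation or None)
    cov = read_covariates(config.covariates)
    counts, meth, cov = intersect_samples(counts, meth, cov)
    manifest.log_stage("read_inputs", n_samples=counts.n_samples,
                       n_taxa=counts.n_taxa, n_cpgs=meth.n_cpgs)

    # --- microbiome prep -------------------------------------------------
    counts = filter_samples_by_depth(counts, config.min_reads)
    counts = zero_low_abundance(counts, config.min_copies)
    meth = meth.subset_samples(counts.sample_ids)
    cov = cov.loc[counts.sample_ids]
    alpha = alpha_diversity(counts)
    rare = iterated_rarefaction(counts, config.rarefaction_iterations, rare_seed)
    genus = merge_to_genus(rare)
    ra = to_relative_abundance(genus)
    manifest.log_stage("microbiome_prep", n_samples=counts.n_samples,
                       n_genera=genus.n_taxa)

    # --- clustering -------------------------------------------------------
    dist = pairwise_distance(ra, config.metric)
    krange = range(config.k_range[0], config.k_range[1] + 1)
    ksel = select_k(dist, krange)
    k = config.k if config.k is not None else ksel.chosen_k
    sol = rename_by_size(pam_cluster(dist, k))
    labels = sol.labels
    stability = loo_stability(dist, sol, krange) if config.run_loo else None
    manifest.log_stage("clustering", k=k, chosen_k=ksel.chosen_k,
                       sizes=sol.sizes().tolist())

    # --- EWAS -------------------------------------------------------------
    refactor = refactor_components(
        meth.values, config.refactor_k, min(config.refactor_t, meth.n_cpgs)
    )
    extra = None
    if config.extra_covariates:
        extra = cov[list(config.extra_covariates)]
    model = ClusterEwas(meth, labels, cov, refactor, extra,
                        winsorize=config.winsorize)
    res = model.fit(robust=config.robust, moderate=config.moderate,
                    alpha=config.alpha)
    try:
        inflation = res.inflation()
    except ValueError:  # too few tests per contrast for stable estimates
        inflation = None
        log.warning("skipping inflation report: too few tests per contrast")
    manifest.thresholds["bonferroni_raw_p"] = res.threshold
    manifest.log_stage("ewas", n_dmps=len(res.dmp_cpgs()),
                       n_contrasts=res.n_contrasts)

    wins_model = ClusterEwas(meth, labels, cov, refactor, extra, winsorize=True)
    wins_res = wins_model.fit(robust=config.robust, moderate=config.moderate,
                              alpha=config.alpha)
    manifest.log_stage("ewas_winsorized", n_dmps=len(wins_res.dmp_cpgs()))

    permutation = None
    if config.run_permutations:
        permutation = res.permutation_null(config.n_permutations, perm_seed,
                                           robust=config.robust,
                                           moderate=config.moderate)
        manifest.log_stage("permutation_null",
                           observed=permutation.observed_dmps,
                           empirical_p=permutation.empirical_p)

    # --- differential abundance over DMPs ---------------------------------
    da_counts = prevalence_filter(merge_to_genus(counts), config.min_prevalence)
    cov_design = model.design.drop(
        columns=[c for c in model.design.columns if str(c).startswith("cluster")]
    )
    da_model = DifferentialAbundanceModel(da_counts, cov_design,
                                          config.pseudo_counts, config.alpha)
    m_vals = as_m_matrix(meth).values
    da_table = da_model.fit_dmps(m_vals, res.dmp_cpgs())
    manifest.log_stage("differential_abundance", n_taxa=da_counts.n_taxa,
                       n_dmps=len(res.dmp_cpgs()))

    # meQTL-style screen: discrete methylation groups vs cluster labels
    screen_rows = []
    for cpg in res.dmp_cpgs():
        scr = genotype_group_screen(meth.values.loc[cpg].to_numpy(), labels, 2)
        if scr.skipped:
            continue
        screen_rows.append(
            {"cpg": cpg, "center_low": scr.centers[0], "center_high": scr.centers[1],
             "chi2": scr.chi2, "df": scr.df, "p": scr.p,
             "low_expected_cells": scr.low_expected}
        )
    meqtl_screen = pd.DataFrame(
        screen_rows, columns=["cpg", "center_low", "center_high", "chi2", "df",
                              "p", "low_expected_cells"]
    )
    manifest.log_stage("meqtl_screen", n_screened=len(meqtl_screen))

    # --- epigenetic age ----------------------------------------------------
    ead_results = None
    ead_contrasts = None
    ead_taxa = None
    if config.clock:
        clock = read_clock(config.clock)
        clk_model = EpigeneticClockModel(meth, clock, cov["age"])
        ead_results = clk_model.fit()
        ead_cov = cov_design.drop(
            columns=[c for c in cov_design.columns if str(c).startswith("RC")],
            errors="ignore",
        )
        ead_contrasts = ead_results.cluster_contrasts(labels, ead_cov)
        ead_taxa = ead_results.taxa_association(
            da_counts, cov_design, config.pseudo_counts, config.alpha
        )
        manifest.log_stage("epigenetic_age", r=ead_results.pearson_r,
                           mae=ead_results.median_abs_error)

    bundle = {
        "labels": sol.as_series(),
        "k_selection": ksel.as_frame(),
        "stability": None if stability is None else stability.as_frame(),
        "alpha_diversity": alpha.table,
        "ewas": res,
        "ewas_winsorized": wins_res,
        "inflation": inflation,
        "permutation": permutation,
        "da": da_table,
        "meqtl_screen": meqtl_screen,
        "ead": ead_results,
        "ead_contrasts": ead_contrasts,
        "ead_taxa": ead_taxa,
    }
    write_results(bundle, config.output_dir, manifest)
    return bundle, manifest


def write_results(bundle: dict, outdir: str, manifest: RunManifest) -> None:
    os.makedirs(outdir, exist_ok=True)

    def _path(name: str) -> str:
        return os.path.join(outdir, name)

    write_table(bundle["labels"].rename_axis("sample").reset_index(),
                _path("cluster_assignments.tsv"))
    write_table(bundle["k_selection"], _path("k_selection.tsv"))
    if bundle["stability"] is not None:
        write_table(bundle["stability"], _path("loo_stability.tsv"))
    write_table(bundle["alpha_diversity"].rename_axis("sample").reset_index(),
                _path("alpha_diversity.tsv"))

    res = bundle["ewas"]
    write_table(res.results_table(), _path("ewas_contrasts.tsv"))
    write_table(bundle["ewas_winsorized"].dmps(), _path("ewas_winsorized_dmps.tsv"))
    if bundle["inflation"] is not None:
        write_table(bundle["inflation"].rename_axis("contrast").reset_index(),
                    _path("inflation.tsv"))
    if bundle["permutation"] is not None:
        perm = bundle["permutation"]
        write_table(
            pd.DataFrame(
                {
                    "observed_dmps": [perm.observed_dmps],
                    "n_permutations": [perm.n_permutations],
                    "max_permuted": [int(perm.permuted_dmps.max())],
                    "empirical_p": [perm.empirical_p],
                }
            ),
            _path("permutation_summary.tsv"),
        )
    write_table(bundle["da"], _path("differential_abundance.tsv"))
    write_table(bundle["meqtl_screen"], _path("meqtl_screen.tsv"))
    if bundle["ead"] is not None:
        ead = bundle["ead"]
        tab = pd.DataFrame(
            {"epigenetic_age": ead.epi_age, "ead": ead.ead}
        ).rename_axis("sample").reset_index()
        write_table(tab, _path("epigenetic_age.tsv"))
        write_table(bundle["ead_contrasts"], _path("ead_cluster_contrasts.tsv"))
        write_table(
            bundle["ead_taxa"].rename_axis("genus").reset_index(),
            _path("ead_taxa_associations.tsv"),
        )

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(
            {
                "config": manifest.config,
                "version": manifest.version,
                "seeds": manifest.seeds,
                "stages": manifest.stages,
                "thresholds": manifest.thresholds,
            },
            fh,
            indent=2,
            default=str,
        )
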