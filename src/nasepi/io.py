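"""Plain-text readers and writers for the pipeline's inputs and outputs.

Counts and Beta matrices are TSV with the row id in the first column and
sample ids in the header; covariates are CSV; the clock is a two-column
CSV with reserved ``(intercept)`` / ``(adult_age)`` rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .clock import ClockDefinition
from .containers import CountMatrix, MethylationMatrix

log = logging.getLogger("nasepi")


def read_counts(counts_path: str, taxonomy_path: str | None = None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    vals = counts.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("count table must contain integers")
    counts = counts.round().astype(np.int64)
    tax = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, keep_default_na=False)
    return CountMatrix(counts, tax)


def read_beta(beta_path: str, annotation_path: str | None = None) -> MethylationMatrix:
    beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    vals = beta.to_numpy()
    bad = np.argwhere((vals <= 0) | (vals >= 1) | ~np.isfinite(vals))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"beta value out of (0,1) at ({beta.index[i]}, {beta.columns[j]})"
        )
    ann = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0, keep_default_na=False)
    return MethylationMatrix(beta, "beta", ann)


def read_covariates(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_clock(path: str) -> ClockDefinition:
    tab = pd.read_csv(path)
    tab.columns = [c.strip() for c in tab.columns]
    ids = tab.iloc[:, 0].astype(str)
    vals = tab.iloc[:, 1].astype(float)
    intercept = 0.0
    adult_age = 20.0
    weights = {}
    for cpg, w in zip(ids, vals):
        if cpg == "(intercept)":
            intercept = float(w)
        elif cpg == "(adult_age)":
            adult_age = float(w)
        else:
            weights[cpg] = float(w)
    return ClockDefinition(intercept, pd.Series(weights, dtype=float), adult_age)


def intersect_samples(
    counts: CountMatrix, meth: MethylationMatrix, cov: pd.DataFrame
) -> tuple[CountMatrix, MethylationMatrix, pd.DataFrame]:
    """Align the three inputs on their common samples (order of the counts).

    Non-overlapping samples are dropped with a logged report; an empty
    intersection is an error.
    """
    common = counts.sample_ids
    common = common[common.isin(meth.sample_ids) & common.isin(cov.index)]
    if len(common) == 0:
        raise ValueError("no samples shared across counts, methylation, covariates")
    dropped = (
        (counts.n_samples - len(common)),
        (meth.values.shape[1] - len(common)),
        (len(cov) - len(common)),
    )
    if any(dropped):
        log.info(
            "sample intersection kept %d samples (dropped: counts %d, "
            "methylation %d, covariates %d)", len(common), *dropped
        )
    return (
        counts.subset_samples(common),
        meth.subset_samples(common),
        cov.loc[common],
    )


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> str:
    """Write a result table as TSV with stable %.6g numeric formatting."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return path
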