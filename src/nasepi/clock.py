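"""Linear epigenetic clock, age transform, and epigenetic age deviation.

The clock is a caller-supplied linear predictor over CpG Beta-values
with the pan-tissue age transform: ages at or below ``adult_age`` are
log-compressed during training, so the inverse transform applied to the
linear predictor L is (adult_age + 1) * exp(L) - 1 for L < 0 and
(adult_age + 1) * L + adult_age otherwise. Epigenetic age deviation
(EAD) is the residual of regressing epigenetic age on chronological age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import pseudocount_sensitivity
from .containers import CountMatrix, MethylationMatrix


@dataclass
class ClockDefinition:
    """Linear clock: intercept + sum(weight_i * beta_i), plus the age knot."""

    intercept: float
    weights: pd.Series  # indexed by CpG id
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not isinstance(self.weights, pd.Series):
            self.weights = pd.Series(self.weights, dtype=float)
        self.weights = self.weights.astype(float)


def age_transform(age: np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Forward transform used in clock training: log-linear with a knot."""
    age = np.asarray(age, dtype=float)
    return np.where(
        age <= adult_age,
        np.log(age + 1.0) - np.log(adult_age + 1.0),
        (age - adult_age) / (adult_age + 1.0),
    )


def inverse_age_transform(l: np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Inverse of :func:`age_transform`: exp branch below the knot."""
    l = np.asarray(l, dtype=float)
    return np.where(
        l < 0,
        (adult_age + 1.0) * np.exp(l) - 1.0,
        (adult_age + 1.0) * l + adult_age,
    )


def apply_clock(beta: pd.DataFrame, clock: ClockDefinition,
                min_coverage: float = 0.8) -> pd.Series:
    """Epigenetic age per sample from a Beta matrix and a clock definition.

    At least ``min_coverage`` of the clock's weighted CpGs must be present
    in the matrix; the remainder are imputed with the cohort mean of the
    available sites' Beta distribution — per-site imputation is impossible
    for an absent site, so missing sites contribute their weight times the
    cohort-wide mean Beta (logged via a warning).
    """
    w = clock.weights
    present = w.index.intersection(beta.index)
    if len(w) > 0 and len(present) < min_coverage * len(w):
        raise ValueError(
            f"only {len(present)}/{len(w)} clock CpGs present (< {min_coverage:.0%})"
        )
    lin = np.full(beta.shape[1], clock.intercept, dtype=float)
    if len(present):
        sub = beta.loc[present]
        lin += w.loc[present].to_numpy() @ sub.to_numpy()
    missing = w.index.difference(beta.index)
    if len(missing):
        warnings.warn(f"{len(missing)} clock CpGs missing; imputed with cohort mean")
        lin += float(w.loc[missing].sum()) * float(beta.to_numpy().mean())
    ages = inverse_age_transform(lin, clock.adult_age)
    return pd.Series(ages, index=beta.columns, name="epigenetic_age")


def compute_ead(epi_age: np.ndarray | pd.Series,
                chron_age: np.ndarray | pd.Series) -> np.ndarray:
    """Epigenetic age deviation: least-squares residuals of epi on chron age."""
    y = np.asarray(epi_age, dtype=float)
    x = np.asarray(chron_age, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("chronological age is constant")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def ead_cluster_contrasts(
    ead: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All pairwise cluster differences in adjusted mean EAD.

    Least-squares fit of EAD on cell-means cluster indicators plus
    covariates; every pairwise coefficient difference is reported with a
    t-based p-value (marginal-means contrasts of a no-interaction model).
    """
    ead = np.asarray(ead, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if any((labels == u).sum() == 0 for u in uniq) or len(uniq) < 2:
        raise ValueError("need at least two nonempty clusters")
    n = ead.size
    cols = [(labels == u).astype(float) for u in uniq]
    if covariates is not None:
        Z = covariates.to_numpy(dtype=float)
        cols.extend(Z.T)
    X = np.column_stack(cols)
    p = X.shape[1]
    if n <= p:
        raise ValueError("too few samples for the design")
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ ead
    resid = ead - X @ coef
    s2 = float(resid @ resid) / (n - p)

    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            c = np.zeros(p)
            c[i], c[j] = 1.0, -1.0
            est = float(c @ coef)
            se = float(np.sqrt(s2 * c @ XtX_inv @ c))
            t = est / se if se > 0 else 0.0
            pval = 2.0 * stats.t.sf(abs(t), df=n - p)
            rows.append(
                {"contrast": f"{uniq[i]}_vs_{uniq[j]}", "estimate": est,
                 "se": se, "t": t, "p": pval}
            )
    return pd.DataFrame(rows)


def ead_taxa_association(
    counts: CountMatrix,
    ead: np.ndarray,
    covariates: pd.DataFrame | None = None,
    pseudo_counts: tuple[float, ...] = (0.1, 0.5, 1.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genus-level differential abundance against EAD in years.

    Delegates to the bias-corrected log-linear model with EAD as the
    exposure, left in year units (logFC per year of age deviation), with
    BH across taxa and the pseudo-count sensitivity flags.
    """
    ead = np.asarray(ead, dtype=float)
    if np.ptp(ead) == 0:
        raise ValueError("EAD exposure is constant")
    return pseudocount_sensitivity(
        counts, ead, covariates, pseudo_counts, alpha=alpha
    )


@dataclass
class EpigeneticClockModel:
    """Clock application + EAD association analyses as a model object."""

    beta: MethylationMatrix
    clock: ClockDefinition
    chron_age: pd.Series

    def fit(self) -> "EpiAgeResults":
        b = self.beta.values if self.beta.scale == "beta" else None
        if b is None:
            from .methylation import as_beta_matrix

            b = as_beta_matrix(self.beta).values
        epi = apply_clock(b, self.clock)
        chron = self.chron_age.loc[epi.index].to_numpy()
        ead = compute_ead(epi.to_numpy(), chron)
        r = float(np.corrcoef(epi.to_numpy(), chron)[0, 1]) if np.ptp(chron) else np.nan
        mae = float(np.median(np.abs(epi.to_numpy() - chron)))
        return EpiAgeResults(
            epi_age=epi,
            ead=pd.Series(ead, index=epi.index, name="ead"),
            pearson_r=r,
            median_abs_error=mae,
            model=self,
        )


@dataclass
class EpiAgeResults:
    epi_age: pd.Series
    ead: pd.Series
    pearson_r: float
    median_abs_error: float
    model: EpigeneticClockModel
    extras: dict = field(default_factory=dict)

    def cluster_contrasts(self, labels, covariates=None) -> pd.DataFrame:
        return ead_cluster_contrasts(self.ead.to_numpy(), labels, covariates)

    def taxa_association(self, counts: CountMatrix, covariates=None,
                         pseudo_counts=(0.1, 0.5, 1.0), alpha=0.05) -> pd.DataFrame:
        return ead_taxa_association(
            counts, self.ead.to_numpy(), covariates, pseudo_counts, alpha
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Epigenetic clock / age deviation",
                f"  samples:              {len(self.epi_age)}",
                f"  clock CpGs:           {len(self.model.clock.weights)}",
                f"  Pearson r (epi~chron): {self.pearson_r:.3f}",
                f"  median abs error:      {self.median_abs_error:.2f} years",
                f"  EAD mean (residuals):  {self.ead.mean():.2e} years",
            ]
        )
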