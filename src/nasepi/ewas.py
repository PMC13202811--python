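"""Multi-group EWAS: design construction, robust per-CpG regression,
empirical-Bayes variance moderation, all pairwise cluster contrasts,
global multiple-testing decisions, inflation diagnostics and the
permutation empirical null.

Methylation M-values are regressed on cell-means cluster indicators plus
covariates (sex, age, BMI z-score, race/ethnicity, maternal education,
annual + biannual season harmonics, assay batch, and reference-free
cell-composition components). Cluster differences are tested through a
contrast matrix over the cell-means coefficients; the family-wise
correction is Bonferroni over CpGs x contrasts. An optional
empirical-Bayes step shrinks per-CpG residual variances toward a common
prior, as in moderated-t pipelines.

The per-CpG robust fit is Huber IRLS vectorised across CpGs: every
iteration solves all weighted normal equations in one batched call, so
permutation re-runs of the full EWAS stay cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import MethylationMatrix, PermutationResult, RefactorComponents
from .methylation import as_m_matrix, delta_m_to_delta_beta, winsorize_m

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def cluster_indicators(labels: np.ndarray, prefix: str = "cluster") -> pd.DataFrame:
    """Cell-means coding: one indicator column per cluster, no intercept."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    cols = {f"{prefix}{u}": (labels == u).astype(float) for u in uniq}
    return pd.DataFrame(cols)


def season_harmonics(day_of_year: np.ndarray, harmonics: int = 2) -> pd.DataFrame:
    """Sine/cosine terms for annual (and biannual) seasonal trends."""
    d = np.asarray(day_of_year, dtype=float)
    out = {}
    for h in range(1, harmonics + 1):
        w = 2.0 * np.pi * h * d / DAYS_PER_YEAR
        out[f"season_sin{h}"] = np.sin(w)
        out[f"season_cos{h}"] = np.cos(w)
    return pd.DataFrame(out)


def build_design(
    covariates: pd.DataFrame,
    labels: np.ndarray,
    refactor: RefactorComponents | None = None,
    extra: pd.DataFrame | pd.Series | None = None,
    harmonics: int = 2,
) -> pd.DataFrame:
    """Assemble the EWAS design matrix (samples x predictors).

    Expected covariate columns: sex (0/1), age, bmi_z, race (categorical),
    education (0/1), day_of_year, batch (categorical). Clusters are
    cell-means coded (no intercept); categorical covariates are one-hot
    with the first (sorted) level dropped as reference. The matrix is
    checked for full column rank.
    """
    cov = covariates
    n = len(cov)
    if len(labels) != n:
        raise ValueError("labels and covariates must align on samples")
    parts = [cluster_indicators(labels).set_index(cov.index)]

    numeric = pd.DataFrame(index=cov.index)
    for col in ("sex", "age", "bmi_z", "education"):
        if col in cov.columns:
            numeric[col] = pd.to_numeric(cov[col])
    parts.append(numeric)

    for col in ("race", "batch"):
        if col in cov.columns:
            dummies = pd.get_dummies(cov[col].astype(str), prefix=col, dtype=float)
            dummies = dummies[sorted(dummies.columns)]
            parts.append(dummies.iloc[:, 1:])  # drop reference level

    if "day_of_year" in cov.columns:
        parts.append(
            season_harmonics(cov["day_of_year"].to_numpy(), harmonics).set_index(
                cov.index
            )
        )

    if refactor is not None:
        parts.append(refactor.scores.loc[cov.index])

    if extra is not None:
        if isinstance(extra, pd.Series):
            extra = extra.to_frame()
        parts.append(extra.loc[cov.index].astype(float))

    X = pd.concat(parts, axis=1).astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    return X


# ---------------------------------------------------------------------------
# robust fit
# ---------------------------------------------------------------------------

@dataclass
class EwasFit:
    """Per-CpG regression state shared by contrast and permutation steps."""

    coef: np.ndarray  # (n_cpgs, p)
    cov_unscaled: np.ndarray  # (n_cpgs, p, p) inverse weighted normal matrices
    s2: np.ndarray  # (n_cpgs,) residual variances
    df: float  # residual degrees of freedom, n - p
    mean_m: np.ndarray  # (n_cpgs,) per-CpG mean M
    cpg_ids: pd.Index
    columns: pd.Index
    converged: np.ndarray | None = None
    # moderation state
    moderated: bool = False
    d0: float = np.inf
    s02: float = np.nan
    s2_post: np.ndarray | None = None

    @property
    def s2_used(self) -> np.ndarray:
        return self.s2_post if self.moderated else self.s2

    @property
    def df_total(self) -> float:
        return self.df + self.d0 if self.moderated else self.df


def _irls_huber(
    Y: np.ndarray, X: np.ndarray, huber_c: float, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched Huber IRLS. Returns (coef, cov_unscaled, weighted s2, converged)."""
    c, n = Y.shape
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T
    W = np.ones_like(Y)
    converged = np.zeros(c, dtype=bool)
    active = np.arange(c)
    for _ in range(max_iter):
        Ya = Y[active]
        Ba = B[active]
        R = Ya - Ba @ X.T
        s = 1.4826 * np.median(np.abs(R), axis=1, keepdims=True)
        s = np.maximum(s, 1e-10)
        Wa = np.minimum(1.0, huber_c * s / np.maximum(np.abs(R), 1e-300))
        XtWX = np.einsum("cn,np,nq->cpq", Wa, X, X, optimize=True)
        XtWy = np.einsum("cn,np->cp", Wa * Ya, X, optimize=True)
        Bnew = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        delta = np.max(np.abs(Bnew - Ba), axis=1)
        scale = 1.0 + np.max(np.abs(Bnew), axis=1)
        done = delta < tol * scale
        B[active] = Bnew
        W[active] = Wa
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    if active.size:
        warnings.warn(
            f"{active.size} CpG fit(s) did not converge; falling back to OLS"
        )
        B[active] = Y[active] @ pinv.T
        W[active] = 1.0

    XtWX = np.einsum("cn,np,nq->cpq", W, X, X, optimize=True)
    cov_unscaled = np.linalg.inv(XtWX)
    R = Y - B @ X.T
    # Huber-weighted RSS is biased low under Gaussian errors:
    # E[min(z^2, c|z|)] = 2*Phi(c) - 1 for z ~ N(0,1); divide it out so the
    # residual variance (and hence the t statistics) stay calibrated.
    kappa = 2.0 * stats.norm.cdf(huber_c) - 1.0
    s2 = np.einsum("cn,cn->c", W, R**2) / ((n - p) * kappa)
    return B, cov_unscaled, s2, converged


def robust_fit(
    m_values: pd.DataFrame,
    X: pd.DataFrame,
    huber_c: float = 1.345,
    max_iter: int = 50,
    tol: float = 1e-8,
    robust: bool = True,
) -> EwasFit:
    """Per-CpG (robust) linear regression of M-values on the design.

    With ``robust`` the fit is iteratively reweighted least squares with
    Huber weights w = min(1, c / |r/s|) and scale s = 1.4826 x median
    absolute residual, iterated to coefficient convergence. With Normal
    errors and no outliers all |r| < c*s and the fit reduces to OLS.
    """
    Y = m_values.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if Y.shape[1] != n:
        raise ValueError("m_values columns must align with design rows")
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")

    if robust:
        B, cov_unscaled, s2, converged = _irls_huber(Y, Xv, huber_c, max_iter, tol)
    else:
        pinv = np.linalg.pinv(Xv)
        B = Y @ pinv.T
        XtX_inv = np.linalg.inv(Xv.T @ Xv)
        cov_unscaled = np.broadcast_to(XtX_inv, (Y.shape[0], p, p)).copy()
        R = Y - B @ Xv.T
        s2 = (R**2).sum(axis=1) / (n - p)
        converged = np.ones(Y.shape[0], dtype=bool)

    return EwasFit(
        coef=B,
        cov_unscaled=cov_unscaled,
        s2=s2,
        df=float(n - p),
        mean_m=Y.mean(axis=1),
        cpg_ids=m_values.index,
        columns=X.columns,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior to sample variances.

    Matches the mean and variance of log(s^2) using digamma/trigamma
    identities; returns (d0, s0^2). An excess variance of zero or less
    yields d0 = inf (all variances equal).
    """
    s2 = np.asarray(s2, dtype=float)
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess dispersion: point prior; undo the log-s2 bias so the
        # prior variance equals the common variance exactly
        s02 = float(np.exp(emean + special.digamma(df / 2.0) - np.log(df / 2.0)))
        return np.inf, s02
    d0 = 2.0 * trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def ebayes_moderate(fit: EwasFit, min_cpgs: int = 100) -> EwasFit:
    """Shrink per-CpG residual variances toward the fitted prior.

    Posterior variance (d0*s0^2 + d*s^2) / (d0 + d); downstream t
    statistics use the posterior variance with d0 + d degrees of
    freedom. Skipped (with a warning) when too few CpGs are available
    to estimate hyperparameters stably.
    """
    if len(fit.s2) < min_cpgs:
        warnings.warn(
            f"only {len(fit.s2)} CpGs; variance moderation skipped"
        )
        return fit
    d0, s02 = fit_f_dist(fit.s2, fit.df)
    if np.isinf(d0):
        s2_post = np.full_like(fit.s2, s02)
    else:
        s2_post = (d0 * s02 + fit.df * fit.s2) / (d0 + fit.df)
    fit.moderated = True
    fit.d0 = d0
    fit.s02 = s02
    fit.s2_post = s2_post
    return fit


# ---------------------------------------------------------------------------
# contrasts and significance
# ---------------------------------------------------------------------------

def make_pairwise_contrasts(columns: pd.Index, prefix: str = "cluster") -> pd.DataFrame:
    """All pairwise difference contrasts over the cell-means cluster columns."""
    cl_cols = [c for c in columns if str(c).startswith(prefix)]
    if len(cl_cols) < 2:
        raise ValueError("need at least two cluster columns for contrasts")
    C = {}
    for i in range(len(cl_cols)):
        for j in range(i + 1, len(cl_cols)):
            name = f"{cl_cols[i].replace(prefix, '')}_vs_{cl_cols[j].replace(prefix, '')}"
            vec = pd.Series(0.0, index=columns)
            vec[cl_cols[i]] = 1.0
            vec[cl_cols[j]] = -1.0
            C[name] = vec
    return pd.DataFrame(C)


def pairwise_contrasts(fit: EwasFit, contrast_matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Estimate all contrasts: long table of (cpg, contrast, dM, SE, t, p, dbeta).

    The Beta-scale effect is the logistic difference at the CpG's mean M
    (M-model-M-mean conversion), reported in percentage points.
    """
    if contrast_matrix is None:
        contrast_matrix = make_pairwise_contrasts(fit.columns)
    missing = contrast_matrix.index.difference(fit.columns)
    if len(missing):
        raise ValueError(f"contrast rows not in design: {list(missing)}")
    C = contrast_matrix.loc[fit.columns].to_numpy(dtype=float)
    names = contrast_matrix.columns

    dM = fit.coef @ C  # (c, ncon)
    var_unscaled = np.einsum("pj,cpq,qj->cj", C, fit.cov_unscaled, C, optimize=True)
    se = np.sqrt(np.maximum(var_unscaled, 0.0) * fit.s2_used[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, dM / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=fit.df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    dbeta = delta_m_to_delta_beta(fit.mean_m[:, None], dM)

    n_cpgs, n_con = dM.shape
    long = pd.DataFrame(
        {
            "cpg": np.repeat(fit.cpg_ids.to_numpy(), n_con),
            "contrast": np.tile(np.asarray(names), n_cpgs),
            "delta_m": dM.ravel(),
            "se": se.ravel(),
            "t": t.ravel(),
            "df": fit.df_total,
            "p": p.ravel(),
            "delta_beta_pct": 100.0 * dbeta.ravel(),
        }
    )
    N = n_cpgs * n_con
    long["p_bonferroni"] = np.minimum(1.0, long["p"] * N)
    long["p_fdr"] = multipletests(long["p"].to_numpy(), method="fdr_bh")[1]
    return long


def bonferroni_threshold(alpha: float, n_cpgs: int, n_contrasts: int) -> float:
    """Raw-p significance cut alpha / (n_cpgs x n_contrasts)."""
    return alpha / (n_cpgs * n_contrasts)


def global_significance(
    p: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> tuple[np.ndarray, float]:
    """Flag significant (CpG, contrast) cells over the pooled p matrix.

    bonferroni: strict p < alpha / (n_cpgs * n_contrasts). fdr: pooled
    Benjamini-Hochberg at level alpha (the returned threshold is the
    largest accepted raw p, or 0 when nothing passes). A DMP is a CpG
    flagged in at least one contrast.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value matrix")
    if method == "bonferroni":
        thr = bonferroni_threshold(alpha, arr.shape[0], arr.shape[1] if arr.ndim > 1 else 1)
        flags = arr < thr
    elif method == "fdr":
        rej, _, _, _ = multipletests(arr.ravel(), alpha=alpha, method="fdr_bh")[:4]
        flags = rej.reshape(arr.shape)
        thr = float(arr.ravel()[rej].max()) if rej.any() else 0.0
    else:
        raise ValueError("method must be 'bonferroni' or 'fdr'")
    return flags, thr


def dmp_count(p_matrix: np.ndarray, alpha: float = 0.05,
              rule: str = "bonferroni") -> int:
    """Number of CpGs significant in at least one contrast.

    ``rule`` picks the per-cell call: 'bonferroni' (the pipeline default,
    strict p < alpha / (CpGs x contrasts)), 'fdr' (pooled BH), or
    'nominal' (p < alpha unadjusted — useful for calibration studies,
    where the count statistic must not be tied at zero).
    """
    if rule == "nominal":
        flags = np.asarray(p_matrix) < alpha
    else:
        flags, _ = global_significance(p_matrix, alpha, rule)
    return int(flags.any(axis=1).sum())


# ---------------------------------------------------------------------------
# inflation diagnostics
# ---------------------------------------------------------------------------

def inflation_report(p: np.ndarray, t: np.ndarray | None = None) -> dict:
    """Genomic inflation factor and an empirical-null location/scale.

    lambda = median(z^2) / 0.4549364 with z the probit transform of the
    two-sided p-values (signed by t when available). The empirical-null
    scale — reported as the Bayesian-inflation-factor analogue — is the
    median / 1.4826*MAD of z estimated on the central 90% of the z
    distribution, a robust stand-in for the original Gibbs-sampler
    estimate of the null scale.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size < 1000:
        raise ValueError("inflation estimates need >= 1000 tests")
    p = np.clip(p, 1e-300, 1.0)
    z = stats.norm.isf(p / 2.0)
    if t is not None:
        z = z * np.sign(np.asarray(t, dtype=float).ravel())
    lam = float(np.median(z**2) / stats.chi2.ppf(0.5, 1))
    lo, hi = np.quantile(z, [0.05, 0.95])
    core = z[(z >= lo) & (z <= hi)]
    loc = float(np.median(core))
    # consistency for a MAD taken on the central 90%: the median absolute
    # deviation of a normal truncated at +-q(0.95) is Phi^-1(0.725) sigma
    mad_const = stats.norm.ppf(0.5 + 0.9 / 4.0)
    scale = float(np.median(np.abs(core - loc)) / mad_const)
    return {"lambda": lam, "null_location": loc, "null_scale": scale}


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def permutation_empirical_p(observed: int, permuted_counts: np.ndarray) -> float:
    """(1 + #(permuted > observed)) / (B + 1), with strict exceedance."""
    permuted_counts = np.asarray(permuted_counts)
    B = permuted_counts.size
    if B < 1:
        raise ValueError("need at least one permutation")
    return float((1 + int((permuted_counts > observed).sum())) / (B + 1))


def _ewas_pmatrix(
    m_values: pd.DataFrame,
    covariate_design: pd.DataFrame | None,
    labels: np.ndarray,
    robust: bool = True,
    moderate: bool = True,
    huber_c: float = 1.345,
    max_iter: int = 50,
) -> np.ndarray:
    parts = [cluster_indicators(labels)]
    if covariate_design is not None:
        parts.append(covariate_design.reset_index(drop=True))
    X = pd.concat(parts, axis=1)
    fit = robust_fit(m_values, X, huber_c=huber_c, max_iter=max_iter, robust=robust)
    if moderate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ebayes_moderate(fit)
    C = make_pairwise_contrasts(X.columns)
    Cv = C.loc[X.columns].to_numpy()
    dM = fit.coef @ Cv
    var_unscaled = np.einsum("pj,cpq,qj->cj", Cv, fit.cov_unscaled, Cv, optimize=True)
    se = np.sqrt(np.maximum(var_unscaled, 0.0) * fit.s2_used[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, dM / se, 0.0)
    return 2.0 * stats.t.sf(np.abs(t), df=fit.df_total)


def permutation_null(
    m_values: pd.DataFrame,
    covariate_design: pd.DataFrame | None,
    labels: np.ndarray,
    n_permutations: int = 500,
    seed: int | None = None,
    alpha: float = 0.05,
    robust: bool = True,
    moderate: bool = True,
    observed_count: int | None = None,
    alpha_rule: str = "bonferroni",
) -> PermutationResult:
    """Empirical null for the genome-wide DMP count.

    Each permutation shuffles the cluster labels uniformly (covariates
    fixed), reruns the full EWAS with pairwise contrasts, and counts the
    CpGs significant in at least one contrast under ``alpha_rule``. The
    empirical p-value uses strict exceedance:
    (1 + #(permuted > observed)) / (B + 1). Note the strict '>' makes
    the p-value anti-conservative when the count statistic is heavily
    tied (e.g. almost always zero); calibration studies should use a
    rule under which counts vary, such as 'nominal'.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)

    if observed_count is None:
        p_obs = _ewas_pmatrix(m_values, covariate_design, labels, robust, moderate)
        observed_count = dmp_count(p_obs, alpha, alpha_rule)

    counts = np.empty(n_permutations, dtype=int)
    for b in range(n_permutations):
        perm = rng.permutation(labels)
        p_b = _ewas_pmatrix(m_values, covariate_design, perm, robust, moderate)
        counts[b] = dmp_count(p_b, alpha, alpha_rule)

    return PermutationResult(
        n_permutations=n_permutations,
        observed_dmps=int(observed_count),
        permuted_dmps=counts,
        empirical_p=permutation_empirical_p(int(observed_count), counts),
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class ClusterEwas:
    """EWAS of methylation on microbiome-cluster membership.

    Parameters
    ----------
    meth : MethylationMatrix
        Beta- or M-scale matrix; converted to M internally.
    labels : array-like
        Per-sample cluster ids (1..k), aligned with the matrix columns.
    covariates : DataFrame, optional
        Sample covariates (sex, age, bmi_z, race, education, day_of_year,
        batch) used to build the adjusted design.
    refactor, extra
        Optional cell-composition components and extra covariates.
    """

    def __init__(
        self,
        meth: MethylationMatrix,
        labels: np.ndarray,
        covariates: pd.DataFrame | None = None,
        refactor: RefactorComponents | None = None,
        extra: pd.DataFrame | pd.Series | None = None,
        winsorize: bool = False,
        harmonics: int = 2,
    ) -> None:
        m = as_m_matrix(meth)
        self.m_values = m.values
        if winsorize:
            self.m_values = winsorize_m(self.m_values)
        self.labels = np.asarray(labels)
        if covariates is not None:
            self.design = build_design(
                covariates, self.labels, refactor, extra, harmonics
            )
        else:
            self.design = cluster_indicators(self.labels).set_index(
                self.m_values.columns
            )
        self.annotation = meth.annotation

    def fit(
        self,
        robust: bool = True,
        moderate: bool = True,
        huber_c: float = 1.345,
        max_iter: int = 50,
        alpha: float = 0.05,
    ) -> "EwasResults":
        fit = robust_fit(self.m_values, self.design, huber_c=huber_c,
                         max_iter=max_iter, robust=robust)
        if moderate:
            fit = ebayes_moderate(fit)
        contrasts = pairwise_contrasts(fit)
        return EwasResults(self, fit, contrasts, alpha)


class EwasResults:
    """Fitted EWAS: contrast table, DMP calls, diagnostics, permutations."""

    def __init__(self, model: ClusterEwas, fit: EwasFit,
                 contrasts: pd.DataFrame, alpha: float) -> None:
        self.model = model
        self.fit = fit
        self.contrasts = contrasts
        self.alpha = alpha
        self.n_contrasts = contrasts["contrast"].nunique()
        self.threshold = bonferroni_threshold(
            alpha, len(fit.cpg_ids), self.n_contrasts
        )

    @property
    def p_matrix(self) -> np.ndarray:
        return (
            self.contrasts.pivot(index="cpg", columns="contrast", values="p")
            .loc[self.fit.cpg_ids]
            .to_numpy()
        )

    def dmps(self) -> pd.DataFrame:
        """Significant rows (Bonferroni) of the contrast table."""
        return self.contrasts[self.contrasts["p"] < self.threshold]

    def dmp_cpgs(self) -> pd.Index:
        return pd.Index(self.dmps()["cpg"].unique())

    def inflation(self) -> pd.DataFrame:
        rows = {}
        for name, grp in self.contrasts.groupby("contrast"):
            rows[name] = inflation_report(grp["p"].to_numpy(), grp["t"].to_numpy())
        return pd.DataFrame(rows).T

    def permutation_null(self, n_permutations: int = 500, seed: int | None = None,
                         robust: bool = True, moderate: bool = True) -> PermutationResult:
        cov_design = self.model.design.drop(
            columns=[c for c in self.model.design.columns if str(c).startswith("cluster")]
        )
        cov_design = cov_design if cov_design.shape[1] else None
        return permutation_null(
            self.model.m_values, cov_design, self.model.labels,
            n_permutations=n_permutations, seed=seed, alpha=self.alpha,
            robust=robust, moderate=moderate,
            observed_count=len(self.dmp_cpgs()),
        )

    def results_table(self) -> pd.DataFrame:
        """Contrast table with probe annotation merged in, sorted by p."""
        tab = self.contrasts.copy()
        if self.model.annotation is not None:
            ann = self.model.annotation
            tab = tab.merge(ann, left_on="cpg", right_index=True, how="left")
        return tab.sort_values("p").reset_index(drop=True)

    def summary(self, top: int = 10) -> str:
        n_dmp = len(self.dmp_cpgs())
        lines = [
            "Microbiome-cluster EWAS",
            f"  CpGs tested:        {len(self.fit.cpg_ids)}",
            f"  pairwise contrasts: {self.n_contrasts}",
            f"  residual df:        {self.fit.df:.0f}"
            + (f" (+ prior d0 = {self.fit.d0:.1f})" if self.fit.moderated else ""),
            f"  Bonferroni raw-p threshold: {self.threshold:.3g}",
            f"  DMPs (significant in >= 1 contrast): {n_dmp}",
            "",
            "Top associations:",
        ]
        cols = ["cpg", "contrast", "delta_m", "delta_beta_pct", "p", "p_bonferroni"]
        head = self.contrasts.nsmallest(top, "p")[cols]
        lines.append(head.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)
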