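"""Design construction, robust regression, moderation, contrasts, inflation
and the permutation empirical null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nasepi.ewas import (
    ClusterEwas,
    bonferroni_threshold,
    build_design,
    cluster_indicators,
    dmp_count,
    ebayes_moderate,
    fit_f_dist,
    global_significance,
    inflation_report,
    make_pairwise_contrasts,
    pairwise_contrasts,
    permutation_empirical_p,
    permutation_null,
    robust_fit,
    season_harmonics,
)
from nasepi.simulate import CohortParams, generate_covariates


def _cov(n=60, seed=0):
    return generate_covariates(CohortParams(n_samples=n, seed=seed))


class TestDesign:
    def test_column_count_matches_coding_rules(self):
        rng = np.random.default_rng(0)
        n = 120
        cov = pd.DataFrame(
            {
                "sex": rng.integers(0, 2, n),
                "age": rng.normal(13, 0.7, n),
                "bmi_z": rng.normal(0, 1, n),
                "race": rng.choice(list("ABCDE"), n),
                "education": rng.integers(0, 2, n),
                "day_of_year": rng.integers(1, 366, n),
                "batch": rng.choice(["b1", "b2", "b3", "b4"], n),
            },
            index=[f"S{i}" for i in range(n)],
        )
        labels = rng.integers(1, 7, n)
        from nasepi.containers import RefactorComponents

        rf = RefactorComponents(
            pd.DataFrame(rng.normal(size=(n, 10)), index=cov.index,
                         columns=[f"RC{i+1}" for i in range(10)]),
            pd.Index([]), 10, 100,
        )
        X = build_design(cov, labels, rf)
        # 6 clusters + sex/age/bmi + 4 race + education + 4 season + 3 batch + 10 RC
        assert X.shape[1] == 31

    def test_season_periodicity(self):
        a = season_harmonics(np.array([0.0]))
        b = season_harmonics(np.array([365.25]))
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_collinear_extra_rejected(self):
        cov = _cov(40)
        labels = np.repeat([1, 2], 20)
        extra = pd.Series(cov["age"].to_numpy(), index=cov.index, name="age_copy")
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(cov, labels, extra=extra)


class TestRobustFit:
    def _design(self, n, seed=1):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {"intercept": 1.0, "x": rng.normal(size=n), "z": rng.normal(size=n)}
        )
        return X, rng

    def test_reduces_to_ols_with_bounded_residuals(self):
        # when every residual stays inside c * scale all Huber weights
        # are 1 and the fit is exactly OLS
        X, rng = self._design(200)
        beta = np.array([1.0, 2.0, -0.5])
        resid = 0.1 * np.where(np.arange(200) % 2 == 0, 1.0, -1.0)
        Y = pd.DataFrame((beta @ X.to_numpy().T)[None, :] + resid[None, :])
        fit = robust_fit(Y, X)
        ols = Y.to_numpy() @ np.linalg.pinv(X.to_numpy()).T
        assert np.allclose(fit.coef, ols, atol=1e-6)

    def test_close_to_ols_under_gaussian_noise(self):
        X, rng = self._design(200)
        beta = np.array([1.0, 2.0, -0.5])
        Y = pd.DataFrame(beta @ X.to_numpy().T + rng.normal(0, 0.05, (5, 200)))
        fit = robust_fit(Y, X)
        ols = Y.to_numpy() @ np.linalg.pinv(X.to_numpy()).T
        assert np.allclose(fit.coef, ols, atol=5e-3)

    def test_resists_gross_outlier(self):
        X, rng = self._design(100, seed=2)
        slope_bias_rob, slope_bias_ols = [], []
        for s in range(40):
            r = np.random.default_rng(s)
            y = 2.0 * X["x"].to_numpy() + r.normal(0, 0.3, 100)
            y[0] += 30.0  # one gross outlier
            Y = pd.DataFrame(y[None, :])
            rob = robust_fit(Y, X).coef[0, 1]
            ols = (np.linalg.pinv(X.to_numpy()) @ y)[1]
            slope_bias_rob.append(abs(rob - 2.0))
            slope_bias_ols.append(abs(ols - 2.0))
        assert np.mean(slope_bias_rob) <= 0.2 * np.mean(slope_bias_ols) + 0.02

    def test_matches_statsmodels_rlm(self):
        sm = pytest.importorskip("statsmodels.api")
        X, rng = self._design(150, seed=3)
        y = 1.0 + 0.8 * X["x"].to_numpy() - 0.3 * X["z"].to_numpy() + rng.standard_t(3, 150)
        fit = robust_fit(pd.DataFrame(y[None, :]), X)
        ref = sm.RLM(y, X.to_numpy(), M=sm.robust.norms.HuberT(1.345)).fit()
        assert np.allclose(fit.coef[0], ref.params, atol=2e-2)

    def test_planted_cluster_difference_recovered(self):
        # delta-M 0.5 between two clusters, noise SD 0.3, n = 372
        n = 372
        labels = np.r_[np.ones(186, int), np.full(186, 2, int)]
        X = cluster_indicators(labels)
        ests = []
        for s in range(50):
            rng = np.random.default_rng(100 + s)
            y = np.where(labels == 1, 0.5, 0.0) + rng.normal(0, 0.3, n)
            fit = robust_fit(pd.DataFrame(y[None, :]), X)
            ests.append(fit.coef[0, 0] - fit.coef[0, 1])
        assert np.mean(ests) == pytest.approx(0.5, abs=0.05)

    def test_needs_more_samples_than_predictors(self):
        X, _ = self._design(2)
        with pytest.raises(ValueError):
            robust_fit(pd.DataFrame(np.zeros((1, 2))), X)


class TestModeration:
    def test_equal_variances_collapse_to_common_value(self):
        n, p = 50, 3
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(n, p)))
        Y = pd.DataFrame(rng.normal(0, 1.0, (200, n)))
        fit = robust_fit(Y, X, robust=False)
        fit.s2 = np.full_like(fit.s2, 0.81)
        fit = ebayes_moderate(fit)
        assert np.allclose(fit.s2_post, 0.81, atol=1e-9)
        assert np.isinf(fit.d0)

    def test_hyperparameters_recovered_from_scaled_chi2(self):
        rng = np.random.default_rng(5)
        d, d0, s02 = 30.0, 8.0, 0.5
        n_cpgs = 100_000
        true_var = s02 * d0 / rng.chisquare(d0, n_cpgs)
        s2 = true_var * rng.chisquare(d, n_cpgs) / d
        d0_hat, s02_hat = fit_f_dist(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.10)
        assert s02_hat == pytest.approx(s02, rel=0.10)

    def test_matches_limma_squeezevar(self, tmp_path):
        import shutil, subprocess

        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable")
        rng = np.random.default_rng(6)
        d = 20.0
        s2 = 0.4 * rng.chisquare(d, 3000) / d
        np.savetxt(tmp_path / "s2.txt", s2)
        script = tmp_path / "sq.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"s2 <- scan('{tmp_path}/s2.txt', quiet=TRUE)\n"
            f"out <- squeezeVar(s2, df={d})\n"
            "cat(sprintf('%.10f %.10f %.10f', out$df.prior, out$var.prior, out$var.post[1]))\n"
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        d0_r, s02_r, post_r = map(float, res.stdout.split())
        d0, s02 = fit_f_dist(s2, d)
        post = (d0 * s02 + d * s2[0]) / (d0 + d)
        if np.isinf(d0):
            assert d0_r > 1e6
        else:
            assert d0 == pytest.approx(d0_r, rel=1e-4)
            assert s02 == pytest.approx(s02_r, rel=1e-4)
            assert post == pytest.approx(post_r, rel=1e-4)

    def test_moderation_off_keeps_raw_t(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(1, 4, 40)
        X = cluster_indicators(labels)
        Y = pd.DataFrame(rng.normal(size=(150, 40)))
        fit = robust_fit(Y, X)
        raw = pairwise_contrasts(fit)
        fit2 = robust_fit(Y, X)
        mod = pairwise_contrasts(ebayes_moderate(fit2))
        assert not np.allclose(raw["t"], mod["t"])
        assert np.allclose(raw["delta_m"], mod["delta_m"])


class TestContrasts:
    def _fit(self, n_clusters=6, n=90, n_cpgs=30, seed=8):
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(1, n_clusters + 1), n // n_clusters)
        X = cluster_indicators(labels)
        Y = pd.DataFrame(rng.normal(size=(n_cpgs, n)))
        return robust_fit(Y, X), X

    def test_six_clusters_give_fifteen_contrasts(self):
        fit, X = self._fit()
        tab = pairwise_contrasts(fit)
        assert tab["contrast"].nunique() == 15

    def test_contrast_is_coefficient_difference(self):
        fit, X = self._fit()
        C = make_pairwise_contrasts(X.columns)
        tab = pairwise_contrasts(fit, C)
        row = tab[(tab["contrast"] == "1_vs_2")].iloc[0]
        assert row["delta_m"] == pytest.approx(fit.coef[0, 0] - fit.coef[0, 1])

    def test_sign_flip_negates_estimate_keeps_p(self):
        fit, X = self._fit()
        C = make_pairwise_contrasts(X.columns)
        flipped = -C
        a = pairwise_contrasts(fit, C)
        b = pairwise_contrasts(fit, flipped)
        assert np.allclose(a["delta_m"], -b["delta_m"])
        assert np.allclose(a["p"], b["p"])

    def test_linearity_of_contrasts(self):
        fit, X = self._fit()
        C = make_pairwise_contrasts(X.columns)
        c12 = C["1_vs_2"].to_numpy()
        c23 = C["2_vs_3"].to_numpy()
        c13 = C["1_vs_3"].to_numpy()
        assert np.allclose(c12 + c23, c13)
        tab = pairwise_contrasts(fit, C)
        wide = tab.pivot(index="cpg", columns="contrast", values="delta_m")
        assert np.allclose(wide["1_vs_2"] + wide["2_vs_3"], wide["1_vs_3"], atol=1e-10)

    def test_unknown_contrast_row_rejected(self):
        fit, X = self._fit()
        C = pd.DataFrame({"bad": [1.0, -1.0]}, index=["nope1", "nope2"])
        with pytest.raises(ValueError, match="not in design"):
            pairwise_contrasts(fit, C)


class TestGlobalSignificance:
    def test_published_threshold_arithmetic(self):
        thr = bonferroni_threshold(0.05, 715_023, 15)
        assert f"{thr:.3g}" == "4.66e-09"

    def test_boundary_is_strict(self):
        n_cpgs, n_con = 100, 15
        thr = bonferroni_threshold(0.05, n_cpgs, n_con)
        p = np.full((n_cpgs, n_con), 1.0)
        p[0, 0] = thr  # exactly at the threshold: not significant
        flags, _ = global_significance(p)
        assert not flags.any()

    def test_all_ones_give_zero_dmps(self):
        p = np.ones((50, 15))
        assert dmp_count(p) == 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            global_significance(np.empty((0, 0)))


class TestInflation:
    def test_calibrated_null(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 1, 100_000)
        p = 2 * stats.norm.sf(np.abs(z))
        rep = inflation_report(p, z)
        assert 0.97 <= rep["lambda"] <= 1.03
        assert 0.97 <= rep["null_scale"] <= 1.03

    def test_scaled_null_detected(self):
        rng = np.random.default_rng(10)
        z = rng.normal(0, 1.3, 100_000)
        p = 2 * stats.norm.sf(np.abs(z))
        rep = inflation_report(p, z)
        assert rep["null_scale"] == pytest.approx(1.3, abs=0.03)

    def test_too_few_tests_rejected(self):
        with pytest.raises(ValueError):
            inflation_report(np.full(100, 0.5))


class TestPermutation:
    def test_published_formula_worked_example(self):
        counts = np.zeros(500, dtype=int)
        counts[:2] = 99  # exactly 2 permutations exceed the observed count
        p = permutation_empirical_p(45, counts)
        assert round(p, 3) == 0.006

    def test_floor_and_ceiling(self):
        assert permutation_empirical_p(10, np.zeros(500, int)) == pytest.approx(1 / 501)
        assert permutation_empirical_p(0, np.ones(500, int)) == pytest.approx(1.0)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_empirical_p(1, np.array([], dtype=int))

    def test_runs_and_is_deterministic(self):
        rng = np.random.default_rng(11)
        n, c = 60, 40
        labels = np.repeat([1, 2, 3], 20)
        m = pd.DataFrame(rng.normal(size=(c, n)))
        a = permutation_null(m, None, labels, n_permutations=8, seed=5,
                             moderate=False)
        b = permutation_null(m, None, labels, n_permutations=8, seed=5,
                             moderate=False)
        assert np.array_equal(a.permuted_dmps, b.permuted_dmps)
        assert a.empirical_p == b.empirical_p
        assert 1 / 9 <= a.empirical_p <= 1.0


class TestClusterEwasModel:
    def test_planted_effects_detected_and_converted(self, small_cohort):
        co = small_cohort
        model = ClusterEwas(co.meth, co.truth.true_labels, co.covariates)
        res = model.fit()
        found = set(res.dmp_cpgs())
        planted = set(co.truth.dmp_table["cpg"])
        assert len(found & planted) >= len(planted) - 2
        # delta-beta sign must match delta-M sign everywhere
        tab = res.contrasts
        nz = tab["delta_m"].abs() > 1e-12
        assert np.all(np.sign(tab.loc[nz, "delta_m"])
                      == np.sign(tab.loc[nz, "delta_beta_pct"]))
        assert "Microbiome-cluster EWAS" in res.summary()

    def test_winsorized_refit_similar(self, small_cohort):
        co = small_cohort
        res = ClusterEwas(co.meth, co.truth.true_labels, co.covariates,
                          winsorize=True).fit()
        planted = set(co.truth.dmp_table["cpg"])
        assert len(set(res.dmp_cpgs()) & planted) >= len(planted) - 3
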