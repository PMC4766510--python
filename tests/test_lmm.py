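import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import multivariate_normal

from gamediv.lmm import (
    NonNestedError,
    RankDeficiencyError,
    fit_lmm,
    lrt,
)


def random_intercept_data(seed=1, G=15, T=8, sd_b=0.7, sd_e=0.5):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(G), T)
    t = np.tile(np.arange(T, dtype=float), G)
    b = rng.normal(0, sd_b, G)
    y = 1.0 + 0.3 * t + b[groups] + rng.normal(0, sd_e, G * T)
    X = pd.DataFrame({"Intercept": np.ones(G * T), "t": t})
    return y, X, groups, t


def ar1_data(seed=2, G=15, T=10, phi=0.5, sd_b=0.7, sd_e=0.5):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(G), T)
    t = np.tile(np.arange(T, dtype=float), G)
    b = rng.normal(0, sd_b, G)
    e = np.zeros(G * T)
    for g in range(G):
        ee = np.empty(T)
        ee[0] = rng.normal(0, sd_e / np.sqrt(1 - phi**2))
        for k in range(1, T):
            ee[k] = phi * ee[k - 1] + rng.normal(0, sd_e)
        e[g * T:(g + 1) * T] = ee
    y = 1.0 + 0.3 * t + b[groups] + e
    X = pd.DataFrame({"Intercept": np.ones(G * T), "t": t})
    return y, X, groups, t


class TestAgainstStatsmodels:
    """Random-intercept fits must agree with an independent mixed-model
    implementation (statsmodels MixedLM) in both estimators."""

    @pytest.mark.parametrize("reml", [True, False])
    def test_estimates_and_loglik_match(self, reml):
        y, X, groups, _ = random_intercept_data()
        mine = fit_lmm(y, X, groups, reml=reml)
        ref = sm.MixedLM(y, X.values, groups=groups).fit(reml=reml)
        assert np.allclose(mine.params.values, ref.fe_params, atol=1e-6)
        assert np.allclose(mine.bse.values, np.asarray(ref.bse_fe), atol=1e-5)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_variance_components_match(self):
        y, X, groups, _ = random_intercept_data(seed=3)
        mine = fit_lmm(y, X, groups, reml=True)
        ref = sm.MixedLM(y, X.values, groups=groups).fit(reml=True)
        assert mine.sigma_resid**2 == pytest.approx(ref.scale, rel=1e-3)
        assert mine.sigma_group**2 == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=1e-3
        )


class TestAR1Likelihood:
    def test_reported_loglik_matches_brute_force_mvn(self):
        """The profiled ML log-likelihood must equal a dense multivariate
        normal evaluated at the fitted parameters."""
        y, X, groups, t = ar1_data()
        fit = fit_lmm(y, X, groups, times=t, ar1=True, reml=False)
        G, T = fit.n_groups, fit.n_obs // fit.n_groups
        gaps = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        V = np.zeros((fit.n_obs, fit.n_obs))
        for g in range(G):
            block = slice(g * T, (g + 1) * T)
            V[block, block] = fit.sigma_group**2 + fit.sigma_resid**2 * fit.phi**gaps
        r = y - X.values @ fit.params.values
        brute = multivariate_normal.logpdf(r, mean=np.zeros(fit.n_obs), cov=V)
        assert fit.loglik == pytest.approx(brute, abs=1e-6)

    def test_phi_recovered(self):
        y, X, groups, t = ar1_data(seed=11, G=40, T=15, phi=0.5)
        fit = fit_lmm(y, X, groups, times=t, ar1=True, reml=True)
        assert fit.phi == pytest.approx(0.5, abs=0.15)
        assert np.isfinite(fit.se_phi)

    def test_phi_near_zero_for_independent_errors(self):
        y, X, groups, t = random_intercept_data(seed=4, G=40, T=15)
        fit = fit_lmm(y, X, groups, times=t, ar1=True, reml=True)
        assert abs(fit.phi) < 0.15


class TestSingleGroupGLS:
    def test_matches_independent_grid_search(self):
        """With one species the model collapses to GLS with AR(1) errors;
        a 1-D grid search over phi (beta profiled by GLS at each value)
        is an independent optimum to compare against."""
        rng = np.random.default_rng(7)
        T = 60
        t = np.arange(T, dtype=float)
        phi = 0.6
        e = np.empty(T)
        e[0] = rng.normal(0, 1 / np.sqrt(1 - phi**2))
        for k in range(1, T):
            e[k] = phi * e[k - 1] + rng.normal()
        y = 2.0 + 0.1 * t + e
        X = np.column_stack([np.ones(T), t])
        fit = fit_lmm(y, X, groups=np.zeros(T), times=t, ar1=True, reml=False,
                      names=["Intercept", "t"])

        gaps = np.abs(np.subtract.outer(t, t))
        best = None
        for p in np.linspace(-0.95, 0.95, 381):
            R = np.abs(p) ** gaps if p != 0 else np.eye(T)
            if p < 0:
                R = R * np.where(np.round(gaps).astype(int) % 2 == 1, -1.0, 1.0)
            Ri = np.linalg.inv(R)
            beta = np.linalg.solve(X.T @ Ri @ X, X.T @ Ri @ y)
            r = y - X @ beta
            rss = float(r @ Ri @ r)
            s2 = rss / T
            ll = -0.5 * (
                T * np.log(2 * np.pi * s2)
                + np.linalg.slogdet(R)[1]
                + T
            )
            if best is None or ll > best[0]:
                best = (ll, p, beta)
        ll_star, phi_star, beta_star = best
        assert fit.phi == pytest.approx(phi_star, abs=0.01)
        assert np.allclose(fit.params.values, beta_star, atol=1e-2)
        assert fit.loglik >= ll_star - 1e-3


class TestDesignValidation:
    def test_rank_deficiency_names_aliased_terms(self):
        y, X, groups, _ = random_intercept_data()
        X = X.assign(t_copy=X["t"])
        with pytest.raises(RankDeficiencyError, match="t"):
            fit_lmm(y, X, groups)

    def test_length_mismatch(self):
        y, X, groups, _ = random_intercept_data()
        with pytest.raises(ValueError, match="matching lengths"):
            fit_lmm(y[:-1], X, groups)


class TestLRT:
    def test_identical_models_give_zero(self):
        y, X, groups, _ = random_intercept_data()
        f = fit_lmm(y, X, groups, reml=False)
        res = lrt(f, f)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_reml_fits_refitted_to_ml(self):
        y, X, groups, _ = random_intercept_data()
        full = fit_lmm(y, X, groups, reml=True)
        reduced = fit_lmm(y, X[["Intercept"]], groups, reml=True)
        res = lrt(full, reduced)
        full_ml = fit_lmm(y, X, groups, reml=False)
        reduced_ml = fit_lmm(y, X[["Intercept"]], groups, reml=False)
        assert res.statistic == pytest.approx(
            2 * (full_ml.loglik - reduced_ml.loglik), abs=1e-5
        )
        assert res.df == 1

    def test_non_nested_rejected(self):
        y, X, groups, _ = random_intercept_data()
        f1 = fit_lmm(y, X[["Intercept"]].assign(a=X["t"] + 1), groups, reml=False)
        f2 = fit_lmm(y, X, groups, reml=False)
        with pytest.raises(NonNestedError):
            lrt(f2, f1)

    def test_statistic_invariant_to_affine_time_recoding(self):
        y, X, groups, _ = random_intercept_data(seed=9)
        X2 = pd.DataFrame({"Intercept": 1.0, "t": 3.0 * X["t"] - 12.0})
        stat1 = lrt(
            fit_lmm(y, X, groups, reml=False),
            fit_lmm(y, X[["Intercept"]], groups, reml=False),
        ).statistic
        stat2 = lrt(
            fit_lmm(y, X2, groups, reml=False),
            fit_lmm(y, X2[["Intercept"]], groups, reml=False),
        ).statistic
        assert stat1 == pytest.approx(stat2, abs=1e-5)


def test_nlme_cross_check(tmp_path):
    """Full AR(1) + random-intercept fit cross-checked against R's nlme::lme,
    the reference implementation for this model family."""
    import subprocess

    y, X, groups, t = ar1_data(seed=5, G=12, T=9)
    frame = pd.DataFrame({"y": y, "t": t, "sp": groups})
    csv = tmp_path / "d.csv"
    frame.to_csv(csv, index=False)
    script = f"""
    suppressMessages(library(nlme))
    d <- read.csv("{csv}")
    m <- lme(y ~ t, random = ~1 | sp, correlation = corAR1(form = ~ t | sp),
             data = d, method = "ML")
    phi <- coef(m$modelStruct$corStruct, unconstrained = FALSE)
    cat(sprintf("%.8f %.8f %.8f %.8f\\n", logLik(m), fixef(m)[1], fixef(m)[2], phi))
    """
    proc = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert proc.returncode == 0, proc.stderr
    ll_r, b0_r, b1_r, phi_r = map(float, proc.stdout.split()[-4:])
    fit = fit_lmm(y, X, groups, times=t, ar1=True, reml=False)
    assert fit.loglik == pytest.approx(ll_r, abs=1e-3)
    assert fit.params["Intercept"] == pytest.approx(b0_r, abs=1e-3)
    assert fit.params["t"] == pytest.approx(b1_r, abs=1e-3)
    assert fit.phi == pytest.approx(phi_r, abs=1e-3)
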