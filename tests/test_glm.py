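import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import gammaln

import lagrisk as lr
from lagrisk.glm import (
    FitResult,
    RankDeficiencyError,
    fit_glm,
    linear_combination_ci,
    pearson_dispersion,
    quasi_aic,
)


def _sim_poisson(rng, n=2000, b0=1.0, b1=0.5):
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(b0 + b1 * x))
    X = np.column_stack([np.ones(n), x])
    return y, X


def test_intercept_only_poisson_is_log_mean():
    y = np.array([1, 2, 3, 4])
    fit = fit_glm(y, np.ones((4, 1)), family="poisson")
    assert fit.coef[0] == pytest.approx(np.log(2.5), abs=1e-10)


def test_simulation_recovery_within_3_se(rng):
    y, X = _sim_poisson(rng)
    fit = fit_glm(y, X, family="poisson")
    assert abs(fit.coef[0] - 1.0) < 3 * fit.se[0]
    assert abs(fit.coef[1] - 0.5) < 3 * fit.se[1]


def test_irls_matches_generic_likelihood_maximizer(rng):
    y, X = _sim_poisson(rng)
    fit = fit_glm(y, X, family="poisson")

    def negll(beta):
        mu = np.exp(X @ beta)
        return -(y @ np.log(mu) - mu.sum())

    opt = optimize.minimize(negll, np.zeros(2), method="BFGS", tol=1e-12)
    assert np.max(np.abs(fit.coef - opt.x)) < 1e-6


def test_matches_statsmodels_poisson(rng):
    import statsmodels.api as sm

    y, X = _sim_poisson(rng, n=500)
    fit = fit_glm(y, X, family="poisson")
    ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(fit.coef, ref.params, atol=1e-8)
    np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-5)


def test_score_equations_hold_at_convergence(rng):
    y, X = _sim_poisson(rng, n=800)
    fit = fit_glm(y, X, family="poisson")
    mu = np.exp(X @ fit.coef)
    assert np.max(np.abs(X.T @ (y - mu))) < 1e-6


def test_rank_deficiency_names_columns(rng):
    x = rng.normal(size=50)
    X = np.column_stack([np.ones(50), x, 2 * x])
    with pytest.raises(RankDeficiencyError, match="dup"):
        fit_glm(rng.poisson(5, 50), X, family="poisson", column_labels=["const", "x", "dup"])


class TestDispersion:
    def test_exact_fit_gives_zero(self):
        y = np.array([3, 3, 3, 3])
        fit = fit_glm(y, np.ones((4, 1)), family="poisson")
        assert pearson_dispersion(fit, y, np.ones((4, 1))) == pytest.approx(0.0, abs=1e-12)

    def test_poisson_data_dispersion_near_one(self):
        rng = np.random.default_rng(5)
        y, X = _sim_poisson(rng, n=4000)
        fit = fit_glm(y, X, family="quasipoisson")
        assert 0.8 <= fit.dispersion <= 1.2

    def test_doubled_variance_dispersion_near_two(self):
        rng = np.random.default_rng(6)
        n = 4000
        x = rng.normal(size=n)
        mu = np.exp(1.0 + 0.5 * x)
        size = mu  # NB2 with size=mu: Var = mu + mu^2/size = 2*mu
        y = rng.negative_binomial(size, size / (size + mu))
        X = np.column_stack([np.ones(n), x])
        fit = fit_glm(y, X, family="quasipoisson")
        assert 1.7 <= fit.dispersion <= 2.3

    def test_quasipoisson_vcov_is_phi_times_poisson(self, rng):
        y, X = _sim_poisson(rng, n=500)
        quasi = fit_glm(y, X, family="quasipoisson")
        pois = fit_glm(y, X, family="poisson")
        np.testing.assert_allclose(
            quasi.vcov, quasi.dispersion * pois.vcov, rtol=1e-10
        )


class TestQuasiAic:
    def _fit(self, family, loglik, phi, k):
        return FitResult(
            coef=np.zeros(k),
            vcov=np.eye(k),
            dispersion=phi,
            loglik=loglik,
            qaic=np.nan,
            n_obs=100,
            n_params=k,
            converged=True,
            family=family,
        )

    def test_poisson_reduces_to_aic(self):
        assert quasi_aic(self._fit("poisson", -100.0, 1.0, 3)) == pytest.approx(206.0)

    def test_quasipoisson_formula(self):
        assert quasi_aic(self._fit("quasipoisson", -100.0, 2.0, 3)) == pytest.approx(108.0)

    def test_zero_dispersion_rejected(self):
        with pytest.raises(ValueError):
            quasi_aic(self._fit("quasipoisson", -100.0, 0.0, 3))

    def test_noise_column_usually_increases_qaic(self):
        # nested comparison on a shared dispersion (taken from the larger
        # model, the standard convention) so only fit vs penalty matters
        rng = np.random.default_rng(17)
        worse = 0
        reps = 40
        for _ in range(reps):
            y, X = _sim_poisson(rng, n=300)
            noise = rng.normal(size=len(y))
            small = fit_glm(y, X, family="quasipoisson")
            big = fit_glm(y, np.column_stack([X, noise]), family="quasipoisson")
            worse += quasi_aic(big, big.dispersion) > quasi_aic(small, big.dispersion)
        assert worse > reps / 2


class TestLinearCombinationCI:
    def test_one_hot_reproduces_wald_interval(self, rng):
        y, X = _sim_poisson(rng, n=500)
        fit = fit_glm(y, X, family="quasipoisson")
        est, lo, hi = linear_combination_ci(fit, np.array([0.0, 1.0]))
        z = stats.norm.ppf(0.975)
        assert est == pytest.approx(fit.coef[1])
        assert lo == pytest.approx(fit.coef[1] - z * fit.se[1])
        assert hi == pytest.approx(fit.coef[1] + z * fit.se[1])

    def test_zero_weights_give_zero_interval(self, rng):
        y, X = _sim_poisson(rng, n=200)
        fit = fit_glm(y, X, family="poisson")
        assert linear_combination_ci(fit, np.zeros(2)) == (0.0, 0.0, 0.0)

    def test_dimension_mismatch_rejected(self, rng):
        y, X = _sim_poisson(rng, n=200)
        fit = fit_glm(y, X, family="poisson")
        with pytest.raises(ValueError):
            linear_combination_ci(fit, np.ones(3))

    def test_matches_parametric_bootstrap(self):
        rng = np.random.default_rng(99)
        y, X = _sim_poisson(rng, n=600)
        fit = fit_glm(y, X, family="quasipoisson")
        w = np.array([1.0, 2.0])
        est, lo, hi = linear_combination_ci(fit, w)
        draws = (
            rng.multivariate_normal(fit.coef, fit.vcov, size=2000, check_valid="ignore")
            @ w
        )
        se = np.sqrt(w @ fit.vcov @ w)
        # MC error of a 2.5% quantile from 2000 draws is ~0.06 se
        assert abs(np.quantile(draws, 0.025) - lo) < 0.25 * se
        assert abs(np.quantile(draws, 0.975) - hi) < 0.25 * se


def test_gaussian_family_is_ordinary_least_squares(rng):
    n = 200
    x = rng.normal(size=n)
    y = 2.0 + 3.0 * x + rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    fit = fit_glm(y, X, family="gaussian")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.coef, beta, atol=1e-10)
    resid = y - X @ fit.coef
    assert fit.dispersion == pytest.approx(resid @ resid / (n - 2))


def test_loglik_is_poisson_likelihood_at_fit(rng):
    y, X = _sim_poisson(rng, n=300)
    fit = fit_glm(y, X, family="poisson")
    mu = np.exp(X @ fit.coef)
    expect = np.sum(y * np.log(mu) - mu - gammaln(y + 1))
    assert fit.loglik == pytest.approx(expect)
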