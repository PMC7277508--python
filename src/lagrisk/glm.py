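"""Shared GLM engine: IRLS fitting, dispersion, quasi-AIC, Wald intervals.

Count models in this package are log-link Poisson regressions; field data
on daily hospitalizations is typically overdispersed (Var(y) > E(y)), so
the working family is quasi-Poisson: coefficients as Poisson, covariance
inflated by the Pearson dispersion φ̂.  Model comparison across
overdispersed fits uses the quasi-AIC

    qAIC = −2·ℓ/φ̂ + 2·(k + 1),

with the Poisson log-likelihood ℓ at the fit and the dispersion counted as
one extra parameter; for the plain Poisson family this reduces to the
ordinary AIC (−2ℓ + 2k, dispersion fixed at 1).  The Gaussian family is
ordinary least squares and serves the Almon distributed-lag model.

Delta-method intervals for any linear combination of coefficients (the
log relative risk of every lag-specific contrast is one) come from
:func:`linear_combination_ci`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.special import gammaln

logger = logging.getLogger("lagrisk")

__all__ = [
    "FitResult",
    "RankDeficiencyError",
    "fit_glm",
    "pearson_dispersion",
    "quasi_aic",
    "linear_combination_ci",
    "wald_block_test",
]

FAMILIES = ("gaussian", "poisson", "quasipoisson")

#: IRLS convergence: relative change in deviance below this stops iteration.
IRLS_TOL = 1e-9
IRLS_MAX_ITER = 100
#: Floor applied to fitted means to guard the log link against underflow.
MU_FLOOR = 1e-10
#: Reciprocal-condition threshold below which design columns are flagged
#: as linearly dependent.
RCOND_COLLINEAR = 1e-10


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; message names the dependent columns."""


def _unweighted_r_inverse(X: np.ndarray) -> np.ndarray:
    _, R = linalg.qr(X, mode="economic")
    return linalg.solve_triangular(R, np.eye(X.shape[1]))


@dataclass
class FitResult:
    """Fitted GLM: coefficients, scaled covariance, dispersion, qAIC."""

    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    loglik: float
    qaic: float
    n_obs: int
    n_params: int
    converged: bool
    family: str
    column_labels: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    def summary_frame(self):
        import pandas as pd

        z = self.z
        return pd.DataFrame(
            {
                "term": self.column_labels or [f"b{i}" for i in range(len(self.coef))],
                "estimate": self.coef,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag[0] == 0:
        raise RankDeficiencyError("design matrix is identically zero")
    bad = diag / diag[0] < RCOND_COLLINEAR
    if bad.any():
        names = [labels[piv[i]] if labels else f"col{piv[i]}" for i in np.where(bad)[0]]
        raise RankDeficiencyError(
            "design matrix is rank deficient; dependent column(s): "
            + ", ".join(names)
        )


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def fit_glm(
    y: np.ndarray,
    X: np.ndarray,
    family: str = "quasipoisson",
    column_labels: list[str] | None = None,
    max_iter: int = IRLS_MAX_ITER,
    tol: float = IRLS_TOL,
) -> FitResult:
    """Fit a GLM by IRLS (log link for count families; OLS for gaussian).

    Count families require non-negative integer ``y``.  The design must be
    full column rank: dependent columns raise :class:`RankDeficiencyError`
    naming them.  Non-convergence returns a result flagged
    ``converged=False`` with a warning rather than raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if n <= k:
        raise ValueError(f"need n_obs > n_params, got n={n}, k={k}")
    labels = list(column_labels) if column_labels else [f"col{i}" for i in range(k)]

    # internal column scaling: numerically equivalent, much better conditioned
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    _check_rank(Xs, labels)

    if family == "gaussian":
        coef_s, _, _, _ = linalg.lstsq(Xs, y)
        coef = coef_s / scale
        resid = y - X @ coef
        rss = float(resid @ resid)
        sigma2_hat = rss / (n - k)
        Rinv = _unweighted_r_inverse(Xs)
        vcov = sigma2_hat * ((Rinv @ Rinv.T) / np.outer(scale, scale))
        # Gaussian MLE log-likelihood (sigma^2 at its MLE rss/n)
        loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        aic = -2 * loglik + 2 * (k + 1)
        return FitResult(
            coef=coef,
            vcov=vcov,
            dispersion=sigma2_hat,
            loglik=loglik,
            qaic=aic,
            n_obs=n,
            n_params=k,
            converged=True,
            family=family,
            column_labels=labels,
            fitted=X @ coef,
        )

    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("count families require non-negative integer y")

    # IRLS for the log link: working response z = eta + (y - mu)/mu, W = mu
    mu = np.clip(y + 0.5, MU_FLOOR, None)
    eta = np.log(mu)
    dev = np.inf
    converged = False
    coef_s = np.zeros(k)
    sw = np.sqrt(mu)
    for _ in range(max_iter):
        z = eta + (y - mu) / mu
        sw = np.sqrt(mu)
        coef_s, _, _, _ = linalg.lstsq(Xs * sw[:, None], z * sw)
        eta = Xs @ coef_s
        mu = np.clip(np.exp(eta), MU_FLOOR, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        dev_new = 2 * float(np.sum(dev_terms))
        if abs(dev_new - dev) / (abs(dev_new) + 0.1) < tol:
            converged = True
            dev = dev_new
            break
        dev = dev_new
    if not converged:
        warnings.warn("IRLS did not converge within the iteration limit")
    coef = coef_s / scale

    # covariance from the R factor of the weighted design (inverse Fisher
    # information), avoiding an explicitly formed and squared condition number
    _, R = linalg.qr(Xs * sw[:, None], mode="economic")
    Rinv = linalg.solve_triangular(R, np.eye(k))
    vcov_poisson = (Rinv @ Rinv.T) / np.outer(scale, scale)
    phi = pearson_dispersion_from(y, mu, k)
    if family == "poisson":
        dispersion = 1.0
        vcov = vcov_poisson
    else:
        dispersion = phi
        vcov = phi * vcov_poisson
    loglik = _poisson_loglik(y, mu)
    fit = FitResult(
        coef=coef,
        vcov=vcov,
        dispersion=dispersion,
        loglik=loglik,
        qaic=np.nan,
        n_obs=n,
        n_params=k,
        converged=converged,
        family=family,
        column_labels=labels,
        fitted=mu,
    )
    fit.qaic = quasi_aic(fit)
    return fit


def pearson_dispersion_from(y: np.ndarray, mu: np.ndarray, k: int) -> float:
    """Pearson dispersion φ̂ = Σ (y−μ̂)²/μ̂ / (n − k)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(np.sum((y - mu) ** 2 / mu) / (len(y) - k))


def pearson_dispersion(fit: FitResult, y: np.ndarray, X: np.ndarray) -> float:
    """Pearson dispersion of a fitted count model on its data."""
    mu = np.clip(np.exp(np.asarray(X, dtype=float) @ fit.coef), MU_FLOOR, None)
    return pearson_dispersion_from(y, mu, fit.n_params)


def quasi_aic(fit: FitResult, dispersion: float | None = None) -> float:
    """Quasi-AIC of a fitted count model (ordinary AIC for family poisson).

    When comparing nested models pass ``dispersion`` from the largest
    candidate so every model is scored on the same scale.
    """
    if fit.family == "poisson":
        return -2 * fit.loglik + 2 * fit.n_params
    phi = fit.dispersion if dispersion is None else dispersion
    if phi <= 0:
        raise ValueError("dispersion must be positive for quasi-AIC")
    return -2 * fit.loglik / phi + 2 * (fit.n_params + 1)


def linear_combination_ci(
    fit: FitResult, weights: np.ndarray, level: float = 0.95
):
    """Delta-method interval for wᵀβ on the linear-predictor (log) scale."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (fit.n_params,):
        raise ValueError(
            f"weights have shape {w.shape}, expected ({fit.n_params},)"
        )
    est = float(w @ fit.coef)
    var = float(w @ fit.vcov @ w)
    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(max(var, 0.0))
    return est, est - half, est + half


def wald_block_test(fit: FitResult, index: np.ndarray):
    """Wald chi-square test that a block of coefficients is jointly zero.

    Returns ``(statistic, df, p_value)`` using the (dispersion-scaled)
    covariance of the fit.
    """
    index = np.asarray(index)
    b = fit.coef[index]
    V = fit.vcov[np.ix_(index, index)]
    stat = float(b @ linalg.solve(V, b, assume_a="pos"))
    df = len(b)
    return stat, df, float(stats.chi2.sf(stat, df))
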