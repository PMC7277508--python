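"""Almon polynomial distributed-lag regression.

The distributed-lag model y_t = ε_t + Σ_{l=0}^{L} β_l x_{t−l} suffers from
heavy collinearity among adjacent lags of a smooth exposure series.  The
Almon device constrains the lag coefficients to a degree-p polynomial in
the lag,

    β_l = α_0 + α_1 l + … + α_p l^p,   l = 0…L,

which turns the regression into one on p+1 transformed columns
z_{t,j} = Σ_l l^j x_{t−l}.  Fitting is ordinary least squares (counts are
treated as continuous in this model family); the implied lag coefficients
and their covariance come from the exact linear map β = H α with
H[l, j] = l^j.

The polynomial is applied over l = 0…L, lag 0 (the event day) included.
Degree selection uses the Gaussian AIC across a candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import FitResult, fit_glm
from .timeseries_io import DailySeries, LagMatrix, ValidationError, build_lag_matrix

__all__ = ["AlmonFit", "almon_design", "fit_almon", "select_almon", "lag_table"]


def polynomial_map(L: int, p: int) -> np.ndarray:
    """H with H[l, j] = l^j mapping polynomial coefficients to lag coefficients."""
    return np.vander(np.arange(L + 1, dtype=float), p + 1, increasing=True)


@dataclass
class AlmonFit:
    """Polynomial-constrained distributed-lag OLS fit.

    ``beta_l = H @ alpha`` exactly and ``vcov_beta = H vcov_alpha Hᵀ``;
    standard errors of the lag coefficients are the square roots of the
    diagonal.
    """

    alpha: np.ndarray
    beta_l: np.ndarray
    vcov_beta: np.ndarray
    L: int
    p: int
    aic: float
    fit: FitResult = field(repr=False)
    intercept: bool = True
    saturated: bool = False  # p == L: constraint does not reduce dimension

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov_beta), 0, None))


def almon_design(lagmat: LagMatrix, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Transformed design Z = X_lag · H with incomplete-history rows excluded.

    Returns ``(Z, rows)`` where ``rows`` indexes the retained rows of the
    original series (complete lag history and no missing exposure cell).
    """
    if p > lagmat.L:
        raise ValidationError(f"polynomial degree p={p} exceeds max lag L={lagmat.L}")
    keep = lagmat.complete_rows()
    rows = np.where(keep)[0]
    H = polynomial_map(lagmat.L, p)
    Z = lagmat.values[rows] @ H
    return Z, rows


def fit_almon(
    series: DailySeries,
    L: int,
    p: int,
    intercept: bool = True,
    date_range: tuple | None = None,
) -> AlmonFit:
    """Fit the Almon DLM of counts on lagged exposure by OLS.

    ``date_range`` (start, end, inclusive) restricts the analysis window —
    lag history may reach before the window start if available in the
    series.
    """
    df = series.data
    x = series.o3_8h
    y = series.y.astype(float)
    lagmat = build_lag_matrix(x, L)
    Z, rows = almon_design(lagmat, p)
    yr = y[rows]
    if date_range is not None:
        start, end = pd.Timestamp(date_range[0]), pd.Timestamp(date_range[1])
        dates = df["date"].iloc[rows]
        m = ((dates >= start) & (dates <= end)).to_numpy()
        Z, yr = Z[m], yr[m]
    if len(yr) <= p + 2:
        raise ValidationError(
            f"insufficient rows (n={len(yr)}) for L={L}, p={p}"
        )
    labels = [f"z{j}" for j in range(p + 1)]
    if intercept:
        X = np.column_stack([np.ones(len(yr)), Z])
        labels = ["const"] + labels
    else:
        X = Z
    fit = fit_glm(yr, X, family="gaussian", column_labels=labels)
    a0 = 1 if intercept else 0
    alpha = fit.coef[a0:]
    vcov_alpha = fit.vcov[a0:, a0:]
    H = polynomial_map(L, p)
    beta = H @ alpha
    vcov_beta = H @ vcov_alpha @ H.T
    return AlmonFit(
        alpha=alpha,
        beta_l=beta,
        vcov_beta=vcov_beta,
        L=L,
        p=p,
        aic=fit.qaic,
        fit=fit,
        intercept=intercept,
        saturated=(p == L),
    )


def select_almon(
    series: DailySeries,
    L: int,
    p_candidates,
    intercept: bool = True,
    date_range: tuple | None = None,
) -> tuple[AlmonFit, pd.DataFrame]:
    """Fit every candidate polynomial degree and pick the AIC minimizer.

    Returns the best fit and the full comparison table (degree, AIC,
    parameter count).
    """
    p_candidates = list(p_candidates)
    if not p_candidates:
        raise ValidationError("empty candidate list")
    if any(p > L for p in p_candidates):
        raise ValidationError("all candidate degrees must be <= L")
    fits = [
        fit_almon(series, L, p, intercept=intercept, date_range=date_range)
        for p in p_candidates
    ]
    table = pd.DataFrame(
        {
            "p": p_candidates,
            "aic": [f.aic for f in fits],
            "n_params": [f.fit.n_params for f in fits],
            "n_obs": [f.fit.n_obs for f in fits],
        }
    )
    best = fits[int(np.argmin(table["aic"].to_numpy()))]
    return best, table


def lag_table(fit: AlmonFit, level: float = 0.95) -> pd.DataFrame:
    """Per-lag coefficient table (lag, beta, se, ci_low, ci_high)."""
    zq = stats.norm.ppf(0.5 + level / 2)
    se = fit.se_beta
    return pd.DataFrame(
        {
            "lag": np.arange(fit.L + 1),
            "beta": fit.beta_l,
            "se": se,
            "ci_low": fit.beta_l - zq * se,
            "ci_high": fit.beta_l + zq * se,
        }
    )
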