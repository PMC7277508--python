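"""Unconstrained distributed-lag quasi-Poisson regression.

The model regresses the log expected daily count on the L+1 lagged
exposure columns plus calendar and meteorological covariates:

    log E(y_t) = β_0 + Σ_{l=0}^{L} β_l x_{t−l}
                 + season + weekday + temp + rh + wind,

with astronomical-season indicators (winter reference), weekday
indicators (Monday reference), and same-day linear meteorology.  Fitting
is quasi-Poisson (see :mod:`lagrisk.glm`); the lag-specific relative risk
of an exposure increment Δx is RR_l = exp(Δx·β_l) with a delta-method
interval.

The default increment, one interquartile range of the daily max 8-h
ozone (50.3 µg/m³ in the motivating study window), can be overridden or
computed from the fitted window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import FitResult, fit_glm, linear_combination_ci
from .timeseries_io import (
    ASTRO_SEASONS,
    WEEKDAYS,
    DailySeries,
    ValidationError,
    build_lag_matrix,
)

logger = logging.getLogger("lagrisk")

__all__ = [
    "RRCurve",
    "PdlmFit",
    "DEFAULT_IQR_INCREMENT",
    "build_pdlm_design",
    "fit_poisson_dlm",
    "rr_per_increment",
]

#: Default RR increment: the study-window IQR of daily max 8-h ozone (µg/m³).
DEFAULT_IQR_INCREMENT = 50.3


@dataclass
class RRCurve:
    """Lag-indexed relative risk per exposure increment with 95% bounds."""

    lag: np.ndarray
    rr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    increment: float
    reference: float | None = None  # absent for the linear-lag model
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lag,
                "rr": self.rr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class PdlmFit:
    """Quasi-Poisson distributed-lag fit with column metadata."""

    fit: FitResult
    L: int
    lag_cols: np.ndarray  # design-column index of each lag coefficient
    column_labels: list[str]
    rows: np.ndarray = field(repr=False)
    exposure_iqr: float = float("nan")


def build_pdlm_design(
    series: DailySeries, L: int, covariates: bool = True
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix for the Poisson DLM.

    Columns: intercept | lagged exposure 0…L | season indicators (winter
    reference) | weekday indicators (Monday reference) | temp, rh, wind.
    Rows with incomplete lag history (the first L days) or any missing
    cell are dropped; factor levels absent from the analysis window are
    dropped with a warning.

    Returns ``(X, labels, rows)`` with ``rows`` the retained row indices.
    """
    df = series.data
    lagmat = build_lag_matrix(series.o3_8h, L)
    keep = lagmat.complete_rows()
    cols: list[np.ndarray] = [np.ones(len(df))]
    labels: list[str] = ["const"]
    for l in range(L + 1):
        cols.append(lagmat.values[:, l])
        labels.append(f"lag{l}")
    if covariates:
        for s in ASTRO_SEASONS:
            if s == "winter":
                continue
            cols.append((df["season_astro"] == s).to_numpy(dtype=float))
            labels.append(f"season[{s}]")
        for d in WEEKDAYS:
            if d == "Mon":
                continue
            cols.append((df["dow"] == d).to_numpy(dtype=float))
            labels.append(f"dow[{d}]")
        for name in ("temp", "rh", "wind"):
            cols.append(df[name].to_numpy(dtype=float))
            labels.append(name)
    X = np.column_stack(cols)
    keep &= ~np.isnan(X).any(axis=1)
    rows = np.where(keep)[0]
    dropped = len(df) - len(rows)
    if dropped:
        logger.info("dropped %d rows (lag history / missing data)", dropped)
    X = X[rows]
    # drop factor columns that are constant in the analysis window
    const = [
        j
        for j in range(X.shape[1])
        if labels[j] != "const" and np.ptp(X[:, j]) == 0
    ]
    if const:
        warnings.warn(
            "dropping constant column(s) in analysis window: "
            + ", ".join(labels[j] for j in const)
        )
        keep_cols = [j for j in range(X.shape[1]) if j not in const]
        X = X[:, keep_cols]
        labels = [labels[j] for j in keep_cols]
    return X, labels, rows


def fit_poisson_dlm(
    series: DailySeries,
    L: int,
    covariates: bool = True,
    family: str = "quasipoisson",
) -> PdlmFit:
    """Fit the distributed-lag count model; quasi-Poisson by default."""
    X, labels, rows = build_pdlm_design(series, L, covariates)
    if X.shape[0] <= X.shape[1] + 2:
        raise ValidationError(
            f"series too short: {X.shape[0]} rows for {X.shape[1]} parameters"
        )
    y = series.y[rows]
    fit = fit_glm(y, X, family=family, column_labels=labels)
    lag_cols = np.array([labels.index(f"lag{l}") for l in range(L + 1)])
    x_window = series.o3_8h[rows]
    q75, q25 = np.percentile(x_window, [75, 25])
    return PdlmFit(
        fit=fit,
        L=L,
        lag_cols=lag_cols,
        column_labels=labels,
        rows=rows,
        exposure_iqr=float(q75 - q25),
    )


def rr_per_increment(
    pdlm: PdlmFit,
    lags=None,
    increment: float | None = DEFAULT_IQR_INCREMENT,
    level: float = 0.95,
) -> RRCurve:
    """Relative risk per exposure increment at each requested lag.

    ``RR_l = exp(Δx·β_l)`` with a delta-method CI.  ``increment=None``
    uses the IQR of the exposure over the fitted window.
    """
    if lags is None:
        lags = np.arange(pdlm.L + 1)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags > pdlm.L):
        raise ValidationError(f"lags must lie in 0…{pdlm.L}")
    dx = pdlm.exposure_iqr if increment is None else float(increment)
    rr = np.empty(len(lags))
    lo = np.empty(len(lags))
    hi = np.empty(len(lags))
    for i, l in enumerate(lags):
        w = np.zeros(pdlm.fit.n_params)
        w[pdlm.lag_cols[l]] = dx
        est, a, b = linear_combination_ci(pdlm.fit, w, level)
        rr[i], lo[i], hi[i] = np.exp(est), np.exp(a), np.exp(b)
    return RRCurve(lag=lags, rr=rr, ci_low=lo, ci_high=hi, increment=dx, level=level)
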