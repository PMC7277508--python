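"""Polynomial, B-spline and natural cubic spline basis matrices.

These bases are the building blocks of every model in the package: the
polynomial map of the Almon constraint, B-spline smooths for meteorology,
and natural cubic splines for the ozone exposure-response, the lag-response
and the long-term seasonality term of the DLNM.  Knots are typically placed
at empirical percentiles of the data (linear-interpolation percentile
definition throughout).

A :class:`BasisSpec` describes a basis declaratively; :func:`evaluate_basis`
resolves it against data (percentile knots → values, data-range boundary →
numbers) and realizes the matrix, so the same resolved spec can later be
evaluated at new points — which is what relative-risk prediction needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "BasisMatrix",
    "percentile_knots",
    "polynomial_basis",
    "bspline_basis",
    "natural_cubic_spline_basis",
    "indicator_basis",
    "evaluate_basis",
]

BASIS_KINDS = ("linear", "polynomial", "bspline", "natural_spline", "indicator")


@dataclass(frozen=True)
class BasisSpec:
    """Declarative description of a one-dimensional basis.

    ``knots`` are interior knot *values* once resolved; before resolution
    they may be given as ``percentiles`` instead.  ``boundary`` is a pair of
    values or ``None`` meaning the data range.  ``intercept`` controls
    whether the basis spans constants on its own.
    """

    kind: str = "linear"
    degree: int = 3
    knots: tuple[float, ...] | None = None
    percentiles: tuple[float, ...] | None = None
    boundary: tuple[float, float] | None = None
    intercept: bool = False
    levels: int | None = None  # indicator basis only

    def __post_init__(self):
        if self.kind not in BASIS_KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.percentiles is not None:
            p = np.asarray(self.percentiles, dtype=float)
            if np.any((p <= 0) | (p >= 100)) or np.any(np.diff(p) <= 0):
                raise ValueError(
                    "percentiles must lie in (0, 100) and increase strictly"
                )
        if self.knots is not None and np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must increase strictly")

    def resolve(self, x: np.ndarray) -> "BasisSpec":
        """Resolve percentile knots and data-range boundary against ``x``."""
        x = np.asarray(x, dtype=float)
        knots = self.knots
        if knots is None and self.percentiles is not None:
            knots = tuple(percentile_knots(x, self.percentiles))
        boundary = self.boundary
        if boundary is None and self.kind in ("bspline", "natural_spline"):
            finite = x[np.isfinite(x)]
            boundary = (float(finite.min()), float(finite.max()))
        return replace(self, knots=knots, percentiles=None, boundary=boundary)

    @property
    def n_columns(self) -> int:
        """Column count of the realized matrix (deterministic in the spec)."""
        ic = 1 if self.intercept else 0
        if self.kind == "linear":
            return 1 + ic
        if self.kind == "polynomial":
            return self.degree + 1  # includes the constant column l^0
        if self.kind == "indicator":
            if self.levels is None:
                raise ValueError("indicator basis needs `levels`")
            return self.levels
        m = 0 if self.knots is None else len(self.knots)
        if self.kind == "bspline":
            return m + self.degree + ic
        # natural spline: m interior + 2 boundary knots → m + 1 (+ intercept)
        return m + 1 + ic


@dataclass
class BasisMatrix:
    """Realized basis: n×k matrix plus the resolved spec and column labels."""

    values: np.ndarray
    spec: BasisSpec
    column_labels: list[str] = field(default_factory=list)

    @property
    def shape(self):
        return self.values.shape


def percentile_knots(x: np.ndarray, percentiles) -> np.ndarray:
    """Empirical percentiles of ``x`` (linear-interpolation definition).

    Raises if the series is degenerate or ties collapse distinct
    percentiles onto one knot value.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("degenerate knot placement: series has < 2 distinct values")
    p = np.asarray(percentiles, dtype=float)
    if np.any((p <= 0) | (p >= 100)) or np.any(np.diff(p) <= 0):
        raise ValueError("percentiles must lie in (0, 100) and increase strictly")
    knots = np.percentile(x, p, method="linear")
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            f"degenerate knot placement: percentiles {tuple(p)} collapse to {knots}"
        )
    return knots


def polynomial_basis(l: np.ndarray, degree: int) -> BasisMatrix:
    """Vandermonde basis: columns l^0, l^1, …, l^degree."""
    if degree < 0:
        raise ValueError("polynomial degree must be >= 0")
    l = np.asarray(l, dtype=float)
    values = np.vander(l, degree + 1, increasing=True)
    spec = BasisSpec(kind="polynomial", degree=degree, intercept=True)
    return BasisMatrix(values, spec, [f"l^{j}" for j in range(degree + 1)])


def bspline_basis(
    x: np.ndarray,
    degree: int = 3,
    knots=(),
    boundary: tuple[float, float] | None = None,
    intercept: bool = False,
) -> BasisMatrix:
    """B-spline basis (Cox–de Boor) with given interior knots.

    With the intercept the rows form a partition of unity inside the
    boundary.  Points outside the boundary raise: B-splines do not
    extrapolate.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if boundary is None:
        boundary = (float(np.nanmin(x)), float(np.nanmax(x)))
    lo, hi = map(float, boundary)
    if knots.size and (knots.min() <= lo or knots.max() >= hi):
        raise ValueError("boundary must strictly enclose all interior knots")
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("B-spline evaluation outside boundary is not defined")
    t = np.concatenate([[lo] * (degree + 1), knots, [hi] * (degree + 1)])
    full = BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()
    spec = BasisSpec(
        kind="bspline",
        degree=degree,
        knots=tuple(knots),
        boundary=(lo, hi),
        intercept=intercept,
    )
    if not intercept:
        # dropping the first column removes the constant from the span
        values = full[:, 1:]
    else:
        values = full
    labels = [f"bs{j}" for j in range(values.shape[1])]
    return BasisMatrix(values, spec, labels)


def _natural_spline_columns(x: np.ndarray, all_knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic spline columns {x̃, N_1, …, N_{K-2}}.

    Standard construction: with knots ξ_1 < … < ξ_K (boundary included),
    d_k(x) = [(x−ξ_k)_+³ − (x−ξ_K)_+³] / (ξ_K − ξ_k) and
    N_k = d_k − d_{K−1}; each N_k has vanishing 2nd and 3rd derivatives
    outside the boundary, so the span is linear there.

    Evaluation happens on the knot-normalized scale
    x̃ = (x − ξ_1)/(ξ_K − ξ_1) to keep the cubic columns O(1): this is a
    fixed affine reparameterization determined by the boundary alone, so
    the spanned model space (given a model intercept) and every contrast
    R(x*) − R(x_ref) are unchanged while the design stays well
    conditioned.
    """
    xi = np.asarray(all_knots, dtype=float)
    lo, hi = xi[0], xi[-1]
    u = (np.asarray(x, dtype=float) - lo) / (hi - lo)
    xi = (xi - lo) / (hi - lo)
    K = xi.size

    def d(k):
        return (
            np.clip(u - xi[k], 0, None) ** 3 - np.clip(u - xi[K - 1], 0, None) ** 3
        ) / (xi[K - 1] - xi[k])

    dK1 = d(K - 2)
    cols = [u] + [d(k) - dK1 for k in range(K - 2)]
    return np.column_stack(cols)


def natural_cubic_spline_basis(
    x: np.ndarray,
    knots=(),
    boundary: tuple[float, float] | None = None,
    intercept: bool = False,
) -> BasisMatrix:
    """Natural cubic spline basis: cubic inside, linear beyond the boundary.

    Dimension is ``len(knots) + 1`` without intercept.  Evaluation outside
    the boundary is allowed (linear extrapolation) — this is what lets the
    ozone exposure-response be read off above the observed range.  With
    fewer than one interior knot the basis degrades to linear with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if boundary is None:
        boundary = (float(np.nanmin(x)), float(np.nanmax(x)))
    lo, hi = map(float, boundary)
    if knots.size < 1:
        warnings.warn("natural spline with no interior knot: using linear basis")
        spec = BasisSpec(kind="linear", intercept=intercept, boundary=(lo, hi))
        cols = [x]
        labels = ["x"]
    else:
        if knots.min() <= lo or knots.max() >= hi:
            raise ValueError("boundary must strictly enclose all interior knots")
        all_knots = np.concatenate([[lo], knots, [hi]])
        spec = BasisSpec(
            kind="natural_spline",
            knots=tuple(knots),
            boundary=(lo, hi),
            intercept=intercept,
        )
        cols = list(_natural_spline_columns(x, all_knots).T)
        labels = ["x"] + [f"ns{j}" for j in range(1, len(cols))]
    if intercept:
        cols = [np.ones_like(x)] + cols
        labels = ["const"] + labels
    return BasisMatrix(np.column_stack(cols), spec, labels)


def indicator_basis(x: np.ndarray, levels: int) -> BasisMatrix:
    """One column per integer level 0…levels−1 (used for lag indicators)."""
    x = np.asarray(x)
    values = np.zeros((x.shape[0], levels))
    for j in range(levels):
        values[:, j] = (x == j).astype(float)
    spec = BasisSpec(kind="indicator", levels=levels, intercept=True)
    return BasisMatrix(values, spec, [f"I{j}" for j in range(levels)])


def evaluate_basis(spec: BasisSpec, x: np.ndarray) -> BasisMatrix:
    """Realize a (resolved) spec at arbitrary points ``x``."""
    x = np.asarray(x, dtype=float)
    if spec.kind == "linear":
        cols = [x]
        labels = ["x"]
        if spec.intercept:
            cols = [np.ones_like(x)] + cols
            labels = ["const"] + labels
        return BasisMatrix(np.column_stack(cols), spec, labels)
    if spec.kind == "polynomial":
        return polynomial_basis(x, spec.degree)
    if spec.kind == "indicator":
        return indicator_basis(x, spec.levels)
    if spec.knots is None or spec.boundary is None:
        raise ValueError("spec must be resolved (knots and boundary as values)")
    if spec.kind == "bspline":
        return bspline_basis(
            x, spec.degree, spec.knots, spec.boundary, spec.intercept
        )
    return natural_cubic_spline_basis(x, spec.knots, spec.boundary, spec.intercept)
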