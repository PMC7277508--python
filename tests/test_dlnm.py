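import numpy as np
import pytest

import lagrisk as lr
from lagrisk.basis import BasisSpec, evaluate_basis
from lagrisk.dlnm import (
    DEFAULT_LAG_KNOTS,
    DlnmModelSpec,
    cross_basis,
)
from lagrisk.timeseries_io import ValidationError, build_lag_matrix


def _linear_exposure():
    return BasisSpec(kind="linear")


def _indicator_lags(L):
    return BasisSpec(kind="indicator", levels=L + 1)


class TestCrossBasis:
    def test_identity_times_indicators_reduces_to_lag_matrix(self, rng):
        x = rng.uniform(0, 100, 80)
        L = 6
        cb = cross_basis(x, L, _linear_exposure(), _indicator_lags(L))
        lm = build_lag_matrix(x, L)
        rows = lm.complete_rows()
        np.testing.assert_allclose(cb.values[rows], lm.values[rows], atol=1e-12)

    def test_identity_times_constant_is_moving_sum(self, rng):
        x = rng.uniform(0, 100, 60)
        L = 21
        cb = cross_basis(
            x, L, _linear_exposure(), BasisSpec(kind="polynomial", degree=0)
        )
        assert cb.values.shape[1] == 1
        rows = np.where(cb.complete_rows())[0]
        for t in rows[:10]:
            assert cb.values[t, 0] == pytest.approx(x[t - L : t + 1].sum())

    def test_every_cell_matches_brute_force_double_sum(self, rng):
        x = rng.uniform(10, 150, 70)
        L = 21
        espec = BasisSpec(kind="natural_spline", percentiles=(10, 50, 90))
        lspec = BasisSpec(kind="natural_spline", knots=DEFAULT_LAG_KNOTS, intercept=True)
        cb = cross_basis(x, L, espec, lspec)
        R = evaluate_basis(cb.exposure_spec, x).values
        C = evaluate_basis(cb.lag_spec, np.arange(L + 1, dtype=float)).values
        rows = np.where(cb.complete_rows())[0]
        for t in rows:
            for j in range(cb.Jx):
                for k in range(cb.Jl):
                    cell = sum(R[t - l, j] * C[l, k] for l in range(L + 1))
                    assert abs(cb.values[t, j * cb.Jl + k] - cell) < 1e-10

    def test_incomplete_history_rows_flagged(self, rng):
        x = rng.uniform(0, 100, 50)
        cb = cross_basis(x, 10, _linear_exposure(), _indicator_lags(10))
        assert not cb.complete_rows()[:10].any()
        assert cb.complete_rows()[10:].all()


class TestFitAndPredict:
    def test_rr_at_reference_is_exactly_one(self, headline):
        series, _ = headline
        fit = lr.fit_dlnm(series, DlnmModelSpec().with_percentiles((10, 50, 90)))
        curve = lr.predict_lag_rr(fit, x_star=120.0, x_ref=120.0)
        np.testing.assert_allclose(curve.rr, 1.0, atol=1e-12)
        np.testing.assert_allclose(curve.ci_low, 1.0, atol=1e-12)

    def test_knot_variant_selection_returns_lower_qaic(self, headline):
        series, _ = headline
        best = lr.fit_dlnm(series)
        assert best.selection_table is not None
        table = best.selection_table
        assert len(table) == 2
        assert best.fit.qaic == pytest.approx(table["qaic"].min())

    def test_reduction_reproduces_poisson_dlm(self, headline):
        series, _ = headline
        L = 21
        pdlm = lr.fit_poisson_dlm(series, L)
        spec = DlnmModelSpec(
            exposure_spec=_linear_exposure(),
            lag_spec=_indicator_lags(L),
            covariate_style="linear",
            L=L,
        )
        dfit = lr.fit_dlnm(series, spec)
        # match coefficients by label: cb[x0,lk] <-> lagk
        for l in range(L + 1):
            j_d = dfit.fit.column_labels.index(f"cb[x0,l{l}]")
            j_p = pdlm.column_labels.index(f"lag{l}")
            assert abs(dfit.fit.coef[j_d] - pdlm.fit.coef[j_p]) < 1e-8
        rr_d = lr.predict_lag_rr(dfit, x_star=130.0, x_ref=120.0)
        rr_p = lr.rr_per_increment(pdlm, increment=10.0)
        np.testing.assert_allclose(rr_d.rr, rr_p.rr, atol=1e-8)
        np.testing.assert_allclose(rr_d.ci_low, rr_p.ci_low, atol=1e-7)

    def test_log_rr_proportional_to_increment_for_linear_basis(self, headline):
        series, _ = headline
        spec = DlnmModelSpec(
            exposure_spec=_linear_exposure(), lag_spec=_indicator_lags(21),
            covariate_style="linear",
        )
        dfit = lr.fit_dlnm(series, spec)
        c1 = lr.predict_lag_rr(dfit, x_star=130.0, x_ref=120.0)
        c3 = lr.predict_lag_rr(dfit, x_star=150.0, x_ref=120.0)
        np.testing.assert_allclose(np.log(c3.rr), 3 * np.log(c1.rr), atol=1e-10)

    def test_spec_hash_mismatch_rejected(self, headline, rng):
        series, _ = headline
        dfit = lr.fit_dlnm(series, DlnmModelSpec().with_percentiles((10, 50, 90)))
        other = cross_basis(
            rng.uniform(0, 100, len(series)), 21,
            BasisSpec(kind="natural_spline", percentiles=(10, 75, 90)),
            BasisSpec(kind="natural_spline", knots=DEFAULT_LAG_KNOTS, intercept=True),
        )
        with pytest.raises(ValidationError, match="match"):
            lr.predict_lag_rr(dfit, crossbasis=other)

    @staticmethod
    def _surface_rmse(n_days, seed):
        # truth built FROM the model's own bases: estimation error only
        rng = np.random.default_rng(seed)
        env = lr.simulate_environment(n_days, seed=rng)
        x = env.o3_8h
        L = 21
        espec = BasisSpec(kind="natural_spline", percentiles=(10, 50, 90)).resolve(x)
        lspec = BasisSpec(
            kind="natural_spline", knots=DEFAULT_LAG_KNOTS, intercept=True
        ).resolve(np.arange(L + 1.0))
        eta = np.array([[0.3, -0.1, 0.05, 0.02, -0.04],
                        [0.1, 0.05, -0.02, 0.01, 0.0],
                        [-0.05, 0.02, 0.01, 0.0, 0.01],
                        [0.02, -0.01, 0.0, 0.01, 0.0]]) * 0.5
        cb = cross_basis(x, L, espec, lspec)
        rows = np.where(cb.complete_rows())[0]
        ref = 120.0
        Rref = evaluate_basis(espec, np.array([ref])).values[0]
        C = evaluate_basis(lspec, np.arange(L + 1.0)).values
        offset = float(Rref @ eta @ C.sum(axis=0))
        lin = cb.values[rows] @ eta.ravel() - offset
        y = np.zeros(len(env), dtype=np.int64)
        y[rows] = rng.poisson(np.exp(np.log(8.0) + lin))
        s = lr.DailySeries(env.data.assign(y=y)[["date", "y", "o3_8h", "temp", "rh", "wind"]])
        dfit = lr.fit_dlnm(s, DlnmModelSpec(covariate_style="none").with_percentiles((10, 50, 90)))
        errs = []
        for xs in np.linspace(60, 150, 7):
            true_lrr = (evaluate_basis(espec, np.array([xs])).values[0] - Rref) @ eta @ C.T
            est = np.log(lr.predict_lag_rr(dfit, x_star=xs, x_ref=ref).rr)
            errs.append(est - true_lrr)
        return np.sqrt(np.mean(np.square(errs)))

    def test_surface_recovery_for_truth_inside_span(self):
        # averaged over a few seeds: a stable estimate of the expected
        # estimation error at the design's sample size
        rmse = np.mean([self._surface_rmse(600, s) for s in range(29, 34)])
        assert rmse < 0.05

    def test_surface_rmse_shrinks_with_sample_size(self):
        small = np.mean([self._surface_rmse(600, s) for s in range(29, 32)])
        big = np.mean([self._surface_rmse(5000, s) for s in range(29, 32)])
        assert big < small

    def test_overparameterized_spec_rejected(self):
        env = lr.simulate_environment(70, seed=3)
        with pytest.raises(ValidationError):
            lr.fit_dlnm(env, DlnmModelSpec().with_percentiles((10, 50, 90)))


class TestCumulativeRR:
    def test_singleton_window_equals_lag_prediction(self, headline):
        series, _ = headline
        dfit = lr.fit_dlnm(series, DlnmModelSpec().with_percentiles((10, 50, 90)))
        curve = lr.predict_lag_rr(dfit, x_star=130.0, x_ref=120.0)
        rr, (lo, hi) = lr.overall_cumulative_rr(
            dfit, x_star=130.0, x_ref=120.0, lag_window=[2]
        )
        assert rr == pytest.approx(curve.rr[2], abs=1e-12)
        assert lo == pytest.approx(curve.ci_low[2], abs=1e-12)

    def test_reference_contrast_is_unity(self, headline):
        series, _ = headline
        dfit = lr.fit_dlnm(series, DlnmModelSpec().with_percentiles((10, 50, 90)))
        rr, _ = lr.overall_cumulative_rr(dfit, x_star=120.0, x_ref=120.0)
        assert rr == pytest.approx(1.0, abs=1e-12)

    def test_empty_window_rejected(self, headline):
        series, _ = headline
        dfit = lr.fit_dlnm(series, DlnmModelSpec().with_percentiles((10, 50, 90)))
        with pytest.raises(ValidationError):
            lr.overall_cumulative_rr(dfit, lag_window=[])

    def test_interval_matches_parametric_bootstrap(self, headline):
        series, _ = headline
        dfit = lr.fit_dlnm(series, DlnmModelSpec().with_percentiles((10, 50, 90)))
        rr, (lo, hi) = lr.overall_cumulative_rr(
            dfit, x_star=130.0, x_ref=120.0, lag_window=range(4)
        )
        W = dfit.crossbasis.contrast_weights(130.0, 120.0)[:4].sum(axis=0)
        w = np.zeros(dfit.fit.n_params)
        w[dfit.cb_cols] = W
        rng = np.random.default_rng(1)
        draws = (
            rng.multivariate_normal(
                dfit.fit.coef, dfit.fit.vcov, size=2000, check_valid="ignore"
            )
            @ w
        )
        se = np.sqrt(w @ dfit.fit.vcov @ w)
        tol = 0.25 * se  # ~4 MC-SE of a tail quantile at 2000 draws
        assert abs(np.log(lo) - np.quantile(draws, 0.025)) < tol
        assert abs(np.log(hi) - np.quantile(draws, 0.975)) < tol
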