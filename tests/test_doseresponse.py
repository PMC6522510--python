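"""Constrained 4PL fitting, the spline-AUC fallback, and fixed-slope Kd fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import screenkit as sk
from screenkit._errors import DataError, FitError, IC50UndefinedError
from screenkit.doseresponse import (
    LOG10_E_BOUNDS,
    SLOPE_BOUNDS,
    fit_spline_auc,
    grid_oracle_sse,
    top_dose_weights,
)

from conftest import random_truth

DESIGN = sk.DoseDesign.ten_point()
X10 = DESIGN.as_array()


def analytic_auc(b, c, d, e, xmin, xmax):
    """Independent numerical-integration oracle for the 4PL mean activity."""
    lo, hi = np.log10(xmin), np.log10(xmax)
    val, _ = quad(lambda t: sk.eval_4pl(b, c, d, e, 10.0**t), lo, hi, limit=200)
    return val / (hi - lo)


class TestEval4PL:
    @given(
        b=st.floats(-10, -0.1),
        c=st.floats(0, 120),
        d=st.floats(0, 120),
        loge=st.floats(-9.5, -4.5),
    )
    def test_midpoint_identity(self, b, c, d, loge):
        assert sk.eval_4pl(b, c, d, 10**loge, 10**loge) == pytest.approx((c + d) / 2)

    def test_zero_slope_is_constant(self):
        vals = sk.eval_4pl(0.0, 80.0, 20.0, 1e-7, X10)
        np.testing.assert_allclose(vals, 50.0)

    def test_closed_form_point(self):
        # b=-1, c=100, d=0, e=1e-7: one decade below the midpoint the curve
        # reads 100/(1 + 1/10) = 90.909...; one decade above, 9.0909...
        assert sk.eval_4pl(-1, 100, 0, 1e-7, 1e-8) == pytest.approx(1000 / 11)
        assert sk.eval_4pl(-1, 100, 0, 1e-7, 1e-6) == pytest.approx(100 / 11)

    def test_limits(self):
        assert sk.eval_4pl(-2, 95, 5, 1e-7, 1e-15) == pytest.approx(95, abs=1e-6)
        assert sk.eval_4pl(-2, 95, 5, 1e-7, 1e1) == pytest.approx(5, abs=1e-6)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DataError):
            sk.eval_4pl(-1, 100, 0, 1e-7, 0.0)
        with pytest.raises(DataError):
            sk.eval_4pl(-1, 100, 0, -1e-7, 1e-7)


class TestFit4PL:
    def test_noiseless_self_consistency_to_six_digits(self):
        truth = (-1.5, 100.0, 5.0, 3e-8)
        y = sk.eval_4pl(*truth, X10)
        fit = sk.fit_4pl(X10, y)
        assert fit.converged and fit.mode == "sigmoid"
        for got, want in zip((fit.b, fit.c, fit.d, fit.e), truth):
            assert abs(got - want) / abs(want) < 5e-7

    def test_constant_response_signals_nonconvergence(self):
        fit = sk.fit_4pl(X10, np.full_like(X10, 100.0))
        assert not fit.converged

    def test_insufficient_distinct_concentrations(self):
        with pytest.raises(FitError):
            sk.fit_4pl([1e-9, 1e-8, 1e-7], [100, 50, 10])

    def test_constraints_hold_and_oracle_dominated(self):
        """Every converged fit satisfies the box constraints exactly and
        achieves a weighted SSE no larger than the brute-force grid oracle."""
        rng = np.random.default_rng(2024)
        for i in range(20):
            t = random_truth(rng)
            tab = sk.simulate_dose_response(t, "L", DESIGN, replicates=3,
                                            noise_sigma=0.05, seed=7000 + i)
            x, y = tab.concentration_M.to_numpy(), tab.response_pct.to_numpy()
            fit = sk.fit_4pl(x, y)
            assert fit.converged
            assert SLOPE_BOUNDS[0] <= fit.b <= SLOPE_BOUNDS[1]
            assert 0.0 <= fit.c <= fit.a_max and 0.0 <= fit.d <= fit.a_max
            assert LOG10_E_BOUNDS[0] <= fit.log10_e <= LOG10_E_BOUNDS[1]
            assert fit.weighted_sse <= grid_oracle_sse(x, y) + 1e-9

    def test_scale_equivariance(self):
        """Multiplying all concentrations by 10 multiplies the fitted e by 10
        and leaves b, c, d unchanged."""
        y = sk.eval_4pl(-1.2, 98.0, 3.0, 4e-8, X10)
        f1 = sk.fit_4pl(X10, y)
        f2 = sk.fit_4pl(X10 * 10.0, y)
        assert f2.e / f1.e == pytest.approx(10.0, rel=1e-6)
        for a, b_ in ((f1.b, f2.b), (f1.c, f2.c), (f1.d, f2.d)):
            assert a == pytest.approx(b_, rel=1e-6, abs=1e-8)

    def test_top_dose_downweighting_protects_the_midpoint(self):
        """Corrupting only the top-concentration response moves the fitted
        log10 e less under 10% weighting than under uniform weighting."""
        truth = (-1.5, 100.0, 0.0, 1e-7)
        y = np.array(sk.eval_4pl(*truth, X10))
        y[-1] = 80.0  # rebound artifact at the highest dose
        shift_w = abs(sk.fit_4pl(X10, y, weights_rule="top10pct").log10_e - np.log10(1e-7))
        shift_u = abs(sk.fit_4pl(X10, y, weights_rule="uniform").log10_e - np.log10(1e-7))
        assert shift_w < shift_u

    def test_weight_vector(self):
        w = top_dose_weights(np.repeat(X10, 3))
        assert (w[-3:] == 0.1).all() and (w[:-3] == 1.0).all()


class TestFallbackAndAUC:
    def test_clean_sigmoid_stays_sigmoid(self):
        y = sk.eval_4pl(-1.0, 100.0, 0.0, 1e-7, X10)
        assert sk.fit_curve(X10, y).mode == "sigmoid"

    def test_bell_shaped_data_triggers_spline_fallback(self):
        y = np.array([100.0, 100, 100, 40, 10, 10, 40, 100, 100, 100])
        fit = sk.fit_curve(X10, y)
        assert fit.mode == "spline_fallback"
        assert fit.b is None and fit.e is None
        assert np.isfinite(fit.auc)

    def test_spline_auc_matches_analytic_sigmoid_auc(self):
        """On noiseless sigmoid data the spline path and the analytic 4PL
        integral agree within 2%."""
        params = (-1.5, 100.0, 0.0, 1e-7)
        y = sk.eval_4pl(*params, X10)
        spline = fit_spline_auc(X10, y)
        target = analytic_auc(*params, X10.min(), X10.max())
        assert abs(spline.auc - target) / target < 0.02

    @pytest.mark.parametrize("level", [100.0, 0.0])
    def test_constant_curve_auc(self, level):
        assert sk.curve_auc(lambda x: np.full_like(np.asarray(x, float), level),
                            DESIGN) == pytest.approx(level, abs=1e-9)

    def test_symmetric_sigmoid_auc_is_half(self):
        # midpoint at the geometric centre of the tested range, c=100, d=0
        auc = sk.curve_auc(lambda x: sk.eval_4pl(-1.0, 100.0, 0.0, 1e-7, x), DESIGN)
        assert auc == pytest.approx(50.0, abs=0.1)

    def test_auc_bounds_on_nonnegative_curves(self):
        rng = np.random.default_rng(5)
        for i in range(10):
            t = random_truth(rng)
            tab = sk.simulate_dose_response(t, "L", DESIGN, replicates=3,
                                            noise_sigma=0.05, seed=8000 + i)
            fit = sk.fit_curve(tab.concentration_M.to_numpy(),
                               tab.response_pct.to_numpy())
            assert 0.0 <= fit.auc <= tab.response_pct.max() + 1e-9

    def test_degenerate_range_rejected(self):
        with pytest.raises(DataError):
            sk.curve_auc(lambda x: x, [1e-7, 1e-7])

    def test_fewer_than_four_points_rejected(self):
        with pytest.raises(FitError):
            sk.fit_curve([1e-9, 1e-8, 1e-7], [100, 50, 10])


class TestRelativeIC50:
    def test_definitional(self):
        fit = sk.FourPLFit(mode="sigmoid", converged=True, auc=50.0,
                           b=-1.0, c=100.0, d=0.0, e=4.5e-8, log10_e=np.log10(4.5e-8))
        assert sk.relative_ic50(fit) == 4.5e-8

    def test_noiseless_45_nM_curve_recovered(self):
        """An AMKL-line JAK-inhibitor-style curve with a 45 nM midpoint is
        recovered exactly from noiseless data."""
        y = sk.eval_4pl(-1.2, 100.0, 0.0, 45e-9, X10)
        fit = sk.fit_curve(X10, y)
        assert sk.relative_ic50(fit) == pytest.approx(45e-9, rel=1e-6)

    def test_spline_fallback_has_no_ic50(self):
        fit = sk.FourPLFit(mode="spline_fallback", converged=False, auc=60.0)
        with pytest.raises(IC50UndefinedError):
            sk.relative_ic50(fit)


class TestHillKd:
    XS = np.geomspace(1e-12, 1e-8, 8)

    def test_fitted_curve_midpoint_identity(self):
        y = 100.0 / (1.0 + self.XS / 5.4e-11)
        fit = sk.fit_hill_kd(self.XS, y)
        assert fit(fit.kd) == pytest.approx((fit.top + fit.bottom) / 2)

    def test_subnanomolar_kd_recovered(self):
        # catalytic-domain binding truth: Kd = 0.054 nM
        y = 5.0 + 95.0 / (1.0 + self.XS / 5.4e-11)
        fit = sk.fit_hill_kd(self.XS, y)
        assert fit.kd == pytest.approx(5.4e-11, rel=1e-3)
        assert fit.slope == -1.0

    def test_constant_signal_rejected(self):
        with pytest.raises(FitError):
            sk.fit_hill_kd(self.XS, np.full_like(self.XS, 7.0))
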