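"""Finite-size model fits: exact recovery, nesting, honest uncertainties."""

import numpy as np
import pytest

import sba
from sba import fits


GRID = np.geomspace(0.02, 1.0, 120)
WINDOW = (0.04, 0.3)


def synthetic(chi_inf=0.0295, c1=0.415, c2=0.0, noise=0.0, seed=0, L0=48.83):
    return sba.generate_synthetic_curve(
        sba.SyntheticCurveSpec(chi_inf=chi_inf, c1=c1, c2=c2, L0=L0,
                               lambda_grid=GRID, seed=seed, noise_sd=noise)
    )


class TestLinearFit:
    def test_noiseless_recovery_to_six_digits(self):
        fit = sba.fit_chi_linear(synthetic(), WINDOW)
        assert fit.params["chi_inf"] == pytest.approx(0.0295, rel=1e-8)
        assert fit.params["c"] == pytest.approx(0.415, rel=1e-8)

    def test_ideal_gas_curve_gives_unit_chi_and_zero_c(self, ideal_traj):
        grid = sba.default_lambda_grid(ideal_traj.box_edge, n=40)
        curve = sba.fluctuation_curve(ideal_traj, grid, 100, seed=8)
        fit = sba.fit_chi_linear(curve, window=(0.1, 0.3))
        assert fit.params["chi_inf"] == pytest.approx(1.0, abs=0.1)
        assert fit.params["c"] == pytest.approx(0.0, abs=0.3)

    def test_agrees_with_statsmodels_wls(self):
        # independent regression route on the same basis
        sm = pytest.importorskip("statsmodels.api")
        curve = synthetic(noise=5e-4, seed=11)
        fit = sba.fit_chi_linear(curve, WINDOW)
        lam = curve.lambda_grid
        m = (lam >= WINDOW[0]) & (lam <= WINDOW[1])
        X = np.column_stack([lam[m] * (1 - lam[m] ** 3), np.ones(m.sum())])
        w = 1.0 / curve.stderr[m] ** 2
        res = sm.WLS(curve.values[m], X, weights=w).fit()
        assert fit.params["chi_inf"] == pytest.approx(res.params[0], rel=1e-10)
        assert fit.params["c"] == pytest.approx(res.params[1] * 48.83, rel=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            sba.fit_chi_linear(synthetic(), window=(0.28, 0.3))


class TestInverseTermFit:
    def test_noiseless_three_parameter_recovery(self):
        curve = synthetic(c2=0.5)
        fit = sba.fit_chi_with_inverse_term(curve, WINDOW)
        assert fit.params["chi_inf"] == pytest.approx(0.0295, rel=1e-8)
        assert fit.params["c"] == pytest.approx(0.415, rel=1e-8)
        assert fit.params["b2"] == pytest.approx(0.5 / 48.83**2, rel=1e-6)

    def test_nesting_b2_zero_data(self):
        # on data generated without the 1/lambda term the extended fit finds
        # b2 ~ 0 and the same chi_inf as the two-parameter fit
        curve = synthetic()
        lin = sba.fit_chi_linear(curve, WINDOW)
        ext = sba.fit_chi_with_inverse_term(curve, WINDOW)
        assert abs(ext.params["b2"]) < 1e-12
        assert ext.params["chi_inf"] == pytest.approx(lin.params["chi_inf"],
                                                      abs=1e-9)

    def test_inverse_term_detected_when_present(self):
        # near-critical behavior: a material 1/lambda contribution must be
        # picked up, and ignoring it must bias the two-parameter fit
        curve = synthetic(c2=3.0, noise=1e-4, seed=21)
        ext = sba.fit_chi_with_inverse_term(curve, WINDOW)
        b2_true = 3.0 / 48.83**2
        assert ext.params["b2"] == pytest.approx(b2_true, rel=0.2)
        assert abs(ext.params["b2"]) > 5 * ext.stderr["b2"]
        lin = sba.fit_chi_linear(curve, WINDOW)
        assert abs(lin.params["chi_inf"] - 0.0295) > abs(
            ext.params["chi_inf"] - 0.0295
        )


class TestKBIFit:
    @staticmethod
    def curve_set(G_inf, alpha, rho_a=0.432, noise=0.0, seed=0, L0=48.83):
        cur = sba.generate_synthetic_kbi_curve(
            G_inf, alpha, L0, GRID, seed=seed, rho_i=rho_a, noise_sd=noise
        )
        return sba.KBICurveSet(
            lambda_grid=GRID, species=["A"],
            values={("A", "A"): cur.values / GRID},
            stderr={("A", "A"): cur.stderr / GRID},
            n_blocks=np.zeros(GRID.size, dtype=int),
            rho={"A": rho_a}, system={"L0": L0},
        )

    def test_noiseless_recovery(self):
        res = sba.fit_kbi(self.curve_set(-0.5, 0.3), WINDOW)[("A", "A")]
        assert res.params["G_inf"] == pytest.approx(-0.5, rel=1e-8)
        assert res.params["alpha"] == pytest.approx(0.3, rel=1e-8)

    def test_ideal_binary_extrapolates_to_zero(self, ideal_binary_traj):
        grid = sba.default_lambda_grid(ideal_binary_traj.box_edge,
                                       min_block_edge=2.0, n=30)
        curves = sba.kbi_curve(ideal_binary_traj, grid, 200, seed=6)
        res = sba.fit_kbi(curves, window=(0.2, 0.45))
        for pair, fit in res.items():
            tol = 4 * fit.stderr["G_inf"] + 0.05
            assert abs(fit.params["G_inf"]) < tol
            assert abs(fit.params["alpha"]) < 4 * fit.stderr["alpha"] + 0.6


class TestPredict:
    def test_model_value_at_lambda_one_with_zero_c(self):
        fit = sba.FitResult(
            model_id="linear_lambda", params={"chi_inf": 0.5, "c": 0.0},
            stderr={}, window=(0.05, 0.3), n_points=10, L0=20.0,
            residual_rms=0.0,
        )
        assert sba.predict_model(fit, np.array([1.0]))[0] == 0.0

    def test_kbi_self_term_evaluation(self):
        # G_inf = 0, alpha = 0, diagonal: lambda*G = -lambda^4/rho
        fit = sba.FitResult(
            model_id="kbi", params={"G_inf": 0.0, "alpha": 0.0}, stderr={},
            window=(0.05, 0.3), n_points=10, L0=20.0, residual_rms=0.0,
            pair=("A", "A"), rho_i=0.432, diagonal=True,
        )
        val = sba.predict_model(fit, np.array([0.5]))[0]
        assert val == pytest.approx(-0.5**4 / 0.432, rel=1e-12)
        assert val == pytest.approx(-0.144675925925926, abs=1e-12)

    def test_predict_then_refit_is_idempotent(self):
        curve = synthetic(c2=0.2)
        fit = sba.fit_chi_with_inverse_term(curve, WINDOW)
        lam = curve.lambda_grid
        refit_curve = sba.FluctuationCurve(
            lambda_grid=lam, values=sba.predict_model(fit, lam),
            stderr=np.zeros_like(lam), n_blocks=np.zeros_like(lam),
            system={"L0": fit.L0}, scaled=True,
        )
        refit = sba.fit_chi_with_inverse_term(refit_curve, WINDOW)
        for k in fit.params:
            assert refit.params[k] == pytest.approx(fit.params[k], rel=1e-9,
                                                    abs=1e-12)

    def test_inverse_model_rejects_nonpositive_lambda(self):
        curve = synthetic(c2=0.2)
        fit = sba.fit_chi_with_inverse_term(curve, WINDOW)
        with pytest.raises(ValueError):
            sba.predict_model(fit, np.array([0.0, 0.5]))

    def test_full_range_overlay_on_ideal_gas_data(self, ideal_traj):
        # the fitted small-window model superimposes on the data over the
        # whole 0 < lambda < 1 range for a well-sampled system
        grid = sba.default_lambda_grid(ideal_traj.box_edge, n=40)
        curve = sba.fluctuation_curve(ideal_traj, grid, 100, seed=12)
        fit = sba.fit_chi_linear(curve, window=(0.1, 0.3))
        pred = sba.predict_model(fit, grid)
        y, sd = curve.scaled_values()
        ok = np.abs(pred - y) <= 3 * np.maximum(sd, 1e-4)
        assert ok.mean() >= 0.9


class TestWindows:
    def test_window_sensitivity_within_uncertainty(self):
        curve = synthetic(noise=3e-4, seed=31)
        f1 = sba.fit_chi_linear(curve, window=(0.04, 0.2))
        f2 = sba.fit_chi_linear(curve, window=(0.04, 0.3))
        comb = np.hypot(f1.stderr["chi_inf"], f2.stderr["chi_inf"])
        assert abs(f1.params["chi_inf"] - f2.params["chi_inf"]) < 2 * comb

    def test_default_window_floors_at_two_sigma(self):
        lo, hi = fits.default_window(40.0)
        assert lo == pytest.approx(2.0 / 40.0)
        assert hi == 0.3
        lo_g, _ = fits.default_window(40.0, zeta_guard=6.0)
        assert lo_g == pytest.approx(6.0 / 40.0)

    def test_degenerate_window_raises(self):
        with pytest.raises(ValueError):
            fits.default_window(5.0)  # 2/L0 = 0.4 > 0.3
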