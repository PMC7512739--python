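"""Thermodynamic conversions and chemical-potential integration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sba
from sba import thermo


class TestKappa:
    def test_ideal_gas_compressibility(self):
        assert sba.kappa_from_chi(1.0, 0.5, 1.2) == pytest.approx(1 / 0.6)

    def test_reference_state_point(self):
        # chi_inf = 0.0295 at rho = 0.864, kT = 1.2
        k = sba.kappa_from_chi(0.0295, 0.864, 1.2)
        assert k == pytest.approx(0.0295 / (0.864 * 1.2), rel=1e-12)
        assert k == pytest.approx(0.0284529320987654, abs=1e-12)

    def test_incompressible_limit(self):
        assert sba.kappa_from_chi(0.0, 0.5, 1.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sba.kappa_from_chi(1.0, -0.5, 1.0)

    def test_kbi_route_all_zero_is_ideal_mixture(self):
        k = sba.kappa_from_kbi(0, 0, 0, 0.4, 0.6, 1.2)
        assert k == pytest.approx(1.0 / (1.2 * 1.0), rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        gaa=st.floats(-1.0, 1.0),
        gbb=st.floats(-1.0, 1.0),
        gab=st.floats(-1.0, 1.0),
        rho_a=st.floats(0.1, 1.2),
    )
    def test_pure_limit_reduces_to_single_component(self, gaa, gbb, gab, rho_a):
        # rhoB -> 0: kappa = (1 + rhoA G_AA) / (kBT rhoA), for any G values
        k = sba.kappa_from_kbi(gaa, gbb, gab, rho_a, 0.0, 1.2)
        assert k == pytest.approx((1 + rho_a * gaa) / (1.2 * rho_a), rel=1e-12)

    def test_unstable_denominator_raises(self):
        # choose G values that null the denominator
        # rhoA + rhoB + rhoA rhoB (G_AA + G_BB - 2 G_AB) = 2 - 2 = 0
        with pytest.raises(ValueError, match="unstable"):
            sba.kappa_from_kbi(-1.0, -1.0, 0.0, 1.0, 1.0, 1.0)


class TestMuDerivative:
    def test_ideal_limit(self):
        assert sba.dmuA_drhoA(0.0, 0.0, 0.5, 1.2) == pytest.approx(2.4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(g=st.floats(-2.0, 2.0), rho_a=st.floats(0.1, 1.2))
    def test_only_difference_matters(self, g, rho_a):
        # shifting both KBIs by the same amount leaves the derivative ideal
        assert sba.dmuA_drhoA(g, g, rho_a, 1.2) == pytest.approx(
            1.2 / rho_a, rel=1e-12
        )

    def test_worked_value(self):
        # kT [1/rhoA + dG / (1 - rhoA dG)] with dG = G_AB - G_AA = 0.5
        v = sba.dmuA_drhoA(0.0, 0.5, 0.4, 1.2)
        assert v == pytest.approx(1.2 * (2.5 + 0.5 / 0.8), rel=1e-12)
        assert v == pytest.approx(3.75, abs=1e-12)

    def test_demixing_pole_raises(self):
        # 1 + rhoA (G_AA - G_AB) = 1 + 0.5 * (-2) = 0
        with pytest.raises(ValueError, match="demixing"):
            sba.dmuA_drhoA(-2.0, 0.0, 0.5, 1.0)


class TestIntegrateMu:
    def test_ideal_gas_quadrature_matches_log(self):
        rho = np.linspace(0.2, 1.0, 101)  # 0.6 is a grid node
        table = sba.CompressibilityTable(rho=rho, chi_inf=np.ones(101), kT=1.2)
        curve = sba.integrate_mu(table, 0.6)
        exact = 1.2 * np.log(rho / 0.6)
        assert np.abs(curve.delta_mu - exact).max() < 1e-6
        i0 = np.argmin(np.abs(rho - 0.6))
        assert curve.delta_mu[i0] == 0.0

    def test_ideal_excess_is_flat(self):
        rho = np.linspace(0.2, 1.0, 100)
        table = sba.CompressibilityTable(rho=rho, chi_inf=np.ones(100), kT=1.2)
        ex = sba.excess_mu(sba.integrate_mu(table, 0.6))
        span = ex.delta_mu_excess.max() - ex.delta_mu_excess.min()
        assert span < 1e-6

    def test_quadrature_convergence_on_smooth_table(self):
        rho = np.linspace(0.3, 1.0, 40)
        table = sba.CompressibilityTable(rho=rho, chi_inf=1 / (1 + rho**2),
                                         kT=1.2)
        a = sba.integrate_mu(table, 0.5, refine=32).delta_mu
        b = sba.integrate_mu(table, 0.5, refine=64).delta_mu
        assert np.abs(a - b).max() < 1e-4

    def test_reference_outside_range_rejected(self):
        rho = np.linspace(0.3, 1.0, 20)
        table = sba.CompressibilityTable(rho=rho, chi_inf=np.ones(20), kT=1.0)
        with pytest.raises(ValueError, match="reference"):
            sba.integrate_mu(table, 0.1)

    def test_nonpositive_chi_rejected(self):
        rho = np.linspace(0.3, 1.0, 20)
        chi = np.ones(20)
        chi[5] = -0.1
        table = sba.CompressibilityTable(rho=rho, chi_inf=chi, kT=1.0)
        with pytest.raises(ValueError, match="non-positive"):
            sba.integrate_mu(table, 0.5)

    def test_error_propagation_grows_away_from_reference(self):
        rho = np.linspace(0.2, 1.0, 30)
        table = sba.CompressibilityTable(
            rho=rho, chi_inf=np.ones(30), kT=1.2,
            chi_err=np.full(30, 0.01),
        )
        curve = sba.integrate_mu(table, 0.6)
        i0 = np.argmin(np.abs(rho - 0.6))
        assert curve.stderr[i0] <= curve.stderr[0]
        assert curve.stderr[i0] <= curve.stderr[-1]


class TestMixtureRoute:
    @staticmethod
    def ideal_table():
        xA = np.linspace(0.1, 0.9, 30)
        rho_tot = 0.9
        return sba.KBITable(
            xA=xA, rhoA=xA * rho_tot, rhoB=(1 - xA) * rho_tot,
            G_AA=np.zeros(30), G_AB=np.zeros(30), G_BB=np.zeros(30), kT=1.2,
        )

    def test_ideal_mixture_excess_is_flat(self):
        table = self.ideal_table()
        curve = sba.integrate_mu(table, reference_density=0.45)
        ex = sba.excess_mu(curve)
        span = ex.delta_mu_excess.max() - ex.delta_mu_excess.min()
        assert span < 1e-6

    def test_ideal_mixture_delta_mu_is_log_density_ratio(self):
        table = self.ideal_table()
        curve = sba.integrate_mu(table, reference_density=0.45)
        exact = 1.2 * np.log(table.rhoA / 0.45)
        assert np.abs(curve.delta_mu - exact).max() < 1e-6

    def test_anchoring_passes_through_reference_exactly(self):
        table = self.ideal_table()
        ex = sba.excess_mu(sba.integrate_mu(table, 0.45))
        anchored = sba.anchor_excess(ex, 0.3, 2.345, provenance="external")
        assert np.interp(0.3, anchored.axis,
                         anchored.delta_mu_excess) == pytest.approx(2.345,
                                                                    abs=1e-12)
        assert anchored.reference["mu0"] == 2.345


class TestConsistency:
    def test_chi_and_kbi_routes_agree_on_one_trajectory(self, wca_small_traj):
        # pure-fluid consistency: chi_inf and 1 + rho * G_AA^inf estimate the
        # same bulk quantity from the same frames
        traj = wca_small_traj
        L0 = traj.box_edge
        grid = sba.default_lambda_grid(L0, n=40)
        window = (2.0 / L0, 0.35)
        curve = sba.fluctuation_curve(traj, grid, 200, seed=3)
        chi_fit = sba.fit_chi_linear(curve, window)
        kbi = sba.kbi_curve(traj, grid, 200, seed=3)
        g_fit = sba.fit_kbi(kbi, window)[("A", "A")]
        rho = traj.density
        chi_from_kbi = 1.0 + rho * g_fit.params["G_inf"]
        comb = np.hypot(chi_fit.stderr["chi_inf"],
                        rho * g_fit.stderr["G_inf"])
        assert abs(chi_fit.params["chi_inf"] - chi_from_kbi) < 3 * comb + 0.01

    def test_monotone_check_warns_but_does_not_fail(self):
        kap = np.array([0.5, 0.6, 0.4])
        with pytest.warns(UserWarning, match="monoton"):
            assert thermo.check_monotone_decreasing(kap) is False
        assert thermo.check_monotone_decreasing(np.array([0.5, 0.4, 0.3]))
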