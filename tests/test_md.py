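"""MD engine: pair potential, integrator, thermostat, pressure, density tuning."""

import numpy as np
import pytest

import sba
from sba import md


class TestPairPotential:
    def test_zero_at_and_beyond_cutoff(self):
        ff = md.ForceField.lj_cutoff_25()
        assert md.pair_energy(2.5, "A", "A", ff) == 0.0
        assert md.pair_energy(3.7, "A", "A", ff) == 0.0

    def test_minimum_value_with_extended_cutoff(self):
        # U(2^(1/6)) = -1 - U_LJ(2.5); U_LJ(2.5) = 4(2.5^-12 - 2.5^-6)
        ff = md.ForceField.lj_cutoff_25()
        u_tail = 4.0 * (2.5**-12 - 2.5**-6)
        expected = -1.0 - u_tail
        assert md.pair_energy(2 ** (1 / 6), "A", "A", ff) == pytest.approx(
            expected, abs=1e-12
        )
        # exact rational arithmetic: -1 - 4*(2.5^-12 - 2.5^-6) = -0.983683108864
        assert expected == pytest.approx(-0.983683108864, abs=1e-12)

    def test_purely_repulsive_cutoff_cancels_minimum(self):
        ff = md.ForceField.single_component()  # rc = 2^(1/6)
        assert md.pair_energy(2 ** (1 / 6), "A", "A", ff) == 0.0

    def test_continuity_at_cutoff(self):
        ff = md.ForceField.lj_cutoff_25()
        for delta in (1e-3, 1e-6, 1e-9):
            assert abs(md.pair_energy(2.5 - delta, "A", "A", ff)) < 1e-2 * delta / 1e-3 + 1e-8

    def test_overlap_raises(self):
        ff = md.ForceField.single_component()
        with pytest.raises(ValueError):
            md.pair_energy(0.0, "A", "A", ff)

    def test_mixture_rules(self):
        ff = md.ForceField.binary_mixture()
        assert ff.epsilon[0, 1] == pytest.approx(1.1)
        assert ff.epsilon[0, 0] == pytest.approx(1.2)
        assert np.all(ff.sigma == 1.0)


class TestForces:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cell_list_matches_bruteforce(self, seed):
        # uniform random configurations contain near-overlaps with enormous
        # forces, so the additive tolerance is paired with a relative one
        cfg = sba.generate_ideal_gas(100, 10.0, seed=seed)
        ff = md.ForceField.lj_cutoff_25()
        f_brute, p_brute, v_brute = md.compute_forces(cfg, ff, brute_force=True)
        f_cell, p_cell, v_cell = md.compute_forces(cfg, ff)
        assert np.allclose(f_brute, f_cell, rtol=1e-12, atol=1e-10)
        assert p_brute == pytest.approx(p_cell, rel=1e-12, abs=1e-9)
        assert v_brute == pytest.approx(v_cell, rel=1e-12, abs=1e-8)

    def test_cell_list_additive_bound_without_overlaps(self):
        # overlap-free configuration of moderate forces: strict additive bound
        box = (100 / 0.7) ** (1.0 / 3.0)
        cfg = md.lattice_configuration(100, box, seed=4)
        ff = md.ForceField.single_component()
        f_brute, _, _ = md.compute_forces(cfg, ff, brute_force=True)
        f_cell, _, _ = md.compute_forces(cfg, ff)
        assert np.abs(f_brute - f_cell).max() < 1e-10

    def test_binary_forces_match_bruteforce(self):
        cfg = sba.generate_ideal_binary(60, 60, 8.0, seed=5)
        ff = md.ForceField.binary_mixture()
        f_b, _, _ = md.compute_forces(cfg, ff, brute_force=True)
        f_c, _, _ = md.compute_forces(cfg, ff)
        assert np.abs(f_b - f_c).max() < 1e-10


class TestIntegrator:
    def test_energy_conservation_without_thermostat(self):
        n = 512
        box = (n / 0.7) ** (1.0 / 3.0)
        init = md.lattice_configuration(n, box, seed=1)
        proto = md.SimulationProtocol(
            temperature=1.0, seed=2, friction=0.0,
            n_equilibration_steps=0, n_production_steps=1000, frame_stride=1000,
        )
        traj = md.run_nvt(init, md.ForceField.single_component(), proto,
                          track_energy=True)
        e = traj.metadata["energies"]
        assert (e.max() - e.min()) / n < 1e-4

    def test_thermostat_hits_target_temperature(self, wca_small_traj):
        t_kin = wca_small_traj.metadata["mean_kinetic_temperature"]
        assert t_kin == pytest.approx(1.2, rel=0.02)

    def test_determinism_same_seed(self):
        n = 64
        box = (n / 0.5) ** (1.0 / 3.0)
        init = md.lattice_configuration(n, box, seed=3)
        ff = md.ForceField.single_component()
        proto = md.SimulationProtocol(
            temperature=1.2, seed=4,
            n_equilibration_steps=100, n_production_steps=500, frame_stride=100,
        )
        t1 = md.run_nvt(init, ff, proto)
        t2 = md.run_nvt(init, ff, proto)
        for a, b in zip(t1.frames, t2.frames):
            assert np.array_equal(a.positions, b.positions)

    def test_cutoff_too_large_rejected(self):
        init = md.lattice_configuration(27, 3.0, seed=1)
        ff = md.ForceField.lj_cutoff_25()
        proto = md.SimulationProtocol(temperature=1.0, seed=1)
        with pytest.raises(ValueError, match="cutoff"):
            md.run_nvt(init, ff, proto)

    def test_ideal_gas_limit_recovers_uniform_fluctuations(self):
        # epsilon -> 0: non-interacting particles equilibrate to the uniform
        # measure, whose block law is Var/mean = 1 - lambda^3
        n = 500
        box = 10.0
        init = md.lattice_configuration(n, box, seed=6)
        ff = md.ForceField(("A",), [[0.0]], [[1.0]], md.WCA_CUTOFF)
        # weak friction -> fast free diffusion (D = kT/gamma), so the lattice
        # start relaxes to the uniform measure and frames decorrelate
        proto = md.SimulationProtocol(
            temperature=1.2, seed=6, friction=0.1,
            n_equilibration_steps=10_000, n_production_steps=40_000,
            frame_stride=1_000,
        )
        traj = md.run_nvt(init, ff, proto)
        grid = np.array([0.3, 0.5, 0.8])
        curve = sba.fluctuation_curve(traj, grid, 100, seed=6)
        expected = 1 - grid**3
        assert np.all(np.abs(curve.values - expected) < 4 * curve.stderr + 0.03)


class TestPressure:
    def test_ideal_gas_pressure_exact(self):
        cfg = sba.generate_ideal_gas(500, 10.0, seed=1)  # rho = 0.5
        ff = md.ForceField(("A",), [[0.0]], [[1.0]], md.WCA_CUTOFF)
        assert md.virial_pressure(cfg, ff, 1.2) == pytest.approx(0.6, abs=1e-12)

    def test_repulsive_fluid_pressure_exceeds_ideal(self, wca_small_traj):
        ff = md.ForceField.single_component()
        fr = wca_small_traj.frames[-1]
        p = md.virial_pressure(fr, ff, 1.2)
        assert p > fr.density * 1.2

    def test_three_particle_hand_summed_virial(self):
        # frozen coordinates; brute-force O(N^2) oracle evaluated in the test
        box = 10.0
        pos = np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0], [1.0, 2.2, 1.0]])
        ff = md.ForceField.lj_cutoff_25()
        cfg = sba.Configuration(pos, np.array(["A"] * 3), box)
        vir = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                d = pos[i] - pos[j]
                d -= box * np.rint(d / box)
                r = np.sqrt(d @ d)
                vir += r * md.pair_force(r, "A", "A", ff)
        expected = 3 / box**3 * 1.2 + vir / (3 * box**3)
        assert md.virial_pressure(cfg, ff, 1.2) == pytest.approx(expected, rel=1e-12)


class TestDensityTuning:
    def test_ideal_gas_inverts_equation_of_state(self):
        ff = md.ForceField(("A",), [[0.0]], [[1.0]], md.WCA_CUTOFF)
        rho = md.tune_density_to_pressure(
            ff, temperature=1.2, target_pressure=0.6, mole_fractions={"A": 1.0},
            tolerance=1e-4, seed=1, n_particles=128,
            n_equilibration_steps=200, n_production_steps=500,
        )
        assert rho == pytest.approx(0.5, rel=2e-3)

    def test_zero_tolerance_rejected(self):
        ff = md.ForceField.single_component()
        with pytest.raises(ValueError, match="tolerance"):
            md.tune_density_to_pressure(
                ff, 1.2, 9.8, {"A": 1.0}, tolerance=0.0, seed=1
            )

    def test_unbracketed_target_reports_scan(self):
        ff = md.ForceField(("A",), [[0.0]], [[1.0]], md.WCA_CUTOFF)
        with pytest.raises(ValueError, match="rho="):
            md.tune_density_to_pressure(
                ff, 1.2, 50.0, {"A": 1.0}, tolerance=0.01, seed=1,
                n_particles=64, density_bracket=(0.1, 0.5),
                n_equilibration_steps=100, n_production_steps=200,
            )


class TestStructure:
    def test_rdf_decays_to_one(self, wca_small_traj):
        # short-ranged repulsive fluid: g(r) ~ 1 beyond a few sigma, so the
        # correlation length is well below the fitted block sizes
        r, g = md.radial_distribution(
            sba.Trajectory(wca_small_traj.frames[::10],
                           metadata=wca_small_traj.metadata),
            r_max=4.5, n_bins=90,
        )
        tail = g[r > 3.0]
        assert np.all(np.abs(tail - 1.0) < 0.1)
        assert np.all(g[r < 0.8] < 0.05)  # core exclusion
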