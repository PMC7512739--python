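"""Shared fixtures: cheap ideal-gas oracles and one short interacting run.

Everything is generated programmatically; the only expensive fixture is a
short purely repulsive LJ run reused by several tests (session scope).
"""

from __future__ import annotations

import numpy as np
import pytest

import sba
from sba import md


@pytest.fixture(scope="session")
def ideal_traj() -> sba.Trajectory:
    """200 independent ideal-gas frames of 1000 particles in a 10-sigma box."""
    return sba.generate_ideal_gas_trajectory(200, 1000, 10.0, seed=42)


@pytest.fixture(scope="session")
def ideal_binary_traj() -> sba.Trajectory:
    """200 independent two-species ideal-gas frames, 500 + 500 particles."""
    return sba.generate_ideal_binary_trajectory(200, 500, 500, 10.0, seed=43)


@pytest.fixture(scope="session")
def wca_small_traj() -> sba.Trajectory:
    """Short purely repulsive (rc = 2^(1/6)) run: N=512, rho=0.6, kBT=1.2.

    Long enough for the thermostat contract and rough fluctuation statistics;
    used for estimator cross-checks, not headline numbers.
    """
    n, rho = 512, 0.6
    box = (n / rho) ** (1.0 / 3.0)
    init = md.lattice_configuration(n, box, seed=7)
    proto = md.SimulationProtocol(
        temperature=1.2,
        seed=7,
        n_equilibration_steps=10_000,
        n_production_steps=50_000,
        frame_stride=100,
    )
    return md.run_nvt(init, md.ForceField.single_component(), proto)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def exact_origin_average_chi(config: sba.Configuration, lam: float) -> float:
    """Closed-form Var/mean of the block count over the *continuum* of block
    origins, for one frozen configuration.

    Independent oracle for the origin-sampling estimators: E[N] = N0 lam^3
    and E[N^2] = sum over particle pairs of the probability that a random
    periodic block of edge lam*L0 contains both, which factorizes per axis
    into overlap lengths of two intervals on a circle.
    """
    L0 = config.box_edge
    ell = lam * L0
    pos = config.positions
    d = np.abs(pos[:, None, :] - pos[None, :, :])
    d = np.minimum(d, L0 - d)
    p_axis = (np.maximum(0.0, ell - d) + np.maximum(0.0, ell - (L0 - d))) / L0
    en2 = float(np.prod(p_axis, axis=2).sum())
    en = config.n_particles * lam**3
    return (en2 - en**2) / en
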