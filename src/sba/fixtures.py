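"""Synthetic inputs with exact ground truth.

Two families of oracles make every downstream stage testable without external
data:

* ideal-gas configurations (uniform, independent positions), whose block
  fluctuation law is exactly binomial: in a subvolume of relative size
  ``lambda^3`` the particle count is Binomial(N0, lambda^3), hence
  Var(N)/<N> = 1 - lambda^3 — the closed-system fluctuation model with
  chi_T^inf = 1 and no boundary term;
* synthetic fluctuation / KBI curves drawn from the finite-size models with
  known parameters, for fit-recovery tests.

Every generator takes a mandatory integer seed; the seed is recorded in the
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Configuration, FluctuationCurve, Trajectory

__all__ = [
    "SyntheticCurveSpec",
    "generate_ideal_gas",
    "generate_ideal_gas_trajectory",
    "generate_ideal_binary",
    "generate_ideal_binary_trajectory",
    "generate_synthetic_curve",
    "generate_synthetic_kbi_curve",
]


def generate_ideal_gas(
    n_particles: int, box_edge: float, seed: int, frame_index: int = 0
) -> Configuration:
    """One ideal-gas frame: positions i.i.d. uniform on ``[0, box_edge)^3``."""
    if n_particles < 1:
        raise ValueError(f"n_particles must be >= 1, got {n_particles}")
    if not box_edge > 0:
        raise ValueError(f"box_edge must be positive, got {box_edge}")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_edge, size=(n_particles, 3))
    species = np.full(n_particles, "A")
    return Configuration(pos, species, box_edge, frame_index=frame_index)


def generate_ideal_gas_trajectory(
    n_frames: int, n_particles: int, box_edge: float, seed: int
) -> Trajectory:
    """Independent ideal-gas frames (statistically equivalent to sampling
    non-interacting dynamics, at no simulation cost)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(n_frames)]
    frames = [
        generate_ideal_gas(n_particles, box_edge, s, frame_index=k)
        for k, s in enumerate(seeds)
    ]
    return Trajectory(
        frames,
        metadata={
            "source": "ideal_gas",
            "seed": int(seed),
            "density": n_particles / box_edge**3,
        },
    )


def generate_ideal_binary(
    nA: int, nB: int, box_edge: float, seed: int, frame_index: int = 0
) -> Configuration:
    """Two ideal-gas species placed independently; cross-species block counts
    are independent, so all cross KBIs vanish identically."""
    if nA < 1 or nB < 1:
        raise ValueError(f"species counts must be >= 1, got nA={nA}, nB={nB}")
    if not box_edge > 0:
        raise ValueError(f"box_edge must be positive, got {box_edge}")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_edge, size=(nA + nB, 3))
    species = np.array(["A"] * nA + ["B"] * nB)
    return Configuration(pos, species, box_edge, frame_index=frame_index)


def generate_ideal_binary_trajectory(
    n_frames: int, nA: int, nB: int, box_edge: float, seed: int
) -> Trajectory:
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(n_frames)]
    frames = [
        generate_ideal_binary(nA, nB, box_edge, s, frame_index=k)
        for k, s in enumerate(seeds)
    ]
    return Trajectory(
        frames,
        metadata={
            "source": "ideal_binary",
            "seed": int(seed),
            "density": (nA + nB) / box_edge**3,
        },
    )


@dataclass
class SyntheticCurveSpec:
    """Parameters of a synthetic scaled fluctuation curve.

    The model is the combined finite-size law

        lambda * chi(lambda) = lambda * chi_inf * (1 - lambda^3)
                               + c1 / L0 + (c2 / L0^2) / lambda

    with chi_inf the thermodynamic-limit reduced compressibility, c1 and c2
    intensive boundary lengths (sigma) and additive Gaussian noise of standard
    deviation ``noise_sd`` on lambda*chi.  The 1/lambda coefficient is carried
    internally as the single dimensionless constant b2 = c2 / L0^2.
    """

    chi_inf: float
    c1: float
    L0: float
    lambda_grid: np.ndarray
    seed: int
    c2: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if np.any(self.lambda_grid <= 0) or np.any(self.lambda_grid > 1):
            raise ValueError("lambda values must lie in (0, 1] (1/lambda term)")
        if np.any(np.diff(self.lambda_grid) <= 0):
            raise ValueError("lambda_grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")

    @property
    def b2(self) -> float:
        return self.c2 / self.L0**2


def generate_synthetic_curve(spec: SyntheticCurveSpec) -> FluctuationCurve:
    """Draw lambda*chi(lambda) from the finite-size model plus noise.

    The returned curve is flagged ``scaled=True`` and its metadata records the
    ground-truth parameters for recovery tests.  ``stderr`` is set to the true
    noise standard deviation (the honest per-point uncertainty).
    """
    lam = spec.lambda_grid
    truth = lam * spec.chi_inf * (1.0 - lam**3) + spec.c1 / spec.L0 + spec.b2 / lam
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd, size=lam.shape) if spec.noise_sd > 0 else 0.0
    return FluctuationCurve(
        lambda_grid=lam,
        values=truth + noise,
        stderr=np.full(lam.shape, float(spec.noise_sd)),
        n_blocks=np.zeros(lam.shape, dtype=int),
        system={
            "L0": spec.L0,
            "seed": spec.seed,
            "truth": {
                "chi_inf": spec.chi_inf,
                "c1": spec.c1,
                "c2": spec.c2,
                "b2": spec.b2,
                "noise_sd": spec.noise_sd,
            },
            "source": "synthetic",
        },
        scaled=True,
    )


def generate_synthetic_kbi_curve(
    G_inf: float,
    alpha: float,
    L0: float,
    lambda_grid: np.ndarray,
    seed: int,
    rho_i: float | None = None,
    noise_sd: float = 0.0,
) -> FluctuationCurve:
    """Draw lambda*G_ij(lambda) from the KBI finite-size model

        lambda*G(lambda) = lambda*G_inf*(1-lambda^3) - delta_ij*lambda^4/rho_i
                           + alpha/L0

    ``rho_i`` is the species density for a diagonal (i == j) pair and None for
    an off-diagonal pair.  Returned as a scaled curve whose metadata records
    the ground truth; values are in sigma^3.
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if np.any(lam <= 0) or np.any(lam > 1):
        raise ValueError("lambda values must lie in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    truth = lam * G_inf * (1.0 - lam**3) + alpha / L0
    if rho_i is not None:
        truth = truth - lam**4 / rho_i
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=lam.shape) if noise_sd > 0 else 0.0
    return FluctuationCurve(
        lambda_grid=lam,
        values=truth + noise,
        stderr=np.full(lam.shape, float(noise_sd)),
        n_blocks=np.zeros(lam.shape, dtype=int),
        system={
            "L0": L0,
            "seed": seed,
            "rho_i": rho_i,
            "truth": {"G_inf": G_inf, "alpha": alpha, "noise_sd": noise_sd},
            "source": "synthetic_kbi",
        },
        scaled=True,
    )
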