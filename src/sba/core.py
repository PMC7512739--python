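"""Core data containers shared across the spatial block analysis pipeline.

All quantities are expressed in reduced Lennard-Jones units: lengths in
``sigma``, energies in ``epsilon``, temperature in ``epsilon/kB``, number
densities in ``sigma^-3``, pressure in ``epsilon/sigma^3`` and time in
``sigma * sqrt(m/epsilon)``.  The unit system is never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "Configuration",
    "Trajectory",
    "FluctuationCurve",
    "KBICurveSet",
    "FitResult",
    "CompressibilityTable",
    "KBITable",
    "ChemPotCurve",
]


@dataclass
class Configuration:
    """One snapshot of a closed system in a cubic periodic box.

    Parameters
    ----------
    positions : (N, 3) array
        Particle coordinates; wrapped into ``[0, box_edge)`` on construction.
    species : (N,) array of str
        Per-particle species label (e.g. ``"A"``, ``"B"``).
    box_edge : float
        Cubic box edge ``L0 > 0``.
    frame_index : int
        Index of this frame within its trajectory.
    """

    positions: np.ndarray
    species: np.ndarray
    box_edge: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        self.species = np.asarray(self.species, dtype=str)
        if self.species.shape != (self.positions.shape[0],):
            raise ValueError("species must have one label per particle")
        if not self.box_edge > 0:
            raise ValueError(f"box_edge must be positive, got {self.box_edge}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        # wrap into [0, L0): the block-counting estimator assumes wrapped coordinates
        self.positions = np.mod(self.positions, self.box_edge)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return self.box_edge**3

    @property
    def density(self) -> float:
        return self.n_particles / self.volume

    def species_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.species, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class Trajectory:
    """Ordered frames of a closed (fixed N, fixed V) system.

    Invariant: all frames share the particle number, the species multiset and
    the box edge.  Violations raise at construction, naming the frame.
    """

    frames: list[Configuration]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory must contain at least one frame")
        ref = self.frames[0]
        ref_counts = ref.species_counts()
        for k, fr in enumerate(self.frames):
            if fr.n_particles != ref.n_particles:
                raise ValueError(
                    f"frame {k}: particle count {fr.n_particles} differs from "
                    f"frame 0 ({ref.n_particles}); trajectories are closed systems"
                )
            if fr.species_counts() != ref_counts:
                raise ValueError(f"frame {k}: species counts differ from frame 0")
            if not np.isclose(fr.box_edge, ref.box_edge, rtol=0, atol=1e-12):
                raise ValueError(f"frame {k}: box edge differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_particles(self) -> int:
        return self.frames[0].n_particles

    @property
    def box_edge(self) -> float:
        return self.frames[0].box_edge

    @property
    def density(self) -> float:
        return self.frames[0].density

    def species_counts(self) -> dict[str, int]:
        return self.frames[0].species_counts()

    def species_densities(self) -> dict[str, float]:
        v = self.frames[0].volume
        return {s: n / v for s, n in self.species_counts().items()}


@dataclass
class FluctuationCurve:
    """Finite-size reduced compressibility chi_T(lambda) on a grid of block sizes.

    ``values`` holds chi_T(lambda) by default; if ``scaled`` is True they hold
    lambda * chi_T(lambda) (the fit coordinate).  ``stderr`` follows the same
    convention.  ``system`` records N0, L0, rho, kT and provenance (seeds).
    """

    lambda_grid: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    n_blocks: np.ndarray
    system: dict[str, Any] = field(default_factory=dict)
    scaled: bool = False

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        self.n_blocks = np.asarray(self.n_blocks)
        if not (self.lambda_grid.shape == self.values.shape == self.stderr.shape):
            raise ValueError("lambda_grid, values and stderr must share a shape")
        if self.lambda_grid.size == 0:
            raise ValueError("empty lambda grid")
        if np.any(self.lambda_grid <= 0) or np.any(self.lambda_grid > 1):
            raise ValueError("lambda values must lie in (0, 1]")
        if np.any(self.stderr < 0):
            raise ValueError("standard errors must be >= 0")

    def scaled_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lambda * chi, stderr of lambda * chi) regardless of storage."""
        if self.scaled:
            return self.values.copy(), self.stderr.copy()
        return self.lambda_grid * self.values, self.lambda_grid * self.stderr


@dataclass
class KBICurveSet:
    """Finite-size Kirkwood-Buff integrals G_ij(lambda) for every species pair.

    Keys of ``values``/``stderr`` are sorted species-label tuples; the estimator
    is symmetric by construction so G_AB and G_BA are the same array.
    """

    lambda_grid: np.ndarray
    species: list[str]
    values: dict[tuple[str, str], np.ndarray]
    stderr: dict[tuple[str, str], np.ndarray]
    n_blocks: np.ndarray
    rho: dict[str, float]
    system: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)

    @staticmethod
    def pair_key(i: str, j: str) -> tuple[str, str]:
        return (i, j) if i <= j else (j, i)

    def g(self, i: str, j: str) -> np.ndarray:
        """G_ij(lambda); symmetric in (i, j)."""
        return self.values[self.pair_key(i, j)]

    def g_err(self, i: str, j: str) -> np.ndarray:
        return self.stderr[self.pair_key(i, j)]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.values.keys())


@dataclass
class FitResult:
    """Extrapolated thermodynamic-limit value plus boundary constants.

    ``model_id`` is one of ``"linear_lambda"`` (ensemble + boundary model,
    fit on the basis {lambda(1-lambda^3), 1}), ``"with_inverse_term"``
    (adds a 1/lambda boundary term) or ``"kbi"`` (KBI finite-size model).
    ``params``/``stderr`` use the keys ``chi_inf``, ``c`` (sigma), ``b2``
    (dimensionless 1/lambda coefficient) for compressibility fits and
    ``G_inf`` (sigma^3), ``alpha`` (sigma) for KBI fits.
    """

    model_id: str
    params: dict[str, float]
    stderr: dict[str, float]
    window: tuple[float, float]
    n_points: int
    L0: float
    residual_rms: float
    cov: np.ndarray | None = None
    pair: tuple[str, str] | None = None
    rho_i: float | None = None
    diagonal: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (0 < lo < hi <= 1):
            raise ValueError("fit window must satisfy 0 < lo < hi <= 1")
        if any(v < 0 for v in self.stderr.values() if np.isfinite(v)):
            raise ValueError("parameter uncertainties must be >= 0")


@dataclass
class CompressibilityTable:
    """Density scan of extrapolated reduced compressibility chi_T^inf at fixed kT."""

    rho: np.ndarray
    chi_inf: np.ndarray
    kT: float
    chi_err: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.chi_inf = np.asarray(self.chi_inf, dtype=float)
        if self.rho.size == 0:
            raise ValueError("empty table")
        if np.any(np.diff(self.rho) <= 0):
            raise ValueError("density axis must be strictly increasing")
        if np.any(self.rho <= 0):
            raise ValueError("densities must be positive")
        if self.chi_err is not None:
            self.chi_err = np.asarray(self.chi_err, dtype=float)

    def kappa(self) -> np.ndarray:
        """Bulk isothermal compressibility kappa_T = chi_inf / (rho kT), sigma^3/eps."""
        return self.chi_inf / (self.rho * self.kT)


@dataclass
class KBITable:
    """Mole-fraction scan of extrapolated KBIs for a binary (A, B) mixture."""

    xA: np.ndarray
    rhoA: np.ndarray
    rhoB: np.ndarray
    G_AA: np.ndarray
    G_AB: np.ndarray
    G_BB: np.ndarray
    kT: float
    G_err: dict[str, np.ndarray] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("xA", "rhoA", "rhoB", "G_AA", "G_AB", "G_BB"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.xA.size == 0:
            raise ValueError("empty table")
        if np.any(np.diff(self.xA) <= 0):
            raise ValueError("mole-fraction axis must be strictly increasing")


@dataclass
class ChemPotCurve:
    """Chemical-potential differences along a density or composition axis.

    ``delta_mu`` is mu - mu(reference); it vanishes exactly at the reference
    point.  ``delta_mu_excess`` subtracts the ideal part kT*ln(rho_species);
    its additive constant is arbitrary until anchored to an externally supplied
    reference value (see :func:`sba.thermo.anchor_excess`).
    """

    axis_name: str
    axis: np.ndarray
    delta_mu: np.ndarray
    kT: float
    delta_mu_excess: np.ndarray | None = None
    stderr: np.ndarray | None = None
    reference: dict[str, Any] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.delta_mu = np.asarray(self.delta_mu, dtype=float)
        if self.axis.shape != self.delta_mu.shape:
            raise ValueError("axis and delta_mu must share a shape")
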