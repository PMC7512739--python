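"""Minimal Langevin NVT molecular dynamics for truncated-and-shifted LJ fluids.

Reduced LJ units throughout (energy eps, length sigma, mass m = 1 for every
species, time sigma*sqrt(m/eps)).  The integrator is velocity Verlet with the
Langevin thermostat applied as a BAOAB splitting; with friction = 0 it reduces
exactly to velocity Verlet, which is how energy conservation is tested.

The potential is 12-6 Lennard-Jones truncated at ``cutoff`` and shifted so
U(rc) = 0 exactly; the force is *not* smoothed, so it has the truncation jump
at rc that the plain truncated-and-shifted form implies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core import Configuration, Trajectory

__all__ = [
    "ForceField",
    "SimulationProtocol",
    "pair_energy",
    "pair_force",
    "lattice_configuration",
    "compute_forces",
    "potential_energy",
    "virial_pressure",
    "run_nvt",
    "tune_density_to_pressure",
    "radial_distribution",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class IntegrationInstabilityError(RuntimeError):
    """Non-finite forces or particle escape; usually cured by a smaller timestep."""


@dataclass
class ForceField:
    """Pairwise TSLJ force field over a finite species alphabet.

    ``epsilon`` and ``sigma`` are symmetric (ns, ns) tables in eps / sigma
    units; ``cutoff`` is a single distance rc (sigma).  ``shifted`` is always
    True here: the potential is shifted so it vanishes exactly at rc.
    """

    species: tuple[str, ...]
    epsilon: np.ndarray
    sigma: np.ndarray
    cutoff: float
    shifted: bool = True

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        ns = len(self.species)
        self.epsilon = np.asarray(self.epsilon, dtype=float).reshape(ns, ns)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(ns, ns)
        for name, m in (("epsilon", self.epsilon), ("sigma", self.sigma)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} table must be symmetric")
        if np.any(self.sigma <= 0) or np.any(self.epsilon < 0) or self.cutoff <= 0:
            raise ValueError("sigma, cutoff must be > 0 and epsilon >= 0")

    @classmethod
    def single_component(
        cls, epsilon: float = 1.0, sigma: float = 1.0, cutoff: float = WCA_CUTOFF
    ) -> "ForceField":
        """Single-species TSLJ; the default rc = 2^(1/6) sigma gives the purely
        repulsive (WCA-like) fluid."""
        return cls(("A",), [[epsilon]], [[sigma]], cutoff)

    @classmethod
    def lj_cutoff_25(cls, epsilon: float = 1.0, sigma: float = 1.0) -> "ForceField":
        """Single-species TSLJ with rc = 2.5 sigma (has an attractive well)."""
        return cls(("A",), [[epsilon]], [[sigma]], 2.5 * sigma)

    @classmethod
    def binary_mixture(cls) -> "ForceField":
        """Purely repulsive binary mixture: eps_AA=1.2, eps_BB=1.0,
        eps_AB=(eps_AA+eps_BB)/2=1.1, all sigma equal, rc=2^(1/6) sigma."""
        eps = [[1.2, 1.1], [1.1, 1.0]]
        sig = [[1.0, 1.0], [1.0, 1.0]]
        return cls(("A", "B"), eps, sig, WCA_CUTOFF)

    def index_of(self, label: str) -> int:
        try:
            return self.species.index(label)
        except ValueError:
            raise KeyError(f"species {label!r} not in force field {self.species}")

    def _tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(eps, sigma^2, rc^2, shift) tables for the kernels."""
        sig2 = self.sigma**2
        rc2 = np.full_like(sig2, self.cutoff**2)
        if self.shifted:
            s6 = (self.sigma / self.cutoff) ** 6
            shift = 4.0 * self.epsilon * (s6**2 - s6)
        else:
            shift = np.zeros_like(sig2)
        return self.epsilon, sig2, rc2, shift

    def type_array(self, species_labels: np.ndarray) -> np.ndarray:
        lut = {s: k for k, s in enumerate(self.species)}
        try:
            return np.array([lut[s] for s in species_labels], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"species {exc.args[0]!r} not in force field") from None


@dataclass
class SimulationProtocol:
    """Langevin NVT protocol in reduced units.

    Defaults follow the standard choices for these fluids: damping
    gamma = 1.0 (inverse time), timestep dt = 1e-3.  Step counts are
    deliberately configurable; desk-scale analyses use far fewer steps than
    production studies.  ``seed`` is mandatory.
    """

    temperature: float
    seed: int
    timestep: float = 1.0e-3
    friction: float = 1.0
    n_equilibration_steps: int = 20_000
    n_production_steps: int = 100_000
    frame_stride: int = 250

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit integer seed is required")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


def pair_energy(r: float, species_i: str, species_j: str, ff: ForceField) -> float:
    """TSLJ pair potential: 4 eps[(s/r)^12 - (s/r)^6] - U_LJ(rc) for r < rc,
    exactly 0 for r >= rc."""
    if r <= 0:
        raise ValueError("r = 0: particle overlap")
    i, j = ff.index_of(species_i), ff.index_of(species_j)
    if r >= ff.cutoff:
        return 0.0
    eps, sig = ff.epsilon[i, j], ff.sigma[i, j]
    s6 = (sig / r) ** 6
    s6c = (sig / ff.cutoff) ** 6
    shift = 4.0 * eps * (s6c**2 - s6c) if ff.shifted else 0.0
    return 4.0 * eps * (s6**2 - s6) - shift


def pair_force(r: float, species_i: str, species_j: str, ff: ForceField) -> float:
    """Magnitude of -dU/dr (positive = repulsive); 0 beyond the cutoff."""
    if r <= 0:
        raise ValueError("r = 0: particle overlap")
    i, j = ff.index_of(species_i), ff.index_of(species_j)
    if r >= ff.cutoff:
        return 0.0
    eps, sig = ff.epsilon[i, j], ff.sigma[i, j]
    s6 = (sig / r) ** 6
    return 24.0 * eps * (2.0 * s6**2 - s6) / r


def lattice_configuration(
    n_particles: int,
    box_edge: float,
    seed: int,
    species: np.ndarray | None = None,
    jitter: float = 0.05,
) -> Configuration:
    """Particles on a perturbed simple-cubic lattice (overlap-free start)."""
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    n_side = math.ceil(n_particles ** (1.0 / 3.0))
    a = box_edge / n_side
    idx = np.arange(n_side**3)
    sites = np.column_stack(
        [idx // (n_side * n_side), (idx // n_side) % n_side, idx % n_side]
    ).astype(float)
    sites = (sites + 0.5) * a
    take = rng.permutation(n_side**3)[:n_particles]
    pos = sites[take] + rng.uniform(-jitter * a, jitter * a, size=(n_particles, 3))
    if species is None:
        species = np.full(n_particles, "A")
    return Configuration(pos, np.asarray(species, dtype=str), box_edge)


def _forces_raw(pos, box, types, ff: ForceField):
    eps, sig2, rc2, shift = ff._tables()
    ncell = int(box / ff.cutoff)
    if ncell >= 3:
        return _kernels.forces_cells(pos, box, types, eps, sig2, rc2, shift, ncell)
    return _kernels.forces_bruteforce(pos, box, types, eps, sig2, rc2, shift)


def compute_forces(
    config: Configuration, ff: ForceField, brute_force: bool = False
) -> tuple[np.ndarray, float, float]:
    """(forces, potential energy, virial sum r.F) for one configuration."""
    types = ff.type_array(config.species)
    pos = np.ascontiguousarray(config.positions)
    if brute_force:
        eps, sig2, rc2, shift = ff._tables()
        return _kernels.forces_bruteforce(
            pos, config.box_edge, types, eps, sig2, rc2, shift
        )
    return _forces_raw(pos, config.box_edge, types, ff)


def potential_energy(config: Configuration, ff: ForceField) -> float:
    return compute_forces(config, ff)[1]


def virial_pressure(config: Configuration, ff: ForceField, temperature: float) -> float:
    """Virial pressure P = rho kT + (1/3V) sum_pairs r.F, minimum-image pairs."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    _, _, vir = compute_forces(config, ff)
    v = config.volume
    return config.density * temperature + vir / (3.0 * v)


def run_nvt(
    initial: Configuration,
    ff: ForceField,
    protocol: SimulationProtocol,
    track_energy: bool = False,
    track_pressure: bool = False,
) -> Trajectory:
    """Langevin (BAOAB) NVT run; frames recorded every ``frame_stride``
    production steps.  Deterministic given the protocol seed.

    The trajectory metadata records the protocol, the mean kinetic temperature
    over production, and optionally per-step energies / sampled pressures.
    """
    box = initial.box_edge
    if ff.cutoff >= box / 2.0:
        raise ValueError(
            f"cutoff {ff.cutoff} must be < half the box edge {box / 2.0:.4g}"
        )
    types = ff.type_array(initial.species)
    pos = np.ascontiguousarray(initial.positions.copy())
    n = pos.shape[0]
    dt = protocol.timestep
    rng = np.random.default_rng(protocol.seed)

    kT = protocol.temperature
    vel = rng.normal(0.0, math.sqrt(kT), size=(n, 3))
    vel -= vel.mean(axis=0)  # no initial net drift

    if protocol.friction > 0:
        a_o = math.exp(-protocol.friction * dt)
        b_o = math.sqrt((1.0 - a_o * a_o) * kT)
    else:
        a_o, b_o = 1.0, 0.0

    f, pot, vir = _forces_raw(pos, box, types, ff)
    frames: list[Configuration] = []
    energies: list[float] = []
    pressures: list[float] = []
    temp_accum = 0.0
    temp_samples = 0
    n_total = protocol.n_equilibration_steps + protocol.n_production_steps
    volume = box**3

    for step in range(n_total):
        vel += 0.5 * dt * f
        pos += 0.5 * dt * vel
        if b_o != 0.0:
            vel *= a_o
            vel += b_o * rng.standard_normal((n, 3))
        pos += 0.5 * dt * vel
        np.mod(pos, box, out=pos)
        f, pot, vir = _forces_raw(pos, box, types, ff)
        vel += 0.5 * dt * f

        if not np.isfinite(pot) or (step % 1000 == 0 and not np.all(np.isfinite(f))):
            raise IntegrationInstabilityError(
                f"non-finite forces at step {step}; try a smaller timestep"
            )
        if track_energy:
            energies.append(0.5 * float(np.sum(vel * vel)) + pot)

        prod_step = step - protocol.n_equilibration_steps
        if prod_step >= 0:
            ke = 0.5 * float(np.sum(vel * vel))
            temp_accum += 2.0 * ke / (3.0 * n)
            temp_samples += 1
            if (prod_step + 1) % protocol.frame_stride == 0:
                frames.append(
                    Configuration(
                        pos.copy(),
                        initial.species,
                        box,
                        frame_index=len(frames),
                    )
                )
                if track_pressure:
                    pressures.append(n / volume * kT + vir / (3.0 * volume))

    if not frames:
        frames = [Configuration(pos.copy(), initial.species, box, frame_index=0)]
    meta = {
        "source": "md_nvt",
        "temperature": kT,
        "density": n / volume,
        "seed": protocol.seed,
        "timestep": dt,
        "friction": protocol.friction,
        "n_equilibration_steps": protocol.n_equilibration_steps,
        "n_production_steps": protocol.n_production_steps,
        "frame_stride": protocol.frame_stride,
        "mean_kinetic_temperature": (
            temp_accum / temp_samples if temp_samples else float("nan")
        ),
    }
    if track_energy:
        meta["energies"] = np.array(energies)
    if track_pressure:
        meta["pressures"] = np.array(pressures)
    return Trajectory(frames, metadata=meta)


def _mean_pressure_at_density(
    rho: float,
    ff: ForceField,
    temperature: float,
    counts: dict[str, int],
    seed: int,
    n_equilibration_steps: int,
    n_production_steps: int,
) -> float:
    n = sum(counts.values())
    box = (n / rho) ** (1.0 / 3.0)
    labels = np.array([s for s, c in sorted(counts.items()) for _ in range(c)])
    init = lattice_configuration(n, box, seed, species=labels)
    proto = SimulationProtocol(
        temperature=temperature,
        seed=seed,
        n_equilibration_steps=n_equilibration_steps,
        n_production_steps=n_production_steps,
        frame_stride=50,
    )
    traj = run_nvt(init, ff, proto, track_pressure=True)
    return float(np.mean(traj.metadata["pressures"]))


def tune_density_to_pressure(
    ff: ForceField,
    temperature: float,
    target_pressure: float,
    mole_fractions: dict[str, float],
    tolerance: float,
    seed: int,
    n_particles: int = 512,
    density_bracket: tuple[float, float] = (0.1, 1.2),
    n_equilibration_steps: int = 2_000,
    n_production_steps: int = 6_000,
    max_iter: int = 30,
) -> float:
    """Find the number density whose time-averaged virial pressure matches
    ``target_pressure`` at the given temperature, by bracketing + bisection on
    short NVT runs (the NPT-free route to fixed-pressure state points).
    """
    if tolerance <= 0:
        raise ValueError(
            "tolerance must be > 0: pressure estimates are stochastic and an "
            "exact match is unattainable"
        )
    if abs(sum(mole_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("mole fractions must sum to 1")
    counts = {s: int(round(x * n_particles)) for s, x in mole_fractions.items()}
    counts = {s: c for s, c in counts.items() if c > 0}
    ss = np.random.SeedSequence(seed)

    def measure(rho: float) -> float:
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        return _mean_pressure_at_density(
            rho, ff, temperature, counts, sub,
            n_equilibration_steps, n_production_steps,
        )

    lo, hi = density_bracket
    scanned: list[tuple[float, float]] = []
    p_lo = measure(lo)
    scanned.append((lo, p_lo))
    if abs(p_lo - target_pressure) <= tolerance:
        return lo
    p_hi = measure(hi)
    scanned.append((hi, p_hi))
    if abs(p_hi - target_pressure) <= tolerance:
        return hi
    if not (p_lo < target_pressure < p_hi):
        table = "\n".join(f"  rho={r:.4f}  P={p:.4f}" for r, p in scanned)
        raise ValueError(
            f"target pressure {target_pressure} not bracketed by the scanned "
            f"densities:\n{table}"
        )
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = measure(mid)
        scanned.append((mid, p_mid))
        if abs(p_mid - target_pressure) <= tolerance:
            return mid
        if p_mid < target_pressure:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    warnings.warn(
        "bisection exhausted before reaching the pressure tolerance; "
        "returning the last midpoint (consider longer sampling runs)"
    )
    return mid


def radial_distribution(
    traj: Trajectory, r_max: float, n_bins: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """All-species radial distribution function g(r) averaged over frames.

    Uses minimum-image distances; r_max must be < L0/2.  Returns (bin centers,
    g).  Intended for diagnostics (e.g. checking that g(r) has decayed to 1
    well inside the smallest fitted block, the zeta < L requirement).
    """
    box = traj.box_edge
    if not 0 < r_max < box / 2:
        raise ValueError("r_max must lie in (0, L0/2)")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    n = traj.n_particles
    for fr in traj:
        d = fr.positions[:, None, :] - fr.positions[None, :, :]
        d -= box * np.rint(d / box)
        r = np.sqrt(np.sum(d * d, axis=-1))
        iu = np.triu_indices(n, k=1)
        hist += np.histogram(r[iu], bins=edges)[0]
    rho = traj.density
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = len(traj.frames) * 0.5 * n * rho * shell
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, hist / norm
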