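"""Spatial block analysis: particle-number moments in cubic subdomains.

A block is a cube of edge L = lambda * L0 with its origin drawn uniformly
over the periodic box; blocks may straddle the boundary (membership is
evaluated on wrapped relative coordinates).  Membership per axis is half-open,
``origin <= x < origin + L``, so tiling blocks never double-count a particle.

From pooled block counts over all (frame, block) samples the module forms

* the finite-size reduced isothermal compressibility
  chi_T(lambda) = (<N^2> - <N>^2) / <N>, which vanishes identically at
  lambda = 1 for a closed system, and
* the finite-size Kirkwood-Buff integrals
  G_ij(lambda) = V [ (<Ni Nj> - <Ni><Nj>) / (<Ni><Nj>) ] - delta_ij V / <Ni>
  with V = (lambda L0)^3.

Standard errors come from a frame-level jackknife (frames are treated as
approximately independent; within-frame blocks are strongly correlated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Configuration, FluctuationCurve, KBICurveSet, Trajectory

__all__ = [
    "BlockCountSample",
    "sample_block_counts",
    "exhaustive_block_counts",
    "default_lambda_grid",
    "fluctuation_curve",
    "kbi_curve",
]


@dataclass
class BlockCountSample:
    """Species counts in one cubic block of one frame."""

    lam: float
    frame_index: int
    block_origin: np.ndarray
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _validate_lambda(lam: float) -> None:
    if not 0 < lam <= 1:
        raise ValueError(f"lambda must lie in (0, 1], got {lam}")


_CHUNK_ELEMS = 8_000_000  # bound on origins x particles per temporary


def _counts_at_origins(
    config: Configuration, origins: np.ndarray, lam: float
) -> dict[str, np.ndarray]:
    """Per-species counts for every origin, half-open membership after wrapping.

    Origins are processed in chunks so exhaustive grids with many origins stay
    within a bounded memory footprint.
    """
    L0 = config.box_edge
    edge = lam * L0
    n_orig = origins.shape[0]
    out: dict[str, np.ndarray] = {}
    for s in np.unique(config.species):
        pos = config.positions[config.species == s]
        counts = np.empty(n_orig, dtype=np.int64)
        if lam >= 1.0:
            counts[:] = pos.shape[0]
        else:
            step = max(1, _CHUNK_ELEMS // max(pos.shape[0], 1))
            for b0 in range(0, n_orig, step):
                og = origins[b0 : b0 + step]
                d = np.mod(pos[None, :, :] - og[:, None, :], L0)
                counts[b0 : b0 + step] = (np.max(d, axis=-1) < edge).sum(axis=1)
        out[str(s)] = counts
    return out


def sample_block_counts(
    config: Configuration, lam: float, n_blocks: int, seed: int
) -> list[BlockCountSample]:
    """Counts in ``n_blocks`` randomly-positioned cubic blocks of edge
    lambda*L0; origins uniform on [0, L0)^3, reproducible given seed."""
    _validate_lambda(lam)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    origins = rng.uniform(0.0, config.box_edge, size=(n_blocks, 3))
    counts = _counts_at_origins(config, origins, lam)
    species = sorted(counts)
    return [
        BlockCountSample(
            lam=lam,
            frame_index=config.frame_index,
            block_origin=origins[b],
            counts={s: int(counts[s][b]) for s in species},
        )
        for b in range(n_blocks)
    ]


def exhaustive_block_counts(
    config: Configuration, lam: float, grid_spacing: float
) -> list[BlockCountSample]:
    """Deterministic counts over a regular grid of block origins.

    A brute-force oracle for the random-origin estimator: both estimate the
    same moments of the block-count distribution.
    """
    _validate_lambda(lam)
    L0 = config.box_edge
    if not 0 < grid_spacing <= lam * L0 / 2.0:
        raise ValueError(
            f"grid_spacing must be in (0, {lam * L0 / 2.0:.4g}] "
            "(several origins per block edge)"
        )
    n_side = max(int(round(L0 / grid_spacing)), 1)
    axis = np.arange(n_side) * (L0 / n_side)
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    origins = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    counts = _counts_at_origins(config, origins, lam)
    species = sorted(counts)
    return [
        BlockCountSample(
            lam=lam,
            frame_index=config.frame_index,
            block_origin=origins[b],
            counts={s: int(counts[s][b]) for s in species},
        )
        for b in range(origins.shape[0])
    ]


def default_lambda_grid(
    L0: float, n: int = 60, min_block_edge: float = 1.0
) -> np.ndarray:
    """Logarithmically spaced lambda grid on [max(min_block_edge/L0, 0.02), 1].

    The lower bound floors the block edge at ``min_block_edge`` (1 sigma for
    single-component fluids, 2 sigma recommended for mixtures) so that blocks
    never shrink below the scale of a particle.
    """
    lo = max(min_block_edge / L0, 0.02)
    if not lo < 1.0:
        raise ValueError("box too small for the requested minimum block edge")
    return np.geomspace(lo, 1.0, n)


def _pooled_sums(
    traj: Trajectory,
    lambda_grid: np.ndarray,
    n_blocks_per_frame: int,
    seed: int,
    species: list[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame, per-lambda sums of counts and count products.

    Returns (S1, S11, n_samples) where S1[s, f, l] = sum over blocks of N_s,
    S11[a, b, f, l] = sum of N_a * N_b (a <= b), n_samples = blocks per frame.
    One set of origins is drawn per frame and shared across the lambda grid
    (per-lambda moments are unaffected; the shared origins let a single sorted
    pass serve every block size).
    """
    L0 = traj.box_edge
    nlam = lambda_grid.size
    ns = len(species)
    F = len(traj.frames)
    edges = lambda_grid * L0
    S1 = np.zeros((ns, F, nlam))
    S11 = np.zeros((ns, ns, F, nlam))
    rng = np.random.default_rng(seed)
    for f, fr in enumerate(traj.frames):
        origins = rng.uniform(0.0, L0, size=(n_blocks_per_frame, 3))
        # m[s][b, p] = max over axes of wrapped separation: particle p is in
        # block b at scale lambda iff m < lambda * L0
        per_species_counts = []
        for s in species:
            pos = fr.positions[fr.species == s]
            d = np.mod(pos[None, :, :] - origins[:, None, :], L0)
            m = np.sort(np.max(d, axis=-1), axis=1)
            # counts[b, l] via searchsorted on each sorted row
            cnt = np.empty((n_blocks_per_frame, nlam), dtype=np.int64)
            for b in range(n_blocks_per_frame):
                cnt[b] = np.searchsorted(m[b], edges, side="left")
            # lambda == 1 must count everything (coords wrapped => m < L0 always,
            # but guard against m == L0 from rounding)
            cnt[:, edges >= L0] = pos.shape[0]
            per_species_counts.append(cnt)
        for a in range(ns):
            ca = per_species_counts[a].astype(float)
            S1[a, f] = ca.sum(axis=0)
            for b in range(a, ns):
                cb = per_species_counts[b].astype(float)
                S11[a, b, f] = (ca * cb).sum(axis=0)
    return S1, S11, np.full(F, n_blocks_per_frame)


def _jackknife(stat_from_sums, sums: list[np.ndarray], n_per_frame: np.ndarray):
    """Frame-level jackknife of a statistic computed from pooled sums.

    ``sums`` are arrays of shape (F, nlam); ``stat_from_sums`` maps total sums
    (nlam,) and total sample count to the statistic.  Returns (value, stderr).
    """
    F = sums[0].shape[0]
    totals = [s.sum(axis=0) for s in sums]
    n_tot = float(n_per_frame.sum())
    value = stat_from_sums(totals, n_tot)
    if F < 2:
        return value, np.zeros_like(value)
    loo = np.empty((F,) + value.shape)
    for f in range(F):
        t_f = [t - s[f] for t, s in zip(totals, sums)]
        loo[f] = stat_from_sums(t_f, n_tot - float(n_per_frame[f]))
    mean_loo = loo.mean(axis=0)
    var = (F - 1) / F * np.sum((loo - mean_loo) ** 2, axis=0)
    return value, np.sqrt(var)


def fluctuation_curve(
    traj: Trajectory,
    lambda_grid: np.ndarray | None = None,
    n_blocks_per_frame: int = 100,
    seed: int = 0,
) -> FluctuationCurve:
    """chi_T(lambda) = (<N^2> - <N>^2) / <N> over a lambda grid, moments
    pooled over all (frame, block) samples; exact zero at lambda = 1.

    Counts all species together (the single-component estimator).  Standard
    errors by frame-level jackknife.  Deterministic given ``seed``.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(traj.box_edge)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(lambda_grid <= 0) or np.any(lambda_grid > 1):
        raise ValueError("lambda values must lie in (0, 1]")
    species = sorted(traj.species_counts())
    S1, S11, n_per_frame = _pooled_sums(
        traj, lambda_grid, n_blocks_per_frame, seed, species
    )
    # total count over species: S1_tot[f, l], S2_tot[f, l] = sum (sum_s N_s)^2
    S1_tot = S1.sum(axis=0)
    ns = len(species)
    S2_tot = np.zeros_like(S1_tot)
    for a in range(ns):
        for b in range(ns):
            S2_tot += S11[min(a, b), max(a, b)]

    def chi(totals, n):
        t1, t2 = totals
        mean = t1 / n
        var = t2 / n - mean**2
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(mean > 0, var / mean, 0.0)
        return out

    value, err = _jackknife(chi, [S1_tot, S2_tot], n_per_frame)
    return FluctuationCurve(
        lambda_grid=lambda_grid,
        values=value,
        stderr=err,
        n_blocks=np.full(lambda_grid.shape, int(n_per_frame.sum()), dtype=int),
        system={
            "N0": traj.n_particles,
            "L0": traj.box_edge,
            "rho": traj.density,
            "kT": traj.metadata.get("temperature"),
            "n_frames": len(traj.frames),
            "n_blocks_per_frame": n_blocks_per_frame,
            "seed": seed,
        },
        scaled=False,
    )


def kbi_curve(
    traj: Trajectory,
    lambda_grid: np.ndarray | None = None,
    n_blocks_per_frame: int = 1000,
    seed: int = 0,
    species: list[str] | None = None,
) -> KBICurveSet:
    """Finite-size Kirkwood-Buff integrals G_ij(lambda) for every species pair.

    The estimator is symmetric in (i, j) by construction (the cross moment
    <Ni Nj> is computed once per unordered pair).  At lambda = 1 the closed
    box gives zero covariances, hence G_ii -> -1/rho_i and G_ij -> 0 exactly.

    With a single-species trajectory only G_AA is produced (the pure-fluid
    limit of the mixture route); requesting an absent species raises.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(traj.box_edge, min_block_edge=2.0)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(lambda_grid <= 0) or np.any(lambda_grid > 1):
        raise ValueError("lambda values must lie in (0, 1]")
    present = sorted(traj.species_counts())
    if species is None:
        species = present
    missing = [s for s in species if s not in present]
    if missing:
        raise ValueError(f"species {missing} absent from the trajectory")
    S1, S11, n_per_frame = _pooled_sums(
        traj, lambda_grid, n_blocks_per_frame, seed, species
    )
    L0 = traj.box_edge
    V = (lambda_grid * L0) ** 3
    values: dict[tuple[str, str], np.ndarray] = {}
    stderr: dict[tuple[str, str], np.ndarray] = {}
    for a, sa in enumerate(species):
        for b in range(a, len(species)):
            sb = species[b]
            diag = a == b

            def gij(totals, n, _diag=diag):
                t_a, t_b, t_ab = totals
                ma = t_a / n
                mb = t_b / n
                cov = t_ab / n - ma * mb
                with np.errstate(invalid="ignore", divide="ignore"):
                    g = V * cov / (ma * mb)
                    if _diag:
                        g = g - V / ma
                return np.where((ma > 0) & (mb > 0), g, np.nan)

            val, err = _jackknife(
                gij, [S1[a], S1[b], S11[a, b]], n_per_frame
            )
            key = KBICurveSet.pair_key(sa, sb)
            values[key] = val
            stderr[key] = err
    return KBICurveSet(
        lambda_grid=lambda_grid,
        species=list(species),
        values=values,
        stderr=stderr,
        n_blocks=np.full(lambda_grid.shape, int(n_per_frame.sum()), dtype=int),
        rho=traj.species_densities(),
        system={
            "N0": traj.n_particles,
            "L0": L0,
            "rho": traj.density,
            "kT": traj.metadata.get("temperature"),
            "n_frames": len(traj.frames),
            "n_blocks_per_frame": n_blocks_per_frame,
            "seed": seed,
        },
    )
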