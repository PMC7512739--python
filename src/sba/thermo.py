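"""Bulk thermodynamics from extrapolated fluctuation quantities.

Single-component route:  chi_inf = rho kBT kappa_T, so kappa_T =
chi_inf/(rho kBT), and the chemical potential follows from
d mu = d rho' / (rho'^2 kappa_T) integrated between a reference density and
the target density.  Mixture route: the thermodynamic-limit Kirkwood-Buff
integrals give the compressibility and the constant-(P, T) derivative of the
species chemical potential, which is integrated over the species density.

Excess ("residual") quantities subtract the ideal part of the chemical
potential at the same density, temperature and composition: for a mixture the
ideal part is kBT ln(x_A rho) = kBT ln(rho_A), i.e. the sum of the
concentration and total-density terms.  The additive constant of an excess
curve is arbitrary until anchored to an externally computed reference value
(:func:`anchor_excess`); no absolute chemical potential is ever invented.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import ChemPotCurve, CompressibilityTable, KBITable

__all__ = [
    "kappa_from_chi",
    "kappa_from_kbi",
    "dmuA_drhoA",
    "integrate_mu",
    "excess_mu",
    "anchor_excess",
]


def kappa_from_chi(chi_inf: float, rho: float, kT: float):
    """kappa_T = chi_inf / (rho kBT); sigma^3/eps.  chi_inf = 1 recovers the
    ideal gas value 1/(rho kBT)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0) or kT <= 0:
        raise ValueError("rho and kT must be positive")
    return chi_inf / (rho * kT)


def kappa_from_kbi(
    G_AA: float, G_BB: float, G_AB: float, rhoA: float, rhoB: float, kT: float
) -> float:
    """Binary-mixture compressibility from thermodynamic-limit KBIs.

    kappa_T = [1 + rhoA G_AA + rhoB G_BB + rhoA rhoB (G_AA G_BB - G_AB^2)]
              / [kBT (rhoA + rhoB + rhoA rhoB (G_AA + G_BB - 2 G_AB))]

    With all G = 0 this is the ideal gas at total density; with rhoB = 0 it
    reduces to the single-component relation (1 + rhoA G_AA)/(kBT rhoA).
    """
    if kT <= 0 or rhoA < 0 or rhoB < 0 or rhoA + rhoB == 0:
        raise ValueError("kT must be > 0 and densities >= 0 with rhoA+rhoB > 0")
    num = 1.0 + rhoA * G_AA + rhoB * G_BB + rhoA * rhoB * (G_AA * G_BB - G_AB**2)
    den = kT * (rhoA + rhoB + rhoA * rhoB * (G_AA + G_BB - 2.0 * G_AB))
    if abs(den) < 1e-300:
        raise ValueError(
            "vanishing denominator in the KBI compressibility: the input is "
            "thermodynamically unstable"
        )
    return num / den


def dmuA_drhoA(G_AA: float, G_AB: float, rhoA: float, kT: float) -> float:
    """(d mu_A / d rho_A) at constant (P, T) from KBIs:

    kBT * [ 1/rhoA + (G_AB - G_AA) / (1 + rhoA (G_AA - G_AB)) ]

    Only the difference G_AB - G_AA enters; a pole of the denominator signals
    a demixing instability and raises.
    """
    if rhoA <= 0 or kT <= 0:
        raise ValueError("rhoA and kT must be positive")
    den = 1.0 + rhoA * (G_AA - G_AB)
    if abs(den) < 1e-12:
        raise ValueError(
            "1 + rhoA (G_AA - G_AB) ~ 0: demixing instability, derivative "
            "diverges"
        )
    return kT * (1.0 / rhoA + (G_AB - G_AA) / den)


def _refined_grid(axis: np.ndarray, extra: float, refine: int) -> np.ndarray:
    """Subdivide each axis interval ``refine`` times, keeping the original
    nodes and the reference point as exact grid nodes."""
    pieces = [
        np.linspace(axis[i], axis[i + 1], refine + 1)
        for i in range(axis.size - 1)
    ]
    fine = np.unique(np.concatenate(pieces + [np.array([extra])]))
    return fine


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


def integrate_mu(
    table: CompressibilityTable | KBITable,
    reference_density: float,
    refine: int = 128,
) -> ChemPotCurve:
    """Chemical-potential differences by quadrature along the tabulated scan.

    Single-component: delta_mu(rho) = integral_{rho0}^{rho} d rho' /
    (rho'^2 kappa_T(rho')), with chi_inf(rho) interpolated by a monotone
    piecewise cubic (PCHIP) and a composite trapezoid on a ``refine``-times
    subdivided grid.  Mixture: the KBI derivative integrand over rho_A, with
    ``reference_density`` interpreted as the reference rho_A.  delta_mu is
    exactly zero at the reference point.
    """
    if isinstance(table, CompressibilityTable):
        axis = table.rho
        kT = table.kT
        if not axis[0] <= reference_density <= axis[-1]:
            raise ValueError(
                f"reference density {reference_density} outside the table "
                f"range [{axis[0]}, {axis[-1]}]"
            )
        if np.any(table.chi_inf <= 0):
            raise ValueError(
                "non-positive chi_inf in the table: kappa_T must be > 0 on "
                "the integration domain"
            )
        chi = PchipInterpolator(axis, table.chi_inf)
        fine = _refined_grid(axis, reference_density, refine)
        # 1/(rho^2 kappa) = kT/(rho chi)
        integrand = kT / (fine * chi(fine))
        cum = _cumtrapz(integrand, fine)
        ref_val = float(np.interp(reference_density, fine, cum))
        dmu_axis = np.interp(axis, fine, cum) - ref_val
        # exact zero at the reference: snap the coincident node (tolerating
        # float spacing noise in tabulated axes)
        i_ref = int(np.argmin(np.abs(axis - reference_density)))
        if abs(axis[i_ref] - reference_density) <= 1e-9 * max(
            1.0, abs(reference_density)
        ):
            dmu_axis[i_ref] = 0.0
        stderr = _propagate_kappa_errors(table, fine, chi, reference_density)
        return ChemPotCurve(
            axis_name="rho",
            axis=axis,
            delta_mu=dmu_axis,
            kT=kT,
            stderr=stderr,
            reference={"rho0": reference_density, "mu0": None,
                       "provenance": "unanchored"},
            meta={"refine": refine},
        )
    if isinstance(table, KBITable):
        kT = table.kT
        rhoA = table.rhoA
        if np.any(np.diff(rhoA) <= 0):
            order = np.argsort(rhoA)
        else:
            order = np.arange(rhoA.size)
        ra = rhoA[order]
        if not ra[0] <= reference_density <= ra[-1]:
            raise ValueError(
                f"reference rho_A {reference_density} outside the tabulated "
                f"range [{ra[0]}, {ra[-1]}]"
            )
        gaa = PchipInterpolator(ra, table.G_AA[order])
        gab = PchipInterpolator(ra, table.G_AB[order])
        fine = _refined_grid(ra, reference_density, refine)
        den = 1.0 + fine * (gaa(fine) - gab(fine))
        if np.any(np.abs(den) < 1e-12):
            raise ValueError("demixing pole inside the integration domain")
        integrand = kT * (1.0 / fine + (gab(fine) - gaa(fine)) / den)
        cum = _cumtrapz(integrand, fine)
        ref_val = float(np.interp(reference_density, fine, cum))
        dmu_sorted = np.interp(ra, fine, cum) - ref_val
        dmu_axis = np.empty_like(dmu_sorted)
        dmu_axis[order] = dmu_sorted
        exact = np.isclose(rhoA, reference_density, rtol=0, atol=0)
        dmu_axis[exact] = 0.0
        return ChemPotCurve(
            axis_name="xA",
            axis=table.xA,
            delta_mu=dmu_axis,
            kT=kT,
            reference={"rhoA0": reference_density, "mu0": None,
                       "provenance": "unanchored"},
            meta={"refine": refine, "rhoA": table.rhoA.tolist(),
                  "rho_total": (table.rhoA + table.rhoB).tolist()},
        )
    raise TypeError(f"cannot integrate a {type(table).__name__}")


def _propagate_kappa_errors(
    table: CompressibilityTable, fine, chi, reference_density
) -> np.ndarray | None:
    """First-order propagation of independent per-point chi uncertainties
    through the integral (each tabulated state point comes from an independent
    simulation)."""
    if table.chi_err is None:
        return None
    axis = table.rho
    kT = table.kT
    # sensitivity of the integrand at node k to chi_k ~ local panel weight
    half = np.zeros_like(axis)
    half[1:] += 0.5 * np.diff(axis)
    half[:-1] += 0.5 * np.diff(axis)
    dintegrand = kT / (axis * table.chi_inf**2)  # |d/d chi of kT/(rho chi)|
    contrib = (half * dintegrand * table.chi_err) ** 2
    # delta_mu(rho_k) accumulates panels between rho0 and rho_k
    var = np.zeros_like(axis)
    for k in range(axis.size):
        lo, hi = sorted((reference_density, axis[k]))
        inside = (axis >= lo) & (axis <= hi)
        var[k] = contrib[inside].sum()
    return np.sqrt(var)


def excess_mu(curve: ChemPotCurve, kT: float | None = None) -> ChemPotCurve:
    """Subtract the ideal part of the chemical potential.

    Single component (axis rho): delta_mu_ex = delta_mu - kBT ln(rho).
    Mixture (axis xA): the ideal part is kBT ln(x_A rho) = kBT ln(rho_A)
    (concentration plus total-density terms), taken from the per-point rho_A
    recorded by :func:`integrate_mu`.  The additive reference constant is
    carried, never invented.
    """
    kT = curve.kT if kT is None else kT
    if curve.axis_name == "rho":
        if np.any(curve.axis <= 0):
            raise ValueError("densities must be positive")
        ex = curve.delta_mu - kT * np.log(curve.axis)
    elif curve.axis_name == "xA":
        if np.any(curve.axis <= 0):
            raise ValueError("mole fractions must be positive")
        rhoA = np.asarray(curve.meta.get("rhoA"), dtype=float)
        if rhoA is None or rhoA.shape != curve.axis.shape:
            raise ValueError("mixture curve lacks per-point rho_A metadata")
        if np.any(rhoA <= 0):
            raise ValueError("species densities must be positive")
        ex = curve.delta_mu - kT * np.log(rhoA)
    else:
        raise ValueError(f"unknown axis {curve.axis_name!r}")
    return ChemPotCurve(
        axis_name=curve.axis_name,
        axis=curve.axis,
        delta_mu=curve.delta_mu,
        kT=kT,
        delta_mu_excess=ex,
        stderr=curve.stderr,
        reference=dict(curve.reference),
        meta=dict(curve.meta),
    )


def anchor_excess(
    curve: ChemPotCurve, axis_ref: float, mu_ref: float, provenance: str = "external"
) -> ChemPotCurve:
    """Shift the excess curve so it passes exactly through an externally
    supplied reference value ``mu_ref`` at ``axis_ref`` (interpolating between
    tabulated points when needed)."""
    if curve.delta_mu_excess is None:
        raise ValueError("call excess_mu before anchoring")
    if not curve.axis.min() <= axis_ref <= curve.axis.max():
        raise ValueError("anchor point outside the curve range")
    current = float(np.interp(axis_ref, curve.axis, curve.delta_mu_excess))
    shift = mu_ref - current
    out = ChemPotCurve(
        axis_name=curve.axis_name,
        axis=curve.axis,
        delta_mu=curve.delta_mu,
        kT=curve.kT,
        delta_mu_excess=curve.delta_mu_excess + shift,
        stderr=curve.stderr,
        reference={
            **curve.reference,
            "anchor_axis": axis_ref,
            "mu0": mu_ref,
            "provenance": provenance,
        },
        meta=dict(curve.meta),
    )
    return out


def check_monotone_decreasing(kappa: np.ndarray) -> bool:
    """Data-quality check: bulk kappa_T(rho) of a simple repulsive fluid above
    its critical temperature should decrease with density.  Returns True when
    monotone; emits a warning (never an error) otherwise."""
    ok = bool(np.all(np.diff(kappa) < 0))
    if not ok:
        warnings.warn(
            "kappa_T(rho) is not monotonically decreasing; near-critical "
            "behavior or insufficient sampling"
        )
    return ok
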