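"""Finite-size model fits and thermodynamic-limit extrapolation.

All fits are linear least squares of the *scaled* curve lambda*chi(lambda)
(or lambda*G_ij(lambda)) on a small-lambda window, weighted by 1/stderr^2
when per-point uncertainties are available:

* ``linear_lambda``:      lambda*chi = chi_inf * lambda(1-lambda^3) + c/L0
* ``with_inverse_term``:  ... + b2 / lambda        (b2 = c2/L0^2, dimensionless)
* ``kbi``:  lambda*G_ij + delta_ij*lambda^4/rho_i
            = G_inf * lambda(1-lambda^3) + alpha_ij/L0

Using lambda(1-lambda^3) rather than plain lambda as the slope basis differs
only by the lambda^4 term that is negligible in the fit window, but it makes
the fit exact on model-generated data and makes ``linear_lambda`` exactly the
b2 = 0 constrained case of ``with_inverse_term``.

Parameter uncertainties come from the regression covariance: the known-noise
generalized-least-squares covariance (X^T W X)^-1 when stderr values are
supplied, or the residual-scaled OLS covariance otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import FitResult, FluctuationCurve, KBICurveSet

__all__ = [
    "fit_chi_linear",
    "fit_chi_with_inverse_term",
    "fit_kbi",
    "predict_model",
    "default_window",
]

MIN_POINTS = 5


def default_window(L0: float, lambda_max: float = 0.3,
                   zeta_guard: float = 0.0) -> tuple[float, float]:
    """Default fit window [max(2 sigma, zeta_guard)/L0, lambda_max].

    The lower bound keeps blocks larger than both two particle diameters and
    an optional user-supplied correlation-length guard ``zeta_guard`` (sigma);
    the correlation length is never estimated automatically.
    """
    lo = max(2.0, zeta_guard) / L0
    if not lo < lambda_max:
        raise ValueError(
            f"window lower bound {lo:.3g} >= upper bound {lambda_max}: box too "
            "small for this fit window"
        )
    return (lo, lambda_max)


def _wls(X: np.ndarray, y: np.ndarray, sd: np.ndarray | None):
    """Weighted linear least squares.  Returns (beta, cov, residual_rms)."""
    n, p = X.shape
    if sd is not None and np.all(np.isfinite(sd)) and np.all(sd > 0):
        w = 1.0 / sd
        known_noise = True
    else:
        w = np.ones(n)
        known_noise = False
    Xw = X * w[:, None]
    yw = y * w
    # collinearity diagnostics on the column-scaled design
    scale = np.linalg.norm(Xw, axis=0)
    if np.any(scale == 0):
        raise np.linalg.LinAlgError("singular design matrix (zero column)")
    cond = np.linalg.cond(Xw / scale)
    if cond > 1e8:
        warnings.warn(
            f"near-collinear design (condition number {cond:.2e}); "
            "parameters are poorly identified on this window"
        )
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    resid = y - X @ beta
    if known_noise:
        cov = xtx_inv
    else:
        dof = max(n - p, 1)
        s2 = float(resid @ resid) / dof
        cov = xtx_inv * s2
    rms = float(np.sqrt(np.mean(resid**2)))
    return beta, cov, rms


def _windowed_scaled(curve: FluctuationCurve, window: tuple[float, float] | None):
    L0 = float(curve.system.get("L0", np.nan))
    if not np.isfinite(L0) or L0 <= 0:
        raise ValueError("curve metadata must record the box edge L0")
    if window is None:
        window = default_window(L0)
    lo, hi = window
    if not 0 < lo < hi < 1:
        raise ValueError("fit window must satisfy 0 < lo < hi < 1")
    y, sd = curve.scaled_values()
    lam = curve.lambda_grid
    mask = (lam >= lo) & (lam <= hi) & np.isfinite(y)
    if mask.sum() < MIN_POINTS:
        raise ValueError(
            f"only {int(mask.sum())} finite points in window [{lo:.3g}, {hi:.3g}]"
            f"; at least {MIN_POINTS} required"
        )
    sd_w = sd[mask]
    use_sd = sd_w if np.all(sd_w > 0) else None
    return lam[mask], y[mask], use_sd, window, L0


def fit_chi_linear(
    curve: FluctuationCurve, window: tuple[float, float] | None = None
) -> FitResult:
    """Two-parameter fit: slope chi_inf, intercept c/L0 (reported as c in sigma)."""
    lam, y, sd, window, L0 = _windowed_scaled(curve, window)
    X = np.column_stack([lam * (1.0 - lam**3), np.ones_like(lam)])
    beta, cov, rms = _wls(X, y, sd)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return FitResult(
        model_id="linear_lambda",
        params={"chi_inf": float(beta[0]), "c": float(beta[1] * L0)},
        stderr={"chi_inf": float(se[0]), "c": float(se[1] * L0)},
        window=window,
        n_points=lam.size,
        L0=L0,
        residual_rms=rms,
        cov=cov,
    )


def fit_chi_with_inverse_term(
    curve: FluctuationCurve, window: tuple[float, float] | None = None
) -> FitResult:
    """Three-parameter fit adding the 1/lambda boundary term (coefficient b2),
    needed near criticality where the correlation length approaches the block
    size; reports chi_inf, c (= c1, sigma) and dimensionless b2."""
    lam, y, sd, window, L0 = _windowed_scaled(curve, window)
    X = np.column_stack(
        [lam * (1.0 - lam**3), np.ones_like(lam), 1.0 / lam]
    )
    beta, cov, rms = _wls(X, y, sd)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return FitResult(
        model_id="with_inverse_term",
        params={
            "chi_inf": float(beta[0]),
            "c": float(beta[1] * L0),
            "b2": float(beta[2]),
        },
        stderr={
            "chi_inf": float(se[0]),
            "c": float(se[1] * L0),
            "b2": float(se[2]),
        },
        window=window,
        n_points=lam.size,
        L0=L0,
        residual_rms=rms,
        cov=cov,
    )


def fit_kbi(
    curves: KBICurveSet, window: tuple[float, float] | None = None
) -> dict[tuple[str, str], FitResult]:
    """Per-pair fit of the KBI finite-size model.

    The known self-term -lambda^4/rho_i (rho_i from the trajectory) is
    subtracted from the scaled diagonal curves before regression on the basis
    {lambda(1-lambda^3), 1}; slope = G_ij^inf, intercept = alpha_ij/L0.
    """
    L0 = float(curves.system.get("L0", np.nan))
    if not np.isfinite(L0) or L0 <= 0:
        raise ValueError("curve metadata must record the box edge L0")
    if window is None:
        window = default_window(L0)
    lo, hi = window
    results: dict[tuple[str, str], FitResult] = {}
    lam_all = curves.lambda_grid
    for pair in curves.pairs:
        diag = pair[0] == pair[1]
        rho_i = curves.rho[pair[0]] if diag else None
        y_all = lam_all * curves.values[pair]
        sd_all = lam_all * curves.stderr[pair]
        if diag:
            y_all = y_all + lam_all**4 / rho_i
        mask = (lam_all >= lo) & (lam_all <= hi) & np.isfinite(y_all)
        if mask.sum() < MIN_POINTS:
            raise ValueError(
                f"pair {pair}: only {int(mask.sum())} points in window "
                f"[{lo:.3g}, {hi:.3g}]"
            )
        lam = lam_all[mask]
        y = y_all[mask]
        sd = sd_all[mask]
        use_sd = sd if np.all(sd > 0) else None
        X = np.column_stack([lam * (1.0 - lam**3), np.ones_like(lam)])
        beta, cov, rms = _wls(X, y, use_sd)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        results[pair] = FitResult(
            model_id="kbi",
            params={"G_inf": float(beta[0]), "alpha": float(beta[1] * L0)},
            stderr={"G_inf": float(se[0]), "alpha": float(se[1] * L0)},
            window=window,
            n_points=lam.size,
            L0=L0,
            residual_rms=rms,
            cov=cov,
            pair=pair,
            rho_i=rho_i,
            diagonal=diag,
        )
    return results


def predict_model(fit: FitResult, lambda_grid: np.ndarray) -> np.ndarray:
    """Evaluate the fitted finite-size model on any lambda grid.

    Returns *scaled* values (lambda*chi or lambda*G_ij), including the
    lambda^4 ensemble term and, for diagonal KBI fits, the known self-term —
    this is the full-range diagnostic overlay.
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if fit.model_id == "with_inverse_term" and np.any(lam <= 0):
        raise ValueError("lambda must be > 0 for models containing 1/lambda")
    if np.any(lam < 0):
        raise ValueError("lambda must be >= 0")
    base = lam * (1.0 - lam**3)
    if fit.model_id == "linear_lambda":
        return fit.params["chi_inf"] * base + fit.params["c"] / fit.L0
    if fit.model_id == "with_inverse_term":
        return (
            fit.params["chi_inf"] * base
            + fit.params["c"] / fit.L0
            + fit.params["b2"] / lam
        )
    if fit.model_id == "kbi":
        out = fit.params["G_inf"] * base + fit.params["alpha"] / fit.L0
        if fit.diagonal:
            if not fit.rho_i or fit.rho_i <= 0:
                raise ValueError("diagonal KBI model requires rho_i > 0")
            out = out - lam**4 / fit.rho_i
        return out
    raise ValueError(f"unknown model_id {fit.model_id!r}")
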