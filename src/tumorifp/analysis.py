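"""Headline analyses: radius sweeps, necrotic-radius sweeps, critical radii.

Two tumor-scale thresholds fall out of the closed-form center pressure
P(0) = 1 - alpha/sinh(alpha) (uniform tumor) and its necrotic-core
generalisation:

* the *critical tumor radius* — the smallest radius at which the center
  pressure comes within a tolerance eps of the effective pressure
  (P(0) >= 1 - eps); below it, drugs reach the center far more easily;
* the *critical necrotic radius* — the largest necrotic core for which the
  center pressure still sits at its maximum (within eps of the value for a
  core-free tumor); larger cores pull the center pressure down toward zero.

Both maps are monotone (P(0) strictly increasing in alpha, non-increasing in
the necrotic radius), so the thresholds are found by bracketing root finding,
with a dense-scan fallback if monotonicity is ever violated numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analytic
from .tissue import TissueParameters, decay_rate, effective_pressure
from scipy.optimize import brentq

__all__ = [
    "SweepResult",
    "critical_tumor_radius",
    "critical_necrotic_radius",
    "radius_sweep",
    "necrotic_sweep",
    "filtration_profile",
    "BracketError",
]


class BracketError(ValueError):
    """The requested threshold is not bracketed by the search interval."""

    def __init__(self, message: str, P0_low: float, P0_high: float):
        super().__init__(f"{message} (attained P(0) bounds: {P0_low:.6g}, {P0_high:.6g})")
        self.P0_low = P0_low
        self.P0_high = P0_high


@dataclass(frozen=True)
class SweepResult:
    """Per-point center pressure / rim velocity over a radius or core sweep."""

    R_cm: np.ndarray
    Rn_cm: np.ndarray
    rn_bar: np.ndarray
    alpha: np.ndarray
    P_center: np.ndarray
    p_center_mmHg: np.ndarray
    u_rim_um_per_s: np.ndarray
    reached_pe: np.ndarray  # P_center >= 1 - eps
    eps: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "R_cm": self.R_cm,
                "Rn_cm": self.Rn_cm,
                "rn_bar": self.rn_bar,
                "alpha": self.alpha,
                "P_center": self.P_center,
                "p_center_mmHg": self.p_center_mmHg,
                "u_rim_um_per_s": self.u_rim_um_per_s,
                "reached_pe": self.reached_pe,
            }
        )


def _check_eps(eps: float) -> None:
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")


def critical_tumor_radius(
    params: TissueParameters,
    eps: float = 0.01,
    R_range: tuple[float, float] = (1e-4, 10.0),
) -> float:
    """Smallest radius R (cm) with center pressure P(0) >= 1 - eps.

    Solves alpha/sinh(alpha) = eps on the strictly monotone closed form and
    converts through alpha = lambda * R; the returned bracket is tight to a
    relative precision of 1e-6.  Doubling the tissue's decay rate lambda
    halves the critical radius (alpha depends only on the product).
    """
    _check_eps(eps)
    if params.lymph_coeff != 0:
        raise ValueError("critical tumor radius is defined for lymph-free (tumor) tissue")
    lam = decay_rate(params)
    lo, hi = R_range
    if not 0 < lo < hi:
        raise ValueError(f"invalid R_range {R_range}")
    f = lambda R: analytic.center_pressure(lam * R) - (1.0 - eps)
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise BracketError(
            f"R_range {R_range} does not bracket the 1-eps threshold",
            f_lo + (1.0 - eps),
            f_hi + (1.0 - eps),
        )
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-9))


def _center_vs_rn(alpha: float, rn_bar: float) -> float:
    return analytic.center_pressure(alpha, rn_bar)


def critical_necrotic_radius(
    params: TissueParameters, R: float, eps: float = 0.01
) -> float:
    """Largest necrotic radius Rn (cm) keeping the center pressure at its maximum.

    "At its maximum" means within the fraction eps of the center pressure of
    the same tumor with no necrotic core; when R is well above the critical
    tumor radius that maximum is the effective pressure itself.  Found by
    bracketing on the non-increasing map Rn -> P(0), checked for monotonicity
    on a coarse grid (dense-scan fallback with a warning otherwise).
    """
    _check_eps(eps)
    a = decay_rate(params) * R
    P00 = _center_vs_rn(a, 0.0)
    target = (1.0 - eps) * P00
    # numerical monotonicity guard
    grid = np.linspace(0.0, 1.0, 65)
    vals = np.array([_center_vs_rn(a, x) for x in grid])
    if np.any(np.diff(vals) > 1e-10 * max(P00, 1e-300)):
        warnings.warn(
            "center pressure not numerically monotone in the necrotic radius; "
            "falling back to a dense scan",
            RuntimeWarning,
        )
        dense = np.linspace(0.0, 1.0, 4001)
        dv = np.array([_center_vs_rn(a, x) for x in dense])
        ok = dense[dv >= target]
        return float(ok.max() * R) if ok.size else 0.0
    f = lambda rn: _center_vs_rn(a, rn) - target
    if f(1.0) >= 0:  # even a fully necrotic tumor stays above target (impossible: P=0)
        return float(R)
    return float(brentq(f, 0.0, 1.0, xtol=1e-12) * R)


def radius_sweep(
    params: TissueParameters,
    radii,
    rn_bar: float = 0.0,
    eps: float = 0.01,
    p_surr: float = 0.0,
) -> SweepResult:
    """Center pressure / rim velocity across tumor radii at a fixed relative core."""
    _check_eps(eps)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be > 0")
    lam = decay_rate(params)
    p_e = effective_pressure(params)
    alphas = lam * radii
    P0 = np.array([analytic.center_pressure(a, rn_bar) for a in alphas])
    U1 = np.array([analytic.rim_velocity_dimensionless(a, rn_bar) for a in alphas])
    u_rim = params.K * (p_e - p_surr) / radii * U1
    return SweepResult(
        R_cm=radii,
        Rn_cm=rn_bar * radii,
        rn_bar=np.full_like(radii, rn_bar),
        alpha=alphas,
        P_center=P0,
        p_center_mmHg=p_surr + P0 * (p_e - p_surr),
        u_rim_um_per_s=u_rim * 1e4,
        reached_pe=P0 >= 1.0 - eps,
        eps=eps,
    )


def necrotic_sweep(
    params: TissueParameters,
    R: float,
    rn_bars,
    eps: float = 0.01,
    p_surr: float = 0.0,
) -> SweepResult:
    """Center pressure / rim velocity across necrotic radii at fixed tumor radius."""
    _check_eps(eps)
    rn_bars = np.asarray(rn_bars, dtype=float)
    if np.any((rn_bars < 0) | (rn_bars > 1)):
        raise ValueError("rn_bars must lie in [0, 1]")
    a = decay_rate(params) * R
    p_e = effective_pressure(params)
    P0 = np.array([analytic.center_pressure(a, x) for x in rn_bars])
    U1 = np.array([analytic.rim_velocity_dimensionless(a, x) for x in rn_bars])
    u_rim = params.K * (p_e - p_surr) / R * U1
    return SweepResult(
        R_cm=np.full_like(rn_bars, R),
        Rn_cm=rn_bars * R,
        rn_bar=rn_bars,
        alpha=np.full_like(rn_bars, a),
        P_center=P0,
        p_center_mmHg=p_surr + P0 * (p_e - p_surr),
        u_rim_um_per_s=u_rim * 1e4,
        reached_pe=P0 >= 1.0 - eps,
        eps=eps,
    )


def filtration_profile(profile: pd.DataFrame, params: TissueParameters) -> np.ndarray:
    """Transcapillary filtration rate Phi_B = Lp*SV*(p_e - p) per profile row.

    Maximal at the rim (where the pressure is lowest) and near zero at the
    center of a large-alpha tumor — the filtration pattern behind the
    peripheral accumulation of convected drug.
    """
    p = np.asarray(profile["p_mmHg"], dtype=float)
    return params.filtration_coeff * (effective_pressure(params) - p)
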