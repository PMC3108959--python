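"""Tissue-level physiology of interstitial fluid exchange.

A tissue is characterised by the hydraulic conductivity of its interstitium
(Darcy permeability), the filtration properties of its microvascular wall
(Starling's law) and, for normal tissue, a lymphatic drainage coefficient.
Units are fixed repo-wide: lengths in cm, time in s, pressures in mmHg.

Three derived scalars recur throughout the model:

* effective pressure ``p_e = pv - sigma * (pi_v - pi_i)`` — the interstitial
  pressure at which net transcapillary filtration vanishes;
* steady-state pressure ``p_ss`` — the pressure balancing vascular efflux
  against lymphatic influx; equal to ``p_e`` when lymphatics are absent
  (the solid-tumor case);
* the dimensionless ratio of interstitial to vascular flow resistance
  ``alpha = R * sqrt((Lp*SV + lymph_coeff) / K)`` for a sphere of radius R,
  which controls how sharply the pressure profile plateaus at ``p_e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueParameters",
    "DerivedScalars",
    "effective_pressure",
    "steady_state_pressure",
    "decay_rate",
    "alpha",
    "starling_source",
    "lymph_sink",
    "derived_scalars",
]


@dataclass(frozen=True)
class TissueParameters:
    """Physiological constants of one tissue type.

    Parameters
    ----------
    K : float
        Hydraulic conductivity of the interstitium, cm^2 mmHg^-1 s^-1.
    Lp : float
        Hydraulic conductivity of the microvascular wall, cm mmHg^-1 s^-1.
    SV : float
        Vascular surface area per unit tissue volume, cm^-1.
    pv : float
        Vascular (microvascular) pressure, mmHg.
    sigma : float
        Average osmotic reflection coefficient for plasma proteins, in [0, 1].
    pi_v : float
        Osmotic pressure of the plasma, mmHg.
    pi_i : float
        Osmotic pressure of the interstitial fluid, mmHg.
    lymph_coeff : float
        Lymphatic filtration coefficient — the product of lymphatic wall
        hydraulic conductivity and lymphatic surface density, mmHg^-1 s^-1.
        Zero for solid tumors, which have no functional lymphatics.
    pL : float
        Hydrostatic pressure of the lymphatics, mmHg.
    """

    K: float
    Lp: float
    SV: float
    pv: float
    sigma: float
    pi_v: float
    pi_i: float
    lymph_coeff: float = 0.0
    pL: float = 0.0

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.Lp < 0:
            raise ValueError(f"Lp must be >= 0, got {self.Lp}")
        if self.SV < 0:
            raise ValueError(f"SV must be >= 0, got {self.SV}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must be in [0, 1], got {self.sigma}")
        if self.lymph_coeff < 0:
            raise ValueError(f"lymph_coeff must be >= 0, got {self.lymph_coeff}")

    @property
    def filtration_coeff(self) -> float:
        """Vascular filtration coefficient Lp * S/V, mmHg^-1 s^-1."""
        return self.Lp * self.SV


@dataclass(frozen=True)
class DerivedScalars:
    """Scalars derived from tissue parameters for a sphere of radius R."""

    alpha: float  # dimensionless resistance ratio
    p_e: float  # effective pressure, mmHg
    p_ss: float  # steady-state pressure, mmHg


def effective_pressure(params: TissueParameters) -> float:
    """Pressure at which Starling filtration is zero: pv - sigma*(pi_v - pi_i)."""
    return params.pv - params.sigma * (params.pi_v - params.pi_i)


def steady_state_pressure(params: TissueParameters) -> float:
    """Interstitial pressure balancing vascular efflux and lymphatic influx.

    ``p_ss = (Lp*SV*p_e + lymph_coeff*pL) / (Lp*SV + lymph_coeff)``; for a
    lymph-free tissue this reduces exactly to the effective pressure.

    Raises
    ------
    ValueError
        If both the vascular and lymphatic filtration coefficients are zero
        (dead tissue: no fluid exchange, the steady state is undefined).
    """
    a = params.filtration_coeff
    l = params.lymph_coeff
    if a + l <= 0.0:
        raise ValueError(
            "steady-state pressure undefined: Lp*SV + lymph_coeff must be > 0 "
            "(tissue with no vascular or lymphatic exchange)"
        )
    return (a * effective_pressure(params) + l * params.pL) / (a + l)


def decay_rate(params: TissueParameters) -> float:
    """Inverse screening length lambda = sqrt((Lp*SV + lymph_coeff)/K), cm^-1.

    ``alpha = lambda * R``; pressure disturbances decay over ~1/lambda.
    """
    return math.sqrt((params.filtration_coeff + params.lymph_coeff) / params.K)


def alpha(params: TissueParameters, R: float) -> float:
    """Dimensionless interstitial-to-vascular resistance ratio for radius R (cm)."""
    if R <= 0:
        raise ValueError(f"R must be > 0, got {R}")
    return R * decay_rate(params)


def starling_source(params: TissueParameters, p):
    """Volumetric transcapillary filtration rate Phi_B(p), s^-1.

    Starling's law with the affine pressure dependence
    ``Lp*SV*(pv - p - sigma*(pi_v - pi_i)) = Lp*SV*(p_e - p)``; positive for
    interstitial pressure below the effective pressure (fluid enters the
    interstitium), zero at ``p = p_e``.
    """
    return params.filtration_coeff * (effective_pressure(params) - np.asarray(p))


def lymph_sink(params: TissueParameters, p):
    """Volumetric lymphatic drainage rate Phi_L(p) = lymph_coeff*(p - pL), s^-1."""
    return params.lymph_coeff * (np.asarray(p) - params.pL)


def derived_scalars(params: TissueParameters, R: float) -> DerivedScalars:
    return DerivedScalars(
        alpha=alpha(params, R),
        p_e=effective_pressure(params),
        p_ss=steady_state_pressure(params),
    )
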