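"""Closed-form spherically symmetric solutions of the interstitial flow model.

In dimensionless form (r̄ = r/R, P = (p - p_surr)/(p_e - p_surr)) the pressure
in the vascularised shell of an isolated spherical tumor obeys

    (1/r̄²) d/dr̄ (r̄² dP/dr̄) = α² (P - 1),

with symmetry at the center (dP/dr̄ = 0 at r̄ = 0) and P = 0 at the tumor
surface.  Inside a necrotic core the source vanishes and the equation reduces
to Laplace's equation, whose regular spherically symmetric solution is a
constant.  The general shell solution is P = 1 + (A sinh(αr̄) + B cosh(αr̄))/r̄;
boundary/interface conditions fix A and B.

The dimensionless radial Darcy velocity is U = -dP/dr̄; dimensionally,
u = K (p_e - p_surr) / R · U.

These solutions are both the fast path of the package and the oracle against
which the finite-volume solvers are verified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .tissue import (
    TissueParameters,
    decay_rate,
    effective_pressure,
    steady_state_pressure,
)

__all__ = [
    "DimensionlessProfile",
    "solve_isolated_uniform",
    "solve_necrotic",
    "solve_embedded",
    "rim_velocity_dimensionless",
    "center_pressure",
    "EmbeddedProfile",
    "profile_frame",
]

PROFILE_COLUMNS = [
    "rbar",
    "r_cm",
    "P",
    "p_mmHg",
    "U",
    "u_cm_per_s",
    "u_um_per_s",
    "phiB_per_s",
]


@dataclass(frozen=True)
class DimensionlessProfile:
    """Dimensionless pressure/velocity profile on a radial grid in [0, 1]."""

    rbar: np.ndarray  # dimensionless radius
    P: np.ndarray  # (p - p_surr)/(p_e - p_surr)
    U: np.ndarray  # -dP/drbar
    alpha: float
    rn_bar: float = 0.0

    def to_dimensional(
        self, params: TissueParameters, R: float, p_surr: float = 0.0
    ) -> pd.DataFrame:
        """Attach dimensions and the local filtration rate; CSV-ready frame."""
        dp = effective_pressure(params) - p_surr
        p = p_surr + self.P * dp
        u = params.K * dp / R * self.U
        necrotic = self.rbar < self.rn_bar
        phiB = np.where(necrotic, 0.0, params.filtration_coeff * (dp - self.P * dp))
        return pd.DataFrame(
            {
                "rbar": self.rbar,
                "r_cm": self.rbar * R,
                "P": self.P,
                "p_mmHg": p,
                "U": self.U,
                "u_cm_per_s": u,
                "u_um_per_s": u * 1e4,
                "phiB_per_s": phiB,
            }
        )


def _sinh_over_r(a: float, r: np.ndarray) -> np.ndarray:
    """sinh(a r)/r with the removable singularity at r=0 evaluated by series."""
    r = np.asarray(r, dtype=float)
    small = np.abs(a * r) < 1e-4
    r_safe = np.where(r == 0.0, 1.0, r)
    exact = np.sinh(a * r_safe) / r_safe
    x2 = (a * r) ** 2
    series = a * (1.0 + x2 / 6.0 + x2 * x2 / 120.0)
    return np.where(small, series, exact)


def _shell_U(a: float, r: np.ndarray) -> np.ndarray:
    """[a r cosh(a r) - sinh(a r)]/r² with series near r=0 (isolated shell)."""
    r = np.asarray(r, dtype=float)
    small = np.abs(a * r) < 1e-4
    r_safe = np.where(r == 0.0, 1.0, r)
    exact = (a * r_safe * np.cosh(a * r_safe) - np.sinh(a * r_safe)) / r_safe**2
    series = a**3 * r / 3.0 + a**5 * r**3 / 30.0
    return np.where(small, series, exact)


def solve_isolated_uniform(alpha: float, rbar_grid) -> DimensionlessProfile:
    """Uniformly vascularised isolated tumor, P(r̄) = 1 - sinh(αr̄)/(r̄ sinh α).

    The center value is the removable-singularity limit 1 - α/sinh(α); the
    surface satisfies P(1) = 0 (fixed surrounding pressure).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    r = np.asarray(rbar_grid, dtype=float)
    if np.any(r < 0) or np.any(r > 1 + 1e-12):
        raise ValueError("rbar_grid must lie within [0, 1]")
    sh = np.sinh(alpha)
    P = 1.0 - _sinh_over_r(alpha, r) / sh
    U = _shell_U(alpha, r) / sh
    return DimensionlessProfile(rbar=r, P=P, U=U, alpha=alpha, rn_bar=0.0)


def _necrotic_constants(alpha: float, rn_bar: float) -> tuple[float, float]:
    """Shell constants F, G of P = 1 + (F e^{α(r̄-1)} + G e^{-α(r̄-rn̄)})/r̄.

    Shifted exponentials keep the system well conditioned at large α, where
    sinh and cosh coincide to machine precision.  Conditions: P(1) = 0 and
    dP/dr̄(rn̄) = 0 (no flux into the sourceless core).
    """
    a = alpha
    rn = rn_bar
    E = np.exp(-a * (1.0 - rn))
    # P(1) = 0  ->  F + G E = -1
    # P'(rn) = 0 -> F E (a rn - 1) + G (-a rn - 1) = 0
    m = np.array([[1.0, E], [E * (a * rn - 1.0), -a * rn - 1.0]])
    F, G = np.linalg.solve(m, np.array([-1.0, 0.0]))
    return float(F), float(G)


def solve_necrotic(alpha: float, rn_bar: float, rbar_grid) -> DimensionlessProfile:
    """Isolated tumor with a necrotic (sourceless) core of dimensionless radius rn̄.

    The core pressure is constant (regular solution of the spherical Laplace
    equation); pressure and flux are continuous at the core boundary.  At
    rn̄ = 0 the solution reduces exactly to :func:`solve_isolated_uniform`,
    at rn̄ = 1 the tumor is fully necrotic and P ≡ 0.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not 0.0 <= rn_bar <= 1.0:
        raise ValueError(f"rn_bar must be in [0, 1], got {rn_bar}")
    r = np.asarray(rbar_grid, dtype=float)
    if rn_bar == 0.0:
        return solve_isolated_uniform(alpha, r)
    if rn_bar == 1.0:
        z = np.zeros_like(r)
        return DimensionlessProfile(rbar=r, P=z, U=z.copy(), alpha=alpha, rn_bar=1.0)
    F, G = _necrotic_constants(alpha, rn_bar)
    a = alpha
    core_P = 1.0 + (F * np.exp(-a * (1.0 - rn_bar)) + G) / rn_bar
    in_core = r < rn_bar
    r_safe = np.where(in_core, rn_bar, r)  # avoid 0/0 in the unused branch
    ep = F * np.exp(a * (r_safe - 1.0))  # growing branch
    em = G * np.exp(-a * (r_safe - rn_bar))  # decaying branch
    shell_P = 1.0 + (ep + em) / r_safe
    # U = -P' = -[a r (ep - em) - (ep + em)] / r²
    shell_U = -(a * r_safe * (ep - em) - (ep + em)) / r_safe**2
    P = np.where(in_core, core_P, shell_P)
    U = np.where(in_core, 0.0, shell_U)
    return DimensionlessProfile(rbar=r, P=P, U=U, alpha=alpha, rn_bar=rn_bar)


def rim_velocity_dimensionless(alpha: float, rn_bar: float = 0.0) -> float:
    """Dimensionless outward radial velocity at the tumor surface, U(1).

    For the uniform tumor U(1) = α coth α - 1; the dimensional rim speed is
    ``K (p_e - p_surr)/R * U(1)``.  Tends to 0 as α→0 (no vasculature) and to
    α - 1 for large α (all filtration in a thin rim layer).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if rn_bar == 0.0:
        return float(alpha / np.tanh(alpha) - 1.0)
    if rn_bar >= 1.0:
        return 0.0
    F, G = _necrotic_constants(alpha, rn_bar)
    E = np.exp(-alpha * (1.0 - rn_bar))
    # U(1) = -P'(1) with F + G E = -1
    return float(-(alpha * (F - G * E) + 1.0))


def center_pressure(alpha: float, rn_bar: float = 0.0) -> float:
    """Dimensionless pressure at the tumor center, P(0).

    Strictly increasing in α (→1 as α→∞: the center reaches the effective
    pressure) and non-increasing in the necrotic radius; 0 for a fully
    necrotic tumor.
    """
    return float(solve_necrotic(alpha, rn_bar, np.array([0.0])).P[0])


@dataclass(frozen=True)
class EmbeddedProfile:
    """Dimensional two-region (tumor + normal shell) solution.

    ``p_of_r``/``u_of_r`` evaluate the closed form at arbitrary radii in
    (0, R_out]; the sampled arrays use the grid passed to
    :func:`solve_embedded`.
    """

    r_cm: np.ndarray
    p_mmHg: np.ndarray
    u_cm_per_s: np.ndarray
    region: np.ndarray  # 'tumor' / 'normal' per sample
    R: float
    R_out: float
    p_far: float
    p_e_tumor: float
    p_of_r: Callable[[np.ndarray], np.ndarray]
    u_of_r: Callable[[np.ndarray], np.ndarray]

    def to_frame(self, tumor: TissueParameters) -> pd.DataFrame:
        dp = self.p_e_tumor - self.p_far
        scale = dp if dp != 0 else 1.0
        phiB = np.where(
            self.region == "tumor",
            tumor.filtration_coeff * (self.p_e_tumor - self.p_mmHg),
            0.0,
        )
        return pd.DataFrame(
            {
                "rbar": self.r_cm / self.R,
                "r_cm": self.r_cm,
                "P": (self.p_mmHg - self.p_far) / scale,
                "p_mmHg": self.p_mmHg,
                "U": self.u_cm_per_s * self.R / (tumor.K * scale),
                "u_cm_per_s": self.u_cm_per_s,
                "u_um_per_s": self.u_cm_per_s * 1e4,
                "phiB_per_s": phiB,
            }
        )


def solve_embedded(
    tumor: TissueParameters,
    normal: TissueParameters,
    R: float,
    R_out: float,
    p_far: float,
    grid,
) -> EmbeddedProfile:
    """Tumor sphere of radius R embedded in a normal-tissue shell out to R_out.

    Tumor region: p = p_e,t + A sinh(λ_t r)/r.  Normal region:
    p = p_ss,n + (B e^{λ_n (r-R_out)} + C e^{-λ_n (r-R)})/r (shifted
    exponentials for conditioning).  The three constants are fixed by pressure
    continuity at R, Darcy-flux continuity K_t p' = K_n p' at R, and the
    far-field Dirichlet condition p(R_out) = p_far.
    """
    if not 0 < R < R_out:
        raise ValueError(f"need 0 < R < R_out, got R={R}, R_out={R_out}")
    lt = decay_rate(tumor)
    ln = decay_rate(normal)
    if lt <= 0:
        raise ValueError("degenerate parameters: tumor has no vascular exchange")
    pe_t = effective_pressure(tumor)
    if ln == 0.0:
        # exchange-free shell: Laplace solution p = B + C/r
        return _solve_embedded_laplace_shell(tumor, normal, R, R_out, p_far, grid, lt, pe_t)
    pss_n = steady_state_pressure(normal)

    def en_p(r):  # e^{ln (r-R_out)}
        return np.exp(ln * (np.asarray(r, float) - R_out))

    def en_m(r):  # e^{-ln (r-R)}
        return np.exp(-ln * (np.asarray(r, float) - R))

    # unknowns x = [A, B, C]
    m = np.zeros((3, 3))
    rhs = np.zeros(3)
    # pressure continuity at R
    m[0] = [np.sinh(lt * R) / R, -en_p(R) / R, -en_m(R) / R]
    rhs[0] = pss_n - pe_t
    # flux continuity K_t p_t'(R) = K_n p_n'(R)
    m[1, 0] = tumor.K * (lt * R * np.cosh(lt * R) - np.sinh(lt * R)) / R**2
    m[1, 1] = -normal.K * en_p(R) * (ln * R - 1.0) / R**2
    m[1, 2] = -normal.K * en_m(R) * (-ln * R - 1.0) / R**2
    # outer Dirichlet p(R_out) = p_far
    m[2] = [0.0, en_p(R_out) / R_out, en_m(R_out) / R_out]
    rhs[2] = p_far - pss_n
    # column equilibration: sinh(lt*R) spans many orders for large alpha
    scale = np.max(np.abs(m), axis=0)
    if np.any(scale == 0) or not np.all(np.isfinite(scale)):
        raise ValueError("singular interface system: degenerate parameters")
    m_s = m / scale
    cond = np.linalg.cond(m_s)
    if not np.isfinite(cond) or cond > 1e14:
        raise ValueError("singular interface system: degenerate parameters")
    A, B, C = np.linalg.solve(m_s, rhs) / scale

    def p_of_r(r):
        r = np.asarray(r, dtype=float)
        in_t = r <= R
        p_t = pe_t + A * _sinh_over_r(lt, r)
        r_safe = np.where(in_t, R_out, r)
        p_n = pss_n + (B * en_p(r_safe) + C * en_m(r_safe)) / r_safe
        return np.where(in_t, p_t, p_n)

    def u_of_r(r):
        r = np.asarray(r, dtype=float)
        in_t = r <= R
        dp_t = A * _shell_U(lt, r)
        r_safe = np.where(in_t, R_out, r)
        dp_n = (
            B * en_p(r_safe) * (ln * r_safe - 1.0)
            + C * en_m(r_safe) * (-ln * r_safe - 1.0)
        ) / r_safe**2
        K = np.where(in_t, tumor.K, normal.K)
        return -K * np.where(in_t, dp_t, dp_n)

    r = np.asarray(grid, dtype=float)
    if np.any(r < 0) or np.any(r > R_out + 1e-12):
        raise ValueError("grid must lie within [0, R_out]")
    return EmbeddedProfile(
        r_cm=r,
        p_mmHg=p_of_r(r),
        u_cm_per_s=u_of_r(r),
        region=np.where(r <= R, "tumor", "normal"),
        R=R,
        R_out=R_out,
        p_far=p_far,
        p_e_tumor=pe_t,
        p_of_r=p_of_r,
        u_of_r=u_of_r,
    )


def _solve_embedded_laplace_shell(
    tumor: TissueParameters,
    normal: TissueParameters,
    R: float,
    R_out: float,
    p_far: float,
    grid,
    lt: float,
    pe_t: float,
) -> EmbeddedProfile:
    """Embedded case with an exchange-free (sourceless) normal shell.

    The shell pressure obeys Laplace's equation, p = B + C/r; the tumor
    solution keeps its sinh/r form.  Conditions: p and Darcy flux continuous
    at R, p(R_out) = p_far.
    """
    # unknowns [A, B, C]
    m = np.array(
        [
            [np.sinh(lt * R) / R, -1.0, -1.0 / R],
            [
                tumor.K * (lt * R * np.cosh(lt * R) - np.sinh(lt * R)) / R**2,
                0.0,
                normal.K / R**2,
            ],
            [0.0, 1.0, 1.0 / R_out],
        ]
    )
    rhs = np.array([-pe_t, 0.0, p_far])
    scale = np.max(np.abs(m), axis=0)
    A, B, C = np.linalg.solve(m / scale, rhs) / scale

    def p_of_r(r):
        r = np.asarray(r, dtype=float)
        in_t = r <= R
        p_t = pe_t + A * _sinh_over_r(lt, r)
        r_safe = np.where(in_t, R_out, r)
        return np.where(in_t, p_t, B + C / r_safe)

    def u_of_r(r):
        r = np.asarray(r, dtype=float)
        in_t = r <= R
        dp_t = A * _shell_U(lt, r)
        r_safe = np.where(in_t, R_out, r)
        dp_n = -C / r_safe**2
        K = np.where(in_t, tumor.K, normal.K)
        return -K * np.where(in_t, dp_t, dp_n)

    r = np.asarray(grid, dtype=float)
    return EmbeddedProfile(
        r_cm=r,
        p_mmHg=p_of_r(r),
        u_cm_per_s=u_of_r(r),
        region=np.where(r <= R, "tumor", "normal"),
        R=R,
        R_out=R_out,
        p_far=p_far,
        p_e_tumor=pe_t,
        p_of_r=p_of_r,
        u_of_r=u_of_r,
    )


def profile_frame(
    profile: DimensionlessProfile,
    params: TissueParameters,
    R: float,
    p_surr: float = 0.0,
) -> pd.DataFrame:
    """Standard CSV schema (see PROFILE_COLUMNS) for a dimensionless profile."""
    return profile.to_dimensional(params, R, p_surr)
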