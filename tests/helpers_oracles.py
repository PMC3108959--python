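"""Independent brute-force oracles for the closed-form solutions.

Node-centered finite differences on fine uniform grids — deliberately a
different discretisation from the package's cell-centered finite-volume
scheme, so that agreement is a genuine cross-check.
"""

import numpy as np
import scipy.linalg as sla

from tumorifp.tissue import (
    TissueParameters,
    effective_pressure,
)


def fd_necrotic(alpha: float, rn_bar: float, M: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless P on nodes r_j = j/M for the (possibly necrotic) isolated
    sphere: (1/r²)(r²P')' = s(r) α² (P-1), s = 0 in the core, P(1) = 0,
    symmetric at the center."""
    h = 1.0 / M
    r = np.arange(M + 1) * h
    s = (r >= rn_bar).astype(float)
    # half-weight source where the core boundary falls on a node: the node's
    # control volume straddles the interface (keeps the oracle second order)
    on_node = np.abs(r - rn_bar) < h / 2.0
    if rn_bar > 0 and on_node.any():
        s[on_node] = 0.5
    # unknowns: P_0..P_{M-1}; P_M = 0
    n = M
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    rhs = np.zeros(n)
    # center node: Laplacian limit 6(P1 - P0)/h² = s α² (P0 - 1)
    diag[0] = 6.0 / h**2 + s[0] * alpha**2
    upper[0] = -6.0 / h**2
    rhs[0] = s[0] * alpha**2
    rp = (r[1:-1] + h / 2.0) ** 2
    rm = (r[1:-1] - h / 2.0) ** 2
    rc2 = r[1:-1] ** 2
    lower[1:] = -rm / (h**2 * rc2)
    upper[1:] = -rp / (h**2 * rc2)
    diag[1:] = (rp + rm) / (h**2 * rc2) + s[1:-1] * alpha**2
    rhs[1:] = s[1:-1] * alpha**2
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1] = diag
    ab[2, :-1] = lower[1:]
    P = sla.solve_banded((1, 1), ab, rhs)
    return r, np.append(P, 0.0)


def fd_isolated(alpha: float, M: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    return fd_necrotic(alpha, 0.0, M)


def fd_two_region(
    tumor: TissueParameters,
    normal: TissueParameters,
    R: float,
    R_out: float,
    p_far: float,
    M: int = 20_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Dimensional two-region pressure on nodes over [0, R_out]; conductivity
    and affine sources are piecewise constant per segment, the interface at R
    snapped onto a node."""
    # snap R onto the node lattice
    j_int = round(R / R_out * M)
    h = R_out / M
    r = np.arange(M + 1) * h
    seg_mid = r[:-1] + h / 2.0
    K_seg = np.where(seg_mid < r[j_int], tumor.K, normal.K)

    def coeffs(params):
        return (
            params.filtration_coeff,
            params.lymph_coeff,
            effective_pressure(params),
            params.pL,
        )

    a_t, l_t, pe_t, pL_t = coeffs(tumor)
    a_n, l_n, pe_n, pL_n = coeffs(normal)
    in_t = r < r[j_int]
    in_t[j_int] = True  # interface node: average of both sides below
    a = np.where(in_t, a_t, a_n)
    l = np.where(in_t, l_t, l_n)
    pe = np.where(in_t, pe_t, pe_n)
    pL = np.where(in_t, pL_t, pL_n)
    a[j_int] = 0.5 * (a_t + a_n)
    l[j_int] = 0.5 * (l_t + l_n)
    src_c = a + l
    src_rhs = a * pe + l * pL
    src_rhs[j_int] = 0.5 * (a_t * pe_t + l_t * pL_t) + 0.5 * (a_n * pe_n + l_n * pL_n)
    src_c[j_int] = 0.5 * (a_t + l_t) + 0.5 * (a_n + l_n)

    n = M  # unknowns 0..M-1, Dirichlet at M
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    rhs = np.zeros(n)
    diag[0] = 6.0 * K_seg[0] / h**2 + src_c[0]
    upper[0] = -6.0 * K_seg[0] / h**2
    rhs[0] = src_rhs[0]
    rp = K_seg[1:] * (r[1:-1] + h / 2.0) ** 2
    rm = K_seg[:-1] * (r[1:-1] - h / 2.0) ** 2
    rc2 = r[1:-1] ** 2
    lower[1:] = -rm / (h**2 * rc2)
    upper[1:] = -rp / (h**2 * rc2)
    diag[1:] = (rp + rm) / (h**2 * rc2) + src_c[1:-1]
    rhs[1:] = src_rhs[1:-1]
    # Dirichlet at the last node
    rhs[-1] -= upper[-1] * p_far
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[:-1]
    ab[1] = diag
    ab[2, :-1] = lower[1:]
    p = sla.solve_banded((1, 1), ab, rhs)
    return r, np.append(p, p_far)
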