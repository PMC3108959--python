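"""Closed-form spherical solutions vs independent finite-difference oracles."""

import numpy as np
import pytest
import sympy
from hypothesis import given
from hypothesis import strategies as st

from helpers_oracles import fd_isolated, fd_necrotic, fd_two_region
from conftest import make_tumor, zero_source_like
from tumorifp import (
    center_pressure,
    rim_velocity_dimensionless,
    solve_embedded,
    solve_isolated_uniform,
    solve_necrotic,
)
from tumorifp.analytic import _necrotic_constants, profile_frame

alphas = st.floats(min_value=0.05, max_value=60.0)


class TestIsolatedUniform:
    @pytest.mark.parametrize("a, P0", [(1.0, 0.149082), (10.0, 0.999092)])
    def test_center_value(self, a, P0):
        # frozen from 1 - a/sinh(a), cross-checked against the FD oracle below
        prof = solve_isolated_uniform(a, np.array([0.0]))
        assert prof.P[0] == pytest.approx(P0, abs=1e-4)

    @pytest.mark.parametrize("a", [0.5, 1.0, 5.0, 10.0, 33.0])
    def test_matches_finite_difference_oracle(self, a):
        r, P_fd = fd_isolated(a, M=10_000)
        prof = solve_isolated_uniform(a, r)
        assert np.max(np.abs(prof.P - P_fd)) < 5e-5

    @given(a=alphas)
    def test_surface_pressure_zero(self, a):
        assert solve_isolated_uniform(a, np.array([1.0])).P[0] == pytest.approx(
            0.0, abs=1e-12
        )

    @given(a=alphas)
    def test_profile_monotone_decreasing(self, a):
        r = np.linspace(0, 1, 400)
        P = solve_isolated_uniform(a, r).P
        assert np.all(np.diff(P) <= 1e-12)
        assert np.all(P >= -1e-12) and np.all(P <= 1.0 + 1e-12)

    def test_center_pressure_increases_with_alpha(self):
        a = np.linspace(0.1, 40, 200)
        P0 = np.array([center_pressure(x) for x in a])
        assert np.all(np.diff(P0) > 0)

    def test_center_reaches_effective_pressure_for_large_alpha(self):
        assert center_pressure(50.0) == pytest.approx(1.0, abs=1e-15)

    def test_ode_satisfied_symbolically(self):
        """Substituting P = 1 - sinh(ar)/(r sinh a) into
        (1/r²)(r² P')' = a²(P-1) gives an identically zero residual."""
        r, a = sympy.symbols("r a", positive=True)
        P = 1 - sympy.sinh(a * r) / (r * sympy.sinh(a))
        res = sympy.simplify(
            sympy.diff(r**2 * sympy.diff(P, r), r) / r**2 - a**2 * (P - 1)
        )
        assert res == 0

    def test_velocity_is_negative_pressure_gradient(self):
        a = 5.0
        r = np.linspace(0.1, 0.999, 50)
        prof = solve_isolated_uniform(a, r)
        h = 1e-7
        dP = (
            solve_isolated_uniform(a, r + h).P - solve_isolated_uniform(a, r - h).P
        ) / (2 * h)
        assert np.max(np.abs(prof.U + dP)) < 1e-6

    def test_grid_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            solve_isolated_uniform(1.0, np.array([1.5]))
        with pytest.raises(ValueError, match="alpha"):
            solve_isolated_uniform(-1.0, np.array([0.5]))


class TestRimVelocity:
    def test_alpha_one(self):
        # a*coth(a) - 1 at a=1; oracle: numerical derivative of P at the rim
        assert rim_velocity_dimensionless(1.0) == pytest.approx(0.31304, abs=1e-5)
        h = 1e-7
        dnum = -(
            solve_isolated_uniform(1.0, np.array([1.0])).P[0]
            - solve_isolated_uniform(1.0, np.array([1.0 - h])).P[0]
        ) / h
        assert rim_velocity_dimensionless(1.0) == pytest.approx(dnum, abs=1e-5)

    def test_vanishes_without_vasculature(self):
        assert rim_velocity_dimensionless(1e-6) == pytest.approx(0.0, abs=1e-9)

    def test_large_alpha_asymptote(self):
        assert rim_velocity_dimensionless(50.0) == pytest.approx(49.0, abs=1e-9)


class TestNecrotic:
    def test_fully_necrotic_is_zero(self, rbar_grid):
        prof = solve_necrotic(7.0, 1.0, rbar_grid)
        assert np.all(prof.P == 0.0) and np.all(prof.U == 0.0)

    def test_reduces_to_uniform_without_core(self, rbar_grid):
        a = 8.0
        d = np.abs(
            solve_necrotic(a, 0.0, rbar_grid).P - solve_isolated_uniform(a, rbar_grid).P
        )
        assert np.max(d) <= 1e-12

    @pytest.mark.parametrize("a, rn", [(10.0, 0.5), (5.0, 0.2), (33.0, 0.8)])
    def test_matches_finite_difference_oracle(self, a, rn):
        r, P_fd = fd_necrotic(a, rn, M=10_000)
        prof = solve_necrotic(a, rn, r)
        assert np.max(np.abs(prof.P - P_fd)) <= 1e-4

    def test_core_pressure_constant_and_continuous(self):
        a, rn = 6.0, 0.4
        r = np.linspace(0, 1, 1001)
        prof = solve_necrotic(a, rn, r)
        core = prof.P[r < rn]
        assert np.ptp(core) == 0.0
        j = np.searchsorted(r, rn)
        assert abs(prof.P[j] - core[0]) < 1e-6  # continuity at the interface

    def test_shell_ode_satisfied_symbolically(self):
        a_val, rn_val = 7.0, 0.3
        F, G = _necrotic_constants(a_val, rn_val)
        r = sympy.symbols("r", positive=True)
        P = 1 + (F * sympy.exp(a_val * (r - 1)) + G * sympy.exp(-a_val * (r - rn_val))) / r
        res = sympy.diff(r**2 * sympy.diff(P, r), r) / r**2 - a_val**2 * (P - 1)
        for rv in (0.35, 0.6, 0.99):
            assert abs(float(res.subs(r, rv))) < 1e-8
        assert abs(float(P.subs(r, 1))) < 1e-12
        assert abs(float(sympy.diff(P, r).subs(r, rn_val))) < 1e-12

    def test_invalid_core_radius_rejected(self):
        with pytest.raises(ValueError, match="rn_bar"):
            solve_necrotic(1.0, 1.5, np.array([0.5]))


class TestCenterPressure:
    def test_fully_necrotic_zero_any_alpha(self):
        for a in (0.5, 3.0, 40.0):
            assert center_pressure(a, 1.0) == 0.0

    def test_non_increasing_in_core_radius(self):
        for a in (2.0, 10.0, 36.8):
            vals = [center_pressure(a, x) for x in np.linspace(0, 1, 50)]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_against_fd_oracle_on_core_sweep(self):
        a = 10.0
        for rn in (0.1, 0.5, 0.9):
            _, P_fd = fd_necrotic(a, rn, M=10_000)
            assert center_pressure(a, rn) == pytest.approx(P_fd[0], abs=1e-4)


class TestEmbedded:
    def test_interface_continuity(self, baseline):
        tumor, normal = baseline
        R, Ro = 1.4, 4.2
        emb = solve_embedded(tumor, normal, R, Ro, 0.0, np.linspace(0, Ro, 10))
        eps = 1e-9
        p_jump = emb.p_of_r(np.array([R - eps]))[0] - emb.p_of_r(np.array([R + eps]))[0]
        u_jump = emb.u_of_r(np.array([R - eps]))[0] - emb.u_of_r(np.array([R + eps]))[0]
        assert abs(p_jump) < 1e-6 * abs(emb.p_e_tumor)
        assert abs(u_jump) < 1e-4 * abs(emb.u_of_r(np.array([R - eps]))[0])
        assert emb.p_of_r(np.array([Ro]))[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_two_region_fd_oracle(self, baseline):
        tumor, normal = baseline
        R, Ro, p_far = 1.4, 4.2, 0.0
        # M divisible by 3 puts the tissue interface exactly on a node
        r, p_fd = fd_two_region(tumor, normal, R, Ro, p_far, M=21_000)
        p = solve_embedded(tumor, normal, R, Ro, p_far, r).p_mmHg
        assert np.max(np.abs(p - p_fd)) / np.max(np.abs(p_fd)) <= 1e-4

    def test_profile_shape(self, baseline):
        """Elevated, near-flat inside the tumor; decays toward p_far outside."""
        tumor, normal = baseline
        R, Ro = 1.4, 4.2
        r = np.linspace(0, Ro, 400)
        emb = solve_embedded(tumor, normal, R, Ro, 0.0, r)
        inside = emb.p_mmHg[r < 0.8 * R]
        assert np.ptp(inside) < 0.05 * emb.p_e_tumor  # flat core
        assert inside[0] > 0.9 * emb.p_e_tumor  # elevated toward p_e
        outside = emb.p_mmHg[r > R]
        assert np.all(np.diff(outside) < 1e-12)  # monotone decay to p_far

    def test_maximum_principle(self, baseline):
        tumor, normal = baseline
        from tumorifp import effective_pressure, steady_state_pressure

        R, Ro = 1.0, 3.0
        r = np.linspace(0, Ro, 500)
        emb = solve_embedded(tumor, normal, R, Ro, 0.0, r)
        bounds = [
            0.0,
            normal.pL,
            effective_pressure(tumor),
            effective_pressure(normal),
        ]
        assert np.all(emb.p_mmHg >= min(bounds) - 1e-9)
        assert np.all(emb.p_mmHg <= max(bounds) + 1e-9)

    def test_zero_source_shell_reduces_to_laplace(self, baseline):
        tumor, _ = baseline
        shell = zero_source_like(tumor)
        R, Ro = 0.5, 1.0
        emb = solve_embedded(tumor, shell, R, Ro, 0.0, np.linspace(0, Ro, 50))
        # in the shell p = B + C/r: r*(p - B) constant
        r = np.linspace(R + 0.05, Ro, 20)
        p = emb.p_of_r(r)
        B = p[-1] - (p[-1] - p[-2]) / (1 / r[-1] - 1 / r[-2]) * 1 / r[-1]
        const = r * (p - B)
        assert np.ptp(const) < 1e-8 * max(abs(const[0]), 1e-30) + 1e-10

    def test_invalid_radii_rejected(self, baseline):
        tumor, normal = baseline
        with pytest.raises(ValueError):
            solve_embedded(tumor, normal, 2.0, 1.0, 0.0, np.array([0.5]))


def test_profile_frame_schema_and_units(tumor_baseline):
    prof = solve_isolated_uniform(5.0, np.linspace(0, 1, 11))
    frame = profile_frame(prof, tumor_baseline, R=1.0, p_surr=0.0)
    assert list(frame.columns) == [
        "rbar", "r_cm", "P", "p_mmHg", "U", "u_cm_per_s", "u_um_per_s", "phiB_per_s",
    ]
    assert np.allclose(frame["u_um_per_s"], frame["u_cm_per_s"] * 1e4)
    assert frame["p_mmHg"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
    assert np.all(frame["phiB_per_s"] >= 0)
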