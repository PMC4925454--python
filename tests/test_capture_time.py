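"""Steady-state solution, flux/population assembly and scaling laws.

Frozen reference numbers were computed with mpmath at 40 decimal digits:
the basis function from its erfi definition, the coefficients from an
independent 2x2 linear solve of the boundary conditions, the shell
integrals from the erf closed form, and the mean times from arbitrary-
precision quadrature of the assembled expression.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from tethercap import (
    DegenerateGeometryError,
    ScaledGeometry,
    TetherModel,
    ValidationError,
    annihilation_flux,
    basis_f,
    concentration,
    concentration_current,
    delta_integrals,
    mean_capture_time,
    mean_time_scaled,
    ode_residual,
    scaling_exponent,
    solve_coefficients,
    steady_state_population,
    tau_cutoff,
)
from tethercap import capture_time as ct

SQRT3 = math.sqrt(3.0)

geometries = st.tuples(
    st.floats(0.05, 1.5), st.floats(0.1, 2.0), st.floats(0.1, 20.0)
).map(lambda t: ScaledGeometry(t[0], t[0] + t[1], t[0] + t[1] + t[2]))


# ---------------------------------------------------------------- basis_f
@pytest.mark.parametrize(
    "x, expected",
    [
        (0.1, -9.9003326676179904),   # mpmath; series -1/x + x - x^3/3 + ...
        (1.0, -0.27522154099292367),  # mpmath erfi evaluation
    ],
)
def test_basis_f_reference_values(x, expected):
    assert basis_f(x) == pytest.approx(expected, rel=1e-13)


@pytest.mark.parametrize("x", [50.0, 100.0])
def test_basis_f_large_x_asymptote(x):
    # the 1/x terms of the Dawson expansion cancel, leaving f(x) -> 1/x^3
    assert basis_f(x) == pytest.approx(x**-3, rel=5e-3)
    assert basis_f(x) > 0


def test_basis_f_no_overflow_far_out():
    # naive erfi*exp form overflows for x >~ 38; the Dawson form must not
    assert np.isfinite(basis_f(500.0))


def test_basis_f_rejects_nonpositive():
    with pytest.raises(ValidationError):
        basis_f(0.0)
    with pytest.raises(ValidationError):
        basis_f(-1.0)


# ------------------------------------------------------------ ODE residual
@pytest.mark.parametrize("x", [0.3, 0.5, 1.0, 2.0, 5.0])
def test_equilibrium_basis_solves_the_ode(x):
    c = math.exp(-(x**2) / 2.0)
    cp = -x * c
    cpp = (x**2 - 1.0) * c
    assert ode_residual(x, c, cp, cpp) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("x", [0.5, 1.0, 2.0, 5.0])
def test_current_basis_solves_the_ode_by_finite_differences(x):
    h = 1e-5
    c = basis_f(x)
    cp = (basis_f(x + h) - basis_f(x - h)) / (2 * h)
    cpp = (basis_f(x + h) - 2 * c + basis_f(x - h)) / h**2
    assert abs(ode_residual(x, c, cp, cpp)) < 1e-5


def test_non_solution_has_nonzero_residual():
    # c = x: residual = 0 + (2/x + x)*1 + 3x = 2/x + 4x != 0
    assert ode_residual(1.0, 1.0, 1.0, 0.0) == pytest.approx(6.0)


# ----------------------------------------------------------- coefficients
def test_coefficients_match_independent_linear_solve(unit_geometry):
    # 2x2 solve of A e^{-x^2/2} + B f(x) = {0 at a_bar, 1 at R_bar} in mpmath
    sol = solve_coefficients(unit_geometry)
    assert sol.A_inner == pytest.approx(1.9435184130840573, rel=1e-12)
    assert sol.B_inner == pytest.approx(4.2831077138756096, rel=1e-12)
    assert sol.B_outer == 0.0
    assert sol.A_outer == pytest.approx(math.exp(1.5), rel=1e-12)


@given(geometry=geometries)
def test_boundary_conditions_hold_for_any_geometry(geometry):
    sol = solve_coefficients(geometry)
    assert sol.B_inner > 0
    c_a = concentration(geometry.a_bar, sol)
    c_R_inner = sol.A_inner * math.exp(-geometry.R_bar**2 / 2) + sol.B_inner * basis_f(
        geometry.R_bar
    )
    c_R_outer = concentration(geometry.R_bar + 1e-15, sol)
    assert abs(c_a) < 1e-10
    assert c_R_inner == pytest.approx(1.0, rel=1e-10)
    assert c_R_outer == pytest.approx(1.0, rel=1e-10)


def test_flux_diverges_as_shell_narrows():
    b_prev = 0.0
    for eps in (0.1, 0.01, 0.001):
        g = ScaledGeometry(SQRT3 - eps, SQRT3, 3.0)
        b = solve_coefficients(g).B_inner
        assert b > b_prev
        b_prev = b
    assert b_prev > 1e2


def test_degenerate_shell_is_rejected():
    with pytest.raises(DegenerateGeometryError):
        solve_coefficients(ScaledGeometry(SQRT3, SQRT3, 3.0))


# ---------------------------------------------------------------- current
def test_outer_region_carries_no_current(unit_geometry):
    sol = solve_coefficients(unit_geometry)
    x = np.linspace(unit_geometry.R_bar + 1e-9, unit_geometry.Rstar_bar, 7)
    assert np.all(concentration_current(x, sol) == 0.0)
    assert concentration_current(unit_geometry.Rstar_bar, sol) == 0.0


@given(geometry=geometries)
def test_shell_current_is_conserved(geometry):
    # x^2 * j(x) is the same through every inner shell (no sources inside)
    sol = solve_coefficients(geometry)
    xa, xR = geometry.a_bar, geometry.R_bar
    assert xa**2 * concentration_current(xa, sol) == pytest.approx(
        xR**2 * concentration_current(xR, sol), rel=1e-10
    )


def test_flux_consistent_with_current(unit_geometry):
    sol = solve_coefficients(unit_geometry)
    r0, D = 2.0, 3.0
    shell = unit_geometry.a_bar**2 * concentration_current(unit_geometry.a_bar, sol)
    assert annihilation_flux(sol, r0, D) == pytest.approx(
        -4.0 * math.pi * r0 * D * shell, rel=1e-12
    )


def test_flux_is_linear_in_D(unit_geometry):
    sol = solve_coefficients(unit_geometry)
    assert annihilation_flux(sol, 1.0, 4.0) == pytest.approx(
        4.0 * annihilation_flux(sol, 1.0, 1.0)
    )


# -------------------------------------------------------------- integrals
def test_delta_reference_values(unit_geometry):
    d1, d2, d3 = delta_integrals(unit_geometry)
    assert d1 == pytest.approx(0.5133910351867543, abs=1e-10)  # erf closed form
    assert d2 == pytest.approx(1.043491990017484, abs=1e-10)   # mpmath quadrature
    assert d3 > 0


def test_empty_intervals_give_zero():
    d1, d2, d3 = delta_integrals(ScaledGeometry(SQRT3, SQRT3, 3.0))
    assert d1 == d2 == 0.0
    assert d3 > 0
    _, _, d3b = delta_integrals(ScaledGeometry(1.0, 3.0, 3.0))
    assert d3b == 0.0


def test_full_gaussian_moment_limit():
    # integral_0^inf z^2 e^{-z^2/2} dz = sqrt(pi/2)
    d1, _, _ = delta_integrals(ScaledGeometry(1e-8, 40.0, 40.0))
    assert d1 == pytest.approx(math.sqrt(math.pi / 2.0), abs=1e-9)


def test_fused_outer_term_matches_naive_product(unit_geometry):
    naive = math.exp(unit_geometry.R_bar**2 / 2.0) * delta_integrals(unit_geometry)[2]
    fused = ct.exp_weighted_tail(unit_geometry.R_bar, unit_geometry.Rstar_bar)
    assert fused == pytest.approx(naive, rel=1e-10)


# ------------------------------------------------------------- population
@given(geometry=geometries)
def test_population_matches_direct_quadrature(geometry):
    sol = solve_coefficients(geometry)
    r0 = 1.3
    pop = steady_state_population(sol, geometry, r0)
    direct, _ = integrate.quad(
        lambda x: x**2 * concentration(x, sol),
        geometry.a_bar, geometry.Rstar_bar,
        points=[geometry.R_bar], epsabs=1e-12, epsrel=1e-12, limit=200,
    )
    assert pop == pytest.approx(4.0 * math.pi * r0**3 * direct, rel=1e-8)


def test_population_decomposes_outer_term(unit_geometry):
    sol = solve_coefficients(unit_geometry)
    no_outer = ScaledGeometry(1.0, SQRT3, SQRT3)
    sol2 = solve_coefficients(no_outer)
    full = steady_state_population(sol, unit_geometry, 1.0)
    trimmed = steady_state_population(sol2, no_outer, 1.0)
    fused = 4.0 * math.pi * ct.exp_weighted_tail(SQRT3, 3.0)
    assert full - trimmed == pytest.approx(fused, rel=1e-10)


# ---------------------------------------------------------- mean time
def test_capture_is_instant_for_single_segment_tether():
    res = mean_capture_time(TetherModel(N=1))
    assert res.tau_scaled == 0.0
    assert res.mean_time == 0.0


@pytest.mark.parametrize(
    "N, expected",
    [
        (5.0, 2.0767872506660608),
        (10.0, 6.7465117407769793),
        (100.0, 238.94933237239058),
    ],
)
def test_mean_time_reference_values(N, expected):
    # mpmath quadrature of the assembled steady-state expression
    assert mean_capture_time(TetherModel(N=N)).tau_scaled == pytest.approx(
        expected, rel=1e-10
    )


def test_mean_time_is_population_over_flux(default_model):
    res = mean_capture_time(default_model)
    assert res.mean_time == pytest.approx(res.population / res.flux, rel=1e-14)
    assert res.tau_scaled == pytest.approx(res.mean_time / default_model.tau0)


def test_mean_time_scaled_matches_full_assembly(unit_geometry):
    assert mean_time_scaled(unit_geometry) == pytest.approx(
        0.75162353659164807, rel=1e-12
    )


def test_mean_time_increases_with_tether_length():
    taus = [
        mean_capture_time(TetherModel(N=N)).tau_scaled
        for N in (1.5, 2, 5, 10, 50, 200, 1e3, 1e4)
    ]
    assert all(t2 > t1 for t1, t2 in zip(taus, taus[1:]))


def test_three_halves_power_between_decades():
    t4 = mean_capture_time(TetherModel(N=1e4)).tau_scaled
    t6 = mean_capture_time(TetherModel(N=1e6)).tau_scaled
    assert t6 / t4 == pytest.approx(1e3, rel=0.05)


# ------------------------------------------------------------- regressions
def test_scaling_exponent_recovers_pure_power_law(monkeypatch, default_model):
    class _Fake:
        def __init__(self, tau_scaled):
            self.tau_scaled = tau_scaled

    monkeypatch.setattr(
        ct, "mean_capture_time", lambda m: _Fake(0.37 * m.N**2.25)
    )
    slope = ct.scaling_exponent(default_model, np.logspace(1, 3, 10))
    assert slope == pytest.approx(2.25, abs=1e-12)


def test_scaling_exponent_input_validation(default_model):
    with pytest.raises(ValidationError):
        scaling_exponent(default_model, [10.0, 100.0])
    with pytest.raises(ValidationError):
        scaling_exponent(default_model, [10.0, 10.0, 10.0])


# ----------------------------------------------------------------- cutoff
def test_cutoff_tether_length_is_cube_root():
    tau_max, n_star = tau_cutoff(TetherModel(N=2, c_inf=1e-6))
    assert n_star == pytest.approx(100.0, rel=1e-12)
    assert tau_max == pytest.approx(
        mean_capture_time(TetherModel(N=100)).mean_time, rel=1e-12
    )


def test_cutoff_time_decreases_with_ambient_concentration():
    taus = [tau_cutoff(TetherModel(N=2, c_inf=c))[0] for c in (1e-8, 1e-6, 1e-4)]
    assert taus[0] > taus[1] > taus[2]


def test_cutoff_requires_dilute_ambient():
    with pytest.raises(ValidationError):
        tau_cutoff(TetherModel(N=2))
    with pytest.raises(ValidationError):
        tau_cutoff(TetherModel(N=2, c_inf=2.0))
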