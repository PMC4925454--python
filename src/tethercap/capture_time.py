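"""Steady-state advection-diffusion solution and the mean time to capture.

The tethered ligand diffuses (constant ``D``) in the harmonic potential
``kappa*r**2/2`` of the Gaussian tether, between an absorbing capture sphere
at ``r = a`` and a reflecting sphere at the maximal extension ``r = R*``.
In the dimensionless radius ``x = r/r0`` the steady-state concentration
obeys::

    c''(x) + (2/x + x) c'(x) + 3 c(x) = 0

whose general solution is ``c(x) = A*exp(-x**2/2) + B*f(x)`` with the
current-carrying basis function::

    f(x) = sqrt(pi/2) * exp(-x**2/2) * erfi(x/sqrt(2)) - 1/x
         = sqrt(2) * dawsn(x/sqrt(2)) - 1/x        (overflow-safe form)

The equilibrium basis ``exp(-x**2/2)`` carries no current; ``f`` carries a
unit radial current through every shell (``f'(x) + x*f(x) = 1/x**2``).

Particles are injected on the shell ``x = R_bar`` (fixing ``c = 1`` there)
and annihilated at ``x = a_bar``.  The mean time to capture is the
steady-state population divided by the annihilation flux, ``T = N_ss/F``,
which equals the mean first-passage time from ``R_bar`` to ``a_bar``.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import dawsn, erf, erfcx

from .exceptions import DegenerateGeometryError, NumericalError, ValidationError
from .tether_model import ScaledGeometry, TetherModel, scaled_geometry

__all__ = [
    "ConcentrationSolution", "CaptureTimeResult", "basis_f", "basis_f_prime",
    "ode_residual", "solve_coefficients", "concentration",
    "concentration_current", "annihilation_flux", "delta_integrals",
    "steady_state_population", "mean_time_scaled", "mean_capture_time",
    "scaling_exponent", "tau_cutoff",
]

_SQRT2 = math.sqrt(2.0)
_SQRT_HALF_PI = math.sqrt(math.pi / 2.0)
_QUAD_TOL = 1e-10  # absolute and relative adaptive-quadrature tolerance


def basis_f(x):
    """Current-carrying basis solution f(x) = sqrt(2)*dawsn(x/sqrt(2)) - 1/x.

    Equivalent to ``sqrt(pi/2)*exp(-x**2/2)*erfi(x/sqrt(2)) - 1/x`` but free
    of the erfi/exp overflow for x >~ 38.  Accepts scalars or arrays; x > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("basis_f requires x > 0")
    out = _SQRT2 * dawsn(x / _SQRT2) - 1.0 / x
    return out if out.ndim else float(out)


def basis_f_prime(x):
    """Derivative f'(x) = -x*f(x) + 1/x**2 (from the Dawson-function ODE)."""
    x = np.asarray(x, dtype=float)
    out = -x * (_SQRT2 * dawsn(x / _SQRT2) - 1.0 / x) + 1.0 / x**2
    return out if out.ndim else float(out)


def ode_residual(x, c, cp, cpp):
    """Residual c'' + (2/x + x) c' + 3 c of the steady-state equation.

    Used to verify that candidate profiles solve (or fail to solve) the
    radial advection-diffusion equation.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("ode_residual requires x > 0")
    return cpp + (2.0 / x + x) * cp + 3.0 * c


@dataclass(frozen=True)
class ConcentrationSolution:
    """Piecewise coefficients of the steady-state concentration profile.

    Inner region (a_bar <= x <= R_bar): ``A_inner*exp(-x^2/2) + B_inner*f(x)``.
    Outer region (R_bar <= x <= Rstar_bar): pure equilibrium profile,
    ``A_outer*exp(-x^2/2)`` with ``A_outer = exp(R_bar^2/2)`` and
    ``B_outer = 0`` (the reflecting boundary forbids current).  ``A_outer``
    is stored in log space and only materialized on demand.
    """

    A_inner: float
    B_inner: float
    log_A_outer: float
    geometry: ScaledGeometry

    B_outer: float = 0.0  # forced by the zero-current outer boundary

    @property
    def A_outer(self) -> float:
        return math.exp(self.log_A_outer)


def solve_coefficients(geometry: ScaledGeometry) -> ConcentrationSolution:
    """Coefficients satisfying c(a_bar)=0, c(R_bar)=1 and zero outer current.

    Closed forms::

        B_inner = 1 / [f(R_bar) - f(a_bar)*exp(-(R_bar^2 - a_bar^2)/2)]
        A_inner = -f(a_bar) * exp(a_bar^2/2) * B_inner
        A_outer = exp(R_bar^2/2),  B_outer = 0
    """
    ab, Rb = geometry.a_bar, geometry.R_bar
    if geometry.is_degenerate:
        raise DegenerateGeometryError(
            "a_bar == R_bar: capture is instantaneous; use mean_capture_time"
        )
    fa, fR = basis_f(ab), basis_f(Rb)
    denom = fR - fa * math.exp(-(Rb**2 - ab**2) / 2.0)
    if abs(denom) < 1e3 * np.finfo(float).eps * max(abs(fR), abs(fa), 1.0):
        raise NumericalError(f"ill-conditioned coefficient solve: denominator {denom}")
    B_inner = 1.0 / denom
    A_inner = -fa * math.exp(ab**2 / 2.0) * B_inner
    return ConcentrationSolution(
        A_inner=A_inner, B_inner=B_inner, log_A_outer=Rb**2 / 2.0, geometry=geometry
    )


def concentration(x, solution: ConcentrationSolution):
    """Assembled steady-state concentration c(x) on [a_bar, Rstar_bar]."""
    g = solution.geometry
    x = np.asarray(x, dtype=float)
    if np.any((x < g.a_bar * (1 - 1e-12)) | (x > g.Rstar_bar * (1 + 1e-12))):
        raise ValidationError("x outside [a_bar, Rstar_bar]")
    inner = solution.A_inner * np.exp(-x**2 / 2.0) + solution.B_inner * basis_f(
        np.maximum(x, g.a_bar)
    )
    outer = np.exp(solution.log_A_outer - x**2 / 2.0)  # = exp((R_bar^2 - x^2)/2)
    out = np.where(x <= g.R_bar, inner, outer)
    return out if out.ndim else float(out)


def concentration_current(x, solution: ConcentrationSolution):
    """Scaled radial current j(x) = -(c'(x) + x*c(x)).

    The physical radial current is ``(D/r0) * j(x)``.  The equilibrium basis
    contributes nothing; the f-basis carries ``j*x**2 = -B`` through every
    shell, so in the outer (pure equilibrium) region the current vanishes,
    satisfying the reflecting condition at ``Rstar_bar``.
    """
    g = solution.geometry
    x = np.asarray(x, dtype=float)
    if np.any((x < g.a_bar * (1 - 1e-12)) | (x > g.Rstar_bar * (1 + 1e-12))):
        raise ValidationError("x outside [a_bar, Rstar_bar]")
    xs = np.maximum(x, g.a_bar)
    # inner: j = -B*(f' + x f) = -B/x^2 ; equilibrium part cancels exactly
    inner = -solution.B_inner / xs**2
    out = np.where(x <= g.R_bar, inner, 0.0)
    return out if out.ndim else float(out)


def annihilation_flux(solution: ConcentrationSolution, r0: float, D: float) -> float:
    """Particle annihilation rate at the capture sphere, F = 4*pi*D*B_inner*r0."""
    return 4.0 * math.pi * D * solution.B_inner * r0


def _gauss_moment_antiderivative(z: float) -> float:
    """Antiderivative of z^2*exp(-z^2/2): -z*exp(-z^2/2) + sqrt(pi/2)*erf(z/sqrt(2))."""
    return -z * math.exp(-(z**2) / 2.0) + _SQRT_HALF_PI * erf(z / _SQRT2)


def _quad(fun, lo: float, hi: float) -> float:
    val, err = integrate.quad(fun, lo, hi, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=200)
    if not math.isfinite(val) or err > 1e3 * _QUAD_TOL * max(1.0, abs(val)):
        raise NumericalError(
            f"quadrature on [{lo}, {hi}] did not converge: value={val}, err={err}"
        )
    return val


def exp_weighted_tail(y: float, upper: float) -> float:
    """Overflow-safe exp(y^2/2) * integral_y^upper z^2 exp(-z^2/2) dz.

    Evaluated via scaled complementary error functions::

        y - upper*E + sqrt(pi/2)*(erfcx(y/sqrt(2)) - E*erfcx(upper/sqrt(2)))

    with ``E = exp((y^2 - upper^2)/2) <= 1``.  Every term stays bounded for
    arbitrarily large radii.
    """
    if upper < y:
        raise ValidationError("upper < y in exp_weighted_tail")
    E = math.exp((y**2 - upper**2) / 2.0)
    return (
        y
        - upper * E
        + _SQRT_HALF_PI * (erfcx(y / _SQRT2) - E * erfcx(upper / _SQRT2))
    )


def delta_integrals(geometry: ScaledGeometry) -> tuple[float, float, float]:
    """The three shell integrals (Delta1, Delta2, Delta3).

    Delta1 = int_{a_bar}^{R_bar} z^2 exp(-z^2/2) dz
    Delta2 = int_{a_bar}^{R_bar} z^2 [f(z) + 1/z] dz
    Delta3 = int_{R_bar}^{Rstar_bar} z^2 exp(-z^2/2) dz

    Delta1 and Delta3 are computed by adaptive quadrature and cross-checked
    against the erf closed form; Delta2's integrand is evaluated as
    ``z^2*sqrt(2)*dawsn(z/sqrt(2))``, which removes the 1/z singularity of
    f at the origin.
    """
    ab, Rb, Rsb = geometry.a_bar, geometry.R_bar, geometry.Rstar_bar
    gauss = lambda z: z**2 * math.exp(-(z**2) / 2.0)
    d1 = _quad(gauss, ab, Rb) if Rb > ab else 0.0
    d3 = _quad(gauss, Rb, Rsb) if Rsb > Rb else 0.0
    for val, lo, hi, name in ((d1, ab, Rb, "Delta1"), (d3, Rb, Rsb, "Delta3")):
        closed = _gauss_moment_antiderivative(hi) - _gauss_moment_antiderivative(lo)
        if abs(val - closed) > 1e-9 * max(1.0, abs(closed)):
            raise NumericalError(f"{name} quadrature {val} != closed form {closed}")
    d2 = (
        _quad(lambda z: z**2 * _SQRT2 * dawsn(z / _SQRT2), ab, Rb) if Rb > ab else 0.0
    )
    return d1, d2, d3


def steady_state_population(
    solution: ConcentrationSolution, geometry: ScaledGeometry, r0: float
) -> float:
    """Steady-state particle number N_ss = 4*pi*r0^3 * [bracket].

    bracket = A_inner*Delta1 + B_inner*Delta2 + A_outer*Delta3
              - (B_inner/2)*(R_bar^2 - a_bar^2)

    The ``A_outer*Delta3`` product is computed as the fused integral
    ``int_{R_bar}^{Rstar_bar} z^2 exp((R_bar^2 - z^2)/2) dz`` so the bare
    ``exp(R_bar^2/2)`` is never materialized.
    """
    bracket = _population_bracket(solution, geometry)
    pop = 4.0 * math.pi * r0**3 * bracket
    if pop < -1e-12 * max(1.0, abs(pop)):
        raise NumericalError(f"negative steady-state population {pop}")
    return max(pop, 0.0)


def _population_bracket(
    solution: ConcentrationSolution, geometry: ScaledGeometry
) -> float:
    ab, Rb = geometry.a_bar, geometry.R_bar
    d1, d2, _ = delta_integrals(geometry)
    fused_outer = exp_weighted_tail(Rb, geometry.Rstar_bar)  # = A_outer * Delta3
    return (
        solution.A_inner * d1
        + solution.B_inner * d2
        + fused_outer
        - solution.B_inner / 2.0 * (Rb**2 - ab**2)
    )


def mean_time_scaled(geometry: ScaledGeometry) -> float:
    """Mean capture time for a scaled geometry, in units of r0^2/D.

    ``T = bracket/B_inner``, the ratio of steady-state population to
    annihilation flux with the common 4*pi*r0 factors cancelled.  The
    degenerate zero-width shell returns 0 exactly.
    """
    if geometry.is_degenerate:
        return 0.0
    solution = solve_coefficients(geometry)
    return _population_bracket(solution, geometry) / solution.B_inner


@dataclass(frozen=True)
class CaptureTimeResult:
    """Mean-capture-time computation for one tether configuration."""

    flux: float
    population: float
    mean_time: float
    tau_scaled: float
    deltas: tuple[float, float, float]
    model: TetherModel
    geometry: ScaledGeometry
    solution: ConcentrationSolution | None


def mean_capture_time(model: TetherModel) -> CaptureTimeResult:
    """Mean time for the tethered ligand to first reach the capture sphere.

    Assembles the scaled geometry (injection at ``R_rms = b*sqrt(N)``),
    solves for the concentration coefficients, and forms
    ``T = N_ss/F``; ``tau_scaled`` is ``T/tau0``.  At ``N = 1`` with
    ``a = b`` the start radius coincides with the capture radius and the
    mean time is exactly zero (the coefficient solve is singular there and
    is bypassed).
    """
    geometry = scaled_geometry(model)
    if geometry.is_degenerate:
        return CaptureTimeResult(
            flux=math.inf, population=0.0, mean_time=0.0, tau_scaled=0.0,
            deltas=(0.0, 0.0, delta_integrals(geometry)[2]),
            model=model, geometry=geometry, solution=None,
        )
    solution = solve_coefficients(geometry)
    r0, D = model.r0, model.D
    flux = annihilation_flux(solution, r0, D)
    population = steady_state_population(solution, geometry, r0)
    mean_time = population / flux  # = r0^2/(D*B_inner) * bracket
    return CaptureTimeResult(
        flux=flux,
        population=population,
        mean_time=mean_time,
        tau_scaled=mean_time / model.tau0,
        deltas=delta_integrals(geometry),
        model=model,
        geometry=geometry,
        solution=solution,
    )


def scaling_exponent(
    template: TetherModel, N_grid: Sequence[float]
) -> float:
    """Least-squares slope of log(tau/tau0) versus log(N).

    In the long-tether regime the mean capture time follows the power law
    ``tau(N) ~ tau0 * N**(3/2)`` (start radius grows as N^(1/2), spring
    constant falls as 1/N), so the slope approaches 1.5.
    """
    N_grid = np.asarray(list(N_grid), dtype=float)
    if N_grid.size < 3:
        raise ValidationError("scaling_exponent needs at least 3 grid points")
    if np.ptp(N_grid) == 0:
        raise ValidationError("N_grid values are all equal")
    tau = np.array(
        [mean_capture_time(template.replace(N=N)).tau_scaled for N in N_grid]
    )
    slope, _ = np.polyfit(np.log(N_grid), np.log(tau), 1)
    return float(slope)


def tau_cutoff(model: TetherModel) -> tuple[float, float]:
    """Competitive-binding cutoff (tau_max, N_star).

    For tethers longer than ``N* = (b^3 c_inf)^(-1/3)`` a free ligand from
    the ambient solution (mean spacing ``c_inf^(-1/3)``) out-competes the
    slow tethered capture, bounding the useful capture time by
    ``tau_max = tau(N*) ~ tau0*(b^3 c_inf)^(-1/2)``.  Requires a dilute
    ambient concentration, ``b^3*c_inf < 1``.
    """
    if model.c_inf is None or model.c_inf <= 0:
        raise ValidationError("tau_cutoff requires c_inf > 0")
    phi = model.b**3 * model.c_inf
    if phi >= 1.0:
        raise ValidationError(
            f"b^3*c_inf = {phi} >= 1: non-dilute regime outside model validity"
        )
    N_star = phi ** (-1.0 / 3.0)
    tau_max = mean_capture_time(model.replace(N=N_star)).mean_time
    return tau_max, N_star
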