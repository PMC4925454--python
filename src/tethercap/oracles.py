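"""Independent checks of the mean capture time.

Two routes to the same number that share no code with the steady-state
solution in :mod:`tethercap.capture_time`:

* :func:`mfpt_quadrature` — the backward-equation closed form for the mean
  exit time of 1-D radial diffusion in the potential x^2/2 with an absorbing
  inner and reflecting outer sphere,

      T(x0) = int_{a_bar}^{x0} dy exp(y^2/2)/y^2 int_y^{Rstar_bar} z^2 exp(-z^2/2) dz

  (in units of r0^2/D).

* :func:`simulate_fpt` — an overdamped Brownian dynamics simulation
  (Euler-Maruyama) of the 3-D motion with drift -(D/r0^2) r, absorbing at
  |r| = a and radially mirror-reflecting at |r| = R*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from numba import njit

from .capture_time import exp_weighted_tail, mean_capture_time
from .exceptions import NumericalError, ValidationError
from .tether_model import ScaledGeometry, TetherModel, scaled_geometry

__all__ = ["BDConfig", "FPTSample", "mfpt_quadrature", "simulate_fpt"]


def mfpt_quadrature(r_start: float, geometry: ScaledGeometry) -> float:
    """Mean first-passage time from x = r_start to the capture sphere.

    Backward-Kolmogorov closed form for radial diffusion in the harmonic
    potential, returned in units of r0^2/D.  The inner (tail) integral is
    evaluated in the overflow-safe erfcx form of
    :func:`tethercap.capture_time.exp_weighted_tail`, so the quadrature is
    stable out to arbitrarily large reflecting radii.
    """
    ab, Rsb = geometry.a_bar, geometry.Rstar_bar
    if not (ab <= r_start <= Rsb * (1 + 1e-12)):
        raise ValidationError(
            f"r_start={r_start} outside [a_bar, Rstar_bar]=[{ab}, {Rsb}]"
        )
    if r_start == ab:
        return 0.0
    val, err = integrate.quad(
        lambda y: exp_weighted_tail(y, Rsb) / y**2,
        ab, r_start, epsabs=1e-12, epsrel=1e-12, limit=500,
    )
    if not math.isfinite(val) or err > 1e-8 * max(1.0, abs(val)):
        raise NumericalError(f"MFPT quadrature failed: value={val}, err={err}")
    return val


@dataclass(frozen=True)
class BDConfig:
    """Brownian-dynamics run settings.

    ``dt`` is the integration time step in units of tau0; the seed is
    mandatory so that every run is reproducible.  ``max_steps`` caps each
    trajectory; None picks a cap of 500x the analytic mean time.
    """

    dt: float
    n_traj: int
    seed: int
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValidationError(f"dt must be > 0, got {self.dt}")
        if self.n_traj < 1:
            raise ValidationError(f"n_traj must be >= 1, got {self.n_traj}")
        if self.max_steps is not None and self.max_steps < 1:
            raise ValidationError("max_steps must be >= 1")


@dataclass(frozen=True)
class FPTSample:
    """Sample statistics of simulated first-passage times."""

    mean: float
    stderr: float
    n_absorbed: int
    n_censored: int

    @property
    def n_traj(self) -> int:
        return self.n_absorbed + self.n_censored

    @property
    def censored_fraction(self) -> float:
        return self.n_censored / self.n_traj


_RNG_BUF = 49152  # normals drawn per batch; multiple of 3


@njit(cache=True)
def _bd_trajectories(n_traj, a, R_star, R0, gamma, sigma, dt, max_steps, seed):
    """First-passage times of n_traj overdamped trajectories.

    Euler-Maruyama: each component moves by -gamma*x + sigma*N(0,1) per
    step, with gamma = (D/r0^2)*dt and sigma = sqrt(2*D*dt).  Normal
    deviates are drawn in large batches (sequence fixed by the seed, so
    runs are bit-reproducible).  Returns (times, absorbed flags).
    """
    np.random.seed(seed)
    times = np.empty(n_traj)
    absorbed = np.zeros(n_traj, dtype=np.bool_)
    a2 = a * a
    R_star2 = R_star * R_star
    buf = np.random.standard_normal(_RNG_BUF)
    idx = 0
    for i in range(n_traj):
        # uniform start on the sphere |r| = R0
        while True:
            if idx + 3 > _RNG_BUF:
                buf = np.random.standard_normal(_RNG_BUF)
                idx = 0
            x, y, z = buf[idx], buf[idx + 1], buf[idx + 2]
            idx += 3
            n = math.sqrt(x * x + y * y + z * z)
            if n > 1e-12:
                break
        x, y, z = R0 * x / n, R0 * y / n, R0 * z / n
        steps = 0
        while steps < max_steps:
            if idx + 3 > _RNG_BUF:
                buf = np.random.standard_normal(_RNG_BUF)
                idx = 0
            x = x - gamma * x + sigma * buf[idx]
            y = y - gamma * y + sigma * buf[idx + 1]
            z = z - gamma * z + sigma * buf[idx + 2]
            idx += 3
            steps += 1
            r2 = x * x + y * y + z * z
            if r2 <= a2:
                absorbed[i] = True
                break
            if r2 > R_star2:
                r = math.sqrt(r2)
                s = (2.0 * R_star - r) / r  # radial mirror reflection
                x *= s
                y *= s
                z *= s
        times[i] = steps * dt
    return times, absorbed


def simulate_fpt(model: TetherModel, config: BDConfig) -> FPTSample:
    """Simulate first-passage times of the tethered ligand.

    Trajectories start uniformly on the sphere ``|r| = R_rms``, drift with
    ``-kappa*mu*r = -(D/r0^2)*r`` and diffuse with constant ``D``; a step
    ending with ``|r| <= a`` absorbs, one ending beyond ``R*`` is mirrored
    radially.  Deterministic given ``config.seed``.

    Censored trajectories (hitting ``max_steps``) trigger a warning; an
    all-censored run is an error.
    """
    geometry = scaled_geometry(model)
    if geometry.is_degenerate:
        raise ValidationError("degenerate geometry: start radius equals capture radius")
    analytic = mean_capture_time(model).mean_time
    dt = config.dt * model.tau0  # config.dt is in units of tau0
    max_steps = config.max_steps
    if max_steps is None:
        max_steps = int(math.ceil(500.0 * analytic / dt))
    if max_steps * dt < 100.0 * analytic:
        warnings.warn(
            f"max_steps*dt = {max_steps * dt:g} is below 100x the analytic mean "
            f"time {analytic:g}; censoring is likely",
            stacklevel=2,
        )
    gamma = model.D / model.r0**2 * dt
    sigma = math.sqrt(2.0 * model.D * dt)
    times, absorbed = _bd_trajectories(
        config.n_traj, model.a, model.R_star, model.R_rms,
        gamma, sigma, dt, max_steps, config.seed,
    )
    n_abs = int(absorbed.sum())
    n_cen = config.n_traj - n_abs
    if n_abs == 0:
        raise NumericalError("all trajectories censored; increase max_steps")
    if n_cen > 0:
        warnings.warn(f"{n_cen} of {config.n_traj} trajectories censored", stacklevel=2)
    t_abs = times[absorbed]
    mean = float(t_abs.mean())
    stderr = float(t_abs.std(ddof=1) / math.sqrt(n_abs)) if n_abs > 1 else math.inf
    return FPTSample(mean=mean, stderr=stderr, n_absorbed=n_abs, n_censored=n_cen)
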