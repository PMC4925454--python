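"""Three-state binding kinetics of the tethered ligand dimer.

States: (I) free tethered dimer, (II) singly bound, (III) doubly bound.
Transitions: I->II at ``r_on``, II->I at ``r_off``, II->III at
``r_capture = 1/tau(N)`` (the inverse mean capture time of the tethered
second head), III->I at ``r_off_double`` (slow unbinding of the doubly
bound complex).  The backward III->II transition is slower still and is
omitted from the model.

The steady state gives the closed-form doubly-bound-to-free ratio

    P_III/P_I = (r_on/r_off_double) * 1/(1 + tau*r_off)

and comparing tethered (``r_capture = 1/tau``) with untethered
(``r_capture = r_on``) dimers yields the avidity enhancement factor

    R = (1 + Kd) / (1 + r_on*tau*Kd),    1 <= R <= 1 + Kd,

where ``Kd = r_off/r_on`` is the single-bond dissociation constant scaled
by the membrane receptor concentration.  A tethered-dimer concentration
``c0`` doubly binds like an untethered concentration ``R*c0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .exceptions import ValidationError

__all__ = [
    "KineticRates", "StateProbabilities", "rate_matrix", "steady_state",
    "evolve", "bound_ratio", "enhancement", "effective_concentration",
]


@dataclass(frozen=True)
class KineticRates:
    """Transition rates of the three-state model (any consistent 1/time unit).

    ``r_capture`` may be ``math.inf`` to represent instantaneous capture
    (tau = 0).  ``Kd`` defaults to ``r_off/r_on``; supplying an inconsistent
    explicit value is an error.
    """

    r_on: float
    r_off: float
    r_off_double: float
    r_capture: float
    Kd: float | None = None

    def __post_init__(self) -> None:
        for name in ("r_on", "r_off", "r_off_double", "r_capture"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise ValidationError(f"rate {name}={v} must be >= 0")
        if self.Kd is not None:
            if self.r_on > 0 and not math.isclose(self.Kd, self.r_off / self.r_on,
                                                  rel_tol=1e-9, abs_tol=0.0):
                raise ValidationError(
                    f"Kd={self.Kd} inconsistent with r_off/r_on={self.r_off / self.r_on}"
                )
        if self.r_off_double >= self.r_off > 0:
            warnings.warn(
                "r_off_double >= r_off: the doubly bound state is expected to "
                "unbind much more slowly than the singly bound one",
                stacklevel=2,
            )

    @property
    def dissociation_constant(self) -> float:
        if self.Kd is not None:
            return self.Kd
        if self.r_on == 0:
            raise ValidationError("Kd undefined: r_on = 0 and no explicit Kd")
        return self.r_off / self.r_on


@dataclass(frozen=True)
class StateProbabilities:
    """Occupancies of states I (free), II (singly bound), III (doubly bound)."""

    P_I: float
    P_II: float
    P_III: float

    def __post_init__(self) -> None:
        probs = (self.P_I, self.P_II, self.P_III)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
            raise ValidationError(f"probabilities out of [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValidationError(f"probabilities sum to {sum(probs)}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.P_I, self.P_II, self.P_III])


def rate_matrix(rates: KineticRates) -> np.ndarray:
    """Generator M of dP/dt = M @ P (columns sum to zero)."""
    if math.isinf(rates.r_capture):
        raise ValidationError("rate_matrix requires finite r_capture")
    return np.array([
        [-rates.r_on, rates.r_off, rates.r_off_double],
        [rates.r_on, -(rates.r_off + rates.r_capture), 0.0],
        [0.0, rates.r_capture, -rates.r_off_double],
    ])


def steady_state(rates: KineticRates) -> StateProbabilities:
    """Steady state of the three-state chain.

    Solves the balance equations ``P_I*r_on = P_II*(r_off + r_capture)`` and
    ``P_II*r_capture = P_III*r_off_double`` with normalization.  Degenerate
    chains are resolved as exact limits: ``r_off_double = 0`` with capture
    active makes state III absorbing (P_III = 1); ``r_capture = inf``
    (instantaneous capture) empties state II.
    """
    ron, roff = rates.r_on, rates.r_off
    rcap, roff2 = rates.r_capture, rates.r_off_double
    if ron == 0 and roff == 0 and rcap == 0 and roff2 == 0:
        raise ValidationError("all rates zero: steady state undefined")
    if ron == 0:
        raise ValidationError("r_on = 0: the chain cannot leave state I")
    if roff2 == 0 and rcap > 0:
        return StateProbabilities(0.0, 0.0, 1.0)  # absorbing doubly bound state
    if math.isinf(rcap):
        # instantaneous capture: II empties, III/I -> r_on/r_off_double
        w3 = ron / roff2
        return StateProbabilities(1.0 / (1.0 + w3), 0.0, w3 / (1.0 + w3))
    if roff + rcap == 0:
        return StateProbabilities(0.0, 1.0, 0.0)  # state II absorbing
    w1 = 1.0
    w2 = ron / (roff + rcap)
    w3 = 0.0 if rcap == 0 else w2 * rcap / roff2
    total = w1 + w2 + w3
    return StateProbabilities(w1 / total, w2 / total, w3 / total)


def evolve(
    rates: KineticRates, p0: StateProbabilities, t_grid
) -> np.ndarray:
    """Transient occupancies on t_grid, shape (len(t_grid), 3).

    Propagates the linear system exactly via the matrix exponential of the
    generator, so probability is conserved to machine precision at every
    output time.
    """
    M = rate_matrix(rates)
    p0_vec = p0.as_array()
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.empty((t_grid.size, 3))
    for i, t in enumerate(t_grid):
        out[i] = expm(M * t) @ p0_vec
    if np.any(out < -1e-9):
        raise ValidationError("negative probabilities beyond tolerance in evolve")
    return out


def bound_ratio(rates: KineticRates, tau: float) -> float:
    """Steady-state P_III/P_I = (r_on/r_off_double) / (1 + tau*r_off).

    ``tau`` is the mean capture time (``r_capture = 1/tau``; ``tau = 0``
    means instantaneous capture).
    """
    if rates.r_off_double == 0:
        raise ValidationError("r_off_double = 0: doubly-bound ratio diverges")
    if tau < 0:
        raise ValidationError(f"tau must be >= 0, got {tau}")
    return rates.r_on / rates.r_off_double / (1.0 + tau * rates.r_off)


def enhancement(Kd: float, r_on: float, tau: float) -> float:
    """Avidity enhancement factor R = (1 + Kd)/(1 + r_on*tau*Kd).

    Ratio of the tethered dimer's doubly-bound occupancy to that of an
    untethered dimer pair (whose second binding proceeds at ``r_on`` rather
    than ``1/tau``).  ``R`` decreases from ``1 + Kd`` at instantaneous
    capture (tau = 0) to 1 at ``r_on*tau = 1``, below which the tether no
    longer helps.
    """
    if Kd <= 0 or r_on <= 0 or tau < 0:
        raise ValidationError("need Kd > 0, r_on > 0, tau >= 0")
    return (1.0 + Kd) / (1.0 + r_on * tau * Kd)


def effective_concentration(c0: float, R: float) -> float:
    """Untethered-equivalent concentration R*c0 of a tethered-dimer dose c0."""
    if c0 < 0 or R < 0:
        raise ValidationError("need c0 >= 0 and R >= 0")
    return R * c0
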