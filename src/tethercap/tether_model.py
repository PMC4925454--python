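"""Physical parameters of the tethered-ligand problem and derived scales.

The tether is a Gaussian coil of ``N`` statistical (Kuhn) segments of length
``b``.  Its entropic elasticity acts on the free ligand head as a Hookean
spring of constant ``kappa = 3*T/(b**2*N)`` (temperature ``T`` in energy
units, Boltzmann constant set to 1).  The receptor site of the already-bound
head is an absorbing sphere of radius ``a``; the tether's maximal extension
``R* = N*b`` is a reflecting outer sphere.  The natural length scale is
``r0 = sqrt(T/kappa) = b*sqrt(N/3)`` — the extension at which the spring
energy equals the thermal energy — and the natural time scale is
``tau0 = a**2/D``, the time to diffuse across the capture radius.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

from .exceptions import DegenerateGeometryError, ValidationError

__all__ = ["TetherModel", "ScaledGeometry", "spring_constant", "scaled_geometry"]


@dataclass(frozen=True)
class TetherModel:
    """Physical parameters of one tethered-ligand configuration.

    Parameters
    ----------
    N : float
        Polymerization index (number of Kuhn segments), ``N >= 1``.  Real
        values are accepted so that scaling studies can use log-spaced grids.
    b : float
        Kuhn length of the tether.
    a : float
        Capture (receptor) radius.  The default unit system sets ``a = b``.
    D : float
        Diffusion constant of the free ligand head.
    T_temp : float
        Temperature in energy units (``k_B = 1``).
    c_inf : float, optional
        Ambient number density of competing free ligands; only needed for
        the competitive-binding cutoff :func:`~tethercap.capture_time.tau_cutoff`.
    """

    N: float
    b: float = 1.0
    a: float = 1.0
    D: float = 1.0
    T_temp: float = 1.0
    c_inf: float | None = None

    def __post_init__(self) -> None:
        checks = [
            ("N", self.N >= 1.0),
            ("b", self.b > 0),
            ("a", self.a > 0),
            ("D", self.D > 0),
            ("T_temp", self.T_temp > 0),
        ]
        for name, ok in checks:
            value = getattr(self, name)
            if not (ok and math.isfinite(value)):
                raise ValidationError(f"invalid field {name}={value!r}")
        if self.c_inf is not None and not (self.c_inf >= 0 and math.isfinite(self.c_inf)):
            raise ValidationError(f"invalid field c_inf={self.c_inf!r}")

    # -- derived scales ----------------------------------------------------
    @property
    def kappa(self) -> float:
        """Entropic spring constant 3*T/(b^2*N) (energy/length^2)."""
        return 3.0 * self.T_temp / (self.b**2 * self.N)

    @property
    def mu(self) -> float:
        """Mobility D/T (Einstein relation)."""
        return self.D / self.T_temp

    @property
    def r0(self) -> float:
        """Thermal spring length sqrt(T/kappa) = b*sqrt(N/3)."""
        return self.b * math.sqrt(self.N / 3.0)

    @property
    def tau0(self) -> float:
        """Capture-radius diffusion time a^2/D."""
        return self.a**2 / self.D

    @property
    def R_rms(self) -> float:
        """Root-mean-square end-to-end distance b*sqrt(N) (injection radius)."""
        return self.b * math.sqrt(self.N)

    @property
    def R_star(self) -> float:
        """Maximal tether extension N*b (reflecting outer radius)."""
        return self.N * self.b

    def replace(self, **kwargs) -> "TetherModel":
        """Return a copy with some fields replaced."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return TetherModel(**current)

    # -- config I/O --------------------------------------------------------
    @classmethod
    def from_config(cls, path: str | Path) -> "TetherModel":
        """Build a model from a flat JSON config with keys N, b, a, D, T_temp, c_inf."""
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class ScaledGeometry:
    """Dimensionless radii of the capture problem, in units of r0.

    ``a_bar`` is the capture radius, ``R_bar`` the injection radius (set to
    the rms end-to-end distance, so ``R_bar = sqrt(3)`` always) and
    ``Rstar_bar`` the reflecting outer radius, with
    ``0 < a_bar <= R_bar <= Rstar_bar``.
    """

    a_bar: float
    R_bar: float
    Rstar_bar: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a_bar <= self.R_bar <= self.Rstar_bar):
            raise DegenerateGeometryError(
                f"need 0 < a_bar <= R_bar <= Rstar_bar, got "
                f"({self.a_bar}, {self.R_bar}, {self.Rstar_bar})"
            )

    @property
    def is_degenerate(self) -> bool:
        """True when the injection shell sits on the capture sphere (zero capture time)."""
        return self.a_bar == self.R_bar


def spring_constant(model: TetherModel) -> float:
    """Entropic spring constant kappa(N) = 3*T/(b^2*N) of the Gaussian tether."""
    return model.kappa


def scaled_geometry(model: TetherModel) -> ScaledGeometry:
    """Dimensionless (a_bar, R_bar, Rstar_bar) = (a, R_rms, R_star)/r0.

    With ``a = b`` this is ``(sqrt(3/N), sqrt(3), sqrt(3*N))``.

    Raises
    ------
    DegenerateGeometryError
        If the capture sphere reaches or exceeds the maximal tether
        extension (``a >= R_star``), or the injection radius lies inside
        the capture sphere.
    """
    r0 = model.r0
    # a == R_star (N=1 at a=b) is the zero-width shell: representable, and
    # mapped to zero capture time downstream; only a beyond R* is rejected.
    if model.a > model.R_star:
        raise DegenerateGeometryError(
            f"capture radius a={model.a} must lie inside the maximal extension "
            f"R*={model.R_star}"
        )
    if model.a > model.R_rms:
        raise DegenerateGeometryError(
            f"injection radius R_rms={model.R_rms} lies inside the capture "
            f"sphere a={model.a}"
        )
    return ScaledGeometry(
        a_bar=model.a / r0,
        R_bar=model.R_rms / r0,
        Rstar_bar=model.R_star / r0,
    )
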