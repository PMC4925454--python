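"""Tether-length dose-response curve and its least-squares fit.

The metabolic-activity enhancement of cells exposed to tethered ligand
dimers, as a function of the polymerization index N of the tether, is
modelled by the two-parameter rational form

    dM(N) = (beta - gamma*N**1.5) / (1 + gamma*N**1.5)

which follows from the avidity enhancement factor R of the three-state
kinetic model (dM proportional to R - 1) combined with the long-tether
power law tau(N) ~ N**1.5 of the capture time.  ``beta`` sets the
zero-length amplitude in percent activity units, ``gamma`` (>= 0) the
N**1.5 scale of the decline.  Reference parameters beta = 78.5,
gamma = 0.00063 describe tethers spanning N = 1-454.

Because the underlying activity measurements are not published as numbers,
:func:`synth_dataset` generates synthetic datasets on the reference curve
with Gaussian noise; fitting is exposed statsmodels-style as
``DoseResponseModel(dataset).fit() -> DoseResponseResults``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import FitError, ValidationError
from .kinetics import enhancement

__all__ = [
    "DoseResponseParams", "MetabolicDataset", "DoseResponseModel",
    "DoseResponseResults", "DoseResponseFit", "dm_theory", "fit",
    "synth_dataset", "dm_from_kinetics",
]

#: Reference curve parameters for the N = 1-454 tether series.
DEFAULT_BETA = 78.5
DEFAULT_GAMMA = 0.00063


@dataclass(frozen=True)
class DoseResponseParams:
    """Parameters (beta, gamma) of the rational dose-response form."""

    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValidationError(f"beta must be finite, got {self.beta}")
        if not (self.gamma >= 0 and math.isfinite(self.gamma)):
            raise ValidationError(f"gamma must be >= 0, got {self.gamma}")


def dm_theory(N, params: DoseResponseParams):
    """Percent activity enhancement dM(N) = (beta - gamma*N^1.5)/(1 + gamma*N^1.5).

    Strictly decreasing in N for gamma > 0 (and beta > -1), from beta at
    N = 0 towards the floor -1 as N -> infinity.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValidationError("N must be >= 0")
    g = params.gamma * N**1.5
    out = (params.beta - g) / (1.0 + g)
    return out if out.ndim else float(out)


def dm_from_kinetics(alpha: float, Kd: float, r_on: float, tau: float) -> float:
    """Activity enhancement alpha*(R - 1) from the kinetic enhancement factor.

    The mechanistic bridge between the three-state model and the fitted
    rational form: with tau = c*N^1.5 and alpha = 1 this reproduces
    dm_theory at beta = alpha*Kd, gamma = Kd*r_on*c.
    """
    if alpha < 0:
        raise ValidationError(f"alpha must be >= 0, got {alpha}")
    return alpha * (enhancement(Kd, r_on, tau) - 1.0)


class MetabolicDataset:
    """Records of (N, dM[, sigma]): tether length versus percent activity.

    Thin wrapper over a pandas DataFrame with columns ``N``, ``dM`` and
    optionally ``sigma`` (per-point noise scale for weighted fitting).
    """

    def __init__(self, N, dM, sigma=None):
        N = np.atleast_1d(np.asarray(N, dtype=float))
        dM = np.atleast_1d(np.asarray(dM, dtype=float))
        if N.size == 0:
            raise ValidationError("dataset is empty")
        if N.shape != dM.shape:
            raise ValidationError("N and dM must have the same length")
        if np.any(N < 1):
            raise ValidationError("all N must be >= 1")
        if sigma is not None:
            sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
            if sigma.shape != N.shape or np.any(sigma <= 0):
                raise ValidationError("sigma must match N and be positive")
        self.N = N
        self.dM = dM
        self.sigma = sigma

    def __len__(self) -> int:
        return self.N.size

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"N": self.N, "dM": self.dM})
        if self.sigma is not None:
            df["sigma"] = self.sigma
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MetabolicDataset":
        missing = {"N", "dM"} - set(df.columns)
        if missing:
            raise ValidationError(f"dataset missing columns: {sorted(missing)}")
        sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
        return cls(df["N"].to_numpy(), df["dM"].to_numpy(), sigma)

    @classmethod
    def from_csv(cls, path) -> "MetabolicDataset":
        try:
            df = pd.read_csv(path)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ValidationError(f"malformed CSV {path}: {exc}") from exc
        try:
            return cls.from_dataframe(df.apply(pd.to_numeric))
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def synth_dataset(
    params: DoseResponseParams,
    N_values: Sequence[float],
    noise_sd: float,
    seed: int,
) -> MetabolicDataset:
    """Synthetic activity dataset on the dose-response curve.

    ``dM_i = dm_theory(N_i) + eps_i`` with independent Gaussian noise of
    standard deviation ``noise_sd`` (percent activity units); deterministic
    given ``seed``.  Stands in for unpublished activity measurements over
    the tether series N = 1-454.
    """
    N_values = np.atleast_1d(np.asarray(N_values, dtype=float))
    if N_values.size == 0:
        raise ValidationError("N_values is empty")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    dM = dm_theory(N_values, params) + rng.normal(0.0, noise_sd, N_values.size)
    sigma = np.full(N_values.size, noise_sd) if noise_sd > 0 else None
    return MetabolicDataset(N_values, dM, sigma)


@dataclass(frozen=True)
class DoseResponseResults:
    """Converged least-squares fit of the dose-response curve."""

    params: DoseResponseParams
    residual_sum_sq: float
    covariance: np.ndarray
    n_points: int

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (beta, gamma) from the Jacobian covariance."""
        return np.sqrt(np.diag(self.covariance))

    def predict(self, N):
        return dm_theory(N, self.params)

    def summary(self) -> str:
        se = self.bse
        buf = io.StringIO()
        buf.write("Dose-response fit: dM(N) = (beta - gamma*N^1.5)/(1 + gamma*N^1.5)\n")
        buf.write("=" * 66 + "\n")
        buf.write(f"{'param':>8} {'estimate':>14} {'std err':>12}\n")
        buf.write(f"{'beta':>8} {self.params.beta:>14.6g} {se[0]:>12.3g}\n")
        buf.write(f"{'gamma':>8} {self.params.gamma:>14.6g} {se[1]:>12.3g}\n")
        buf.write("-" * 66 + "\n")
        buf.write(f"n points: {self.n_points}    RSS: {self.residual_sum_sq:.6g}\n")
        return buf.getvalue()


#: Back-compat alias: the fit result container.
DoseResponseFit = DoseResponseResults


class DoseResponseModel:
    """Least-squares model for the rational dose-response curve.

    Parameters
    ----------
    dataset : MetabolicDataset
        Observed (N, dM) records; per-point ``sigma`` enables weighted fits.
    exclude_n : sequence of float, optional
        N values to drop before fitting (the reference analysis drops the
        shortest tether, N = 1, where the Gaussian-coil picture fails).
    """

    def __init__(self, dataset: MetabolicDataset, exclude_n: Sequence[float] | None = None):
        if exclude_n:
            keep = ~np.isin(dataset.N, np.asarray(exclude_n, dtype=float))
            if not keep.any():
                raise ValidationError("exclusion list removes every record")
            dataset = MetabolicDataset(
                dataset.N[keep], dataset.dM[keep],
                None if dataset.sigma is None else dataset.sigma[keep],
            )
        if len(dataset) < 3:
            raise ValidationError("at least 3 records required for fitting")
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exclude_n=None) -> "DoseResponseModel":
        return cls(MetabolicDataset.from_dataframe(df), exclude_n=exclude_n)

    def _default_init(self) -> DoseResponseParams:
        # beta0 = max(dM); gamma0 = 1/median(N)^1.5 — safe basin for the
        # monotone rational form
        return DoseResponseParams(
            beta=float(np.max(self.dataset.dM)),
            gamma=float(np.median(self.dataset.N)) ** -1.5,
        )

    def fit(self, init: DoseResponseParams | None = None) -> DoseResponseResults:
        """Minimize sum((dM_i - dm(N_i; beta, gamma))^2), with gamma >= 0."""
        ds = self.dataset
        if np.unique(ds.N).size < 2:
            raise FitError("non-identifiable: dataset has a single distinct N")
        if init is None:
            init = self._default_init()
        model = lambda N, beta, gamma: dm_theory(N, DoseResponseParams(beta, gamma))
        try:
            popt, pcov = curve_fit(
                model, ds.N, ds.dM,
                p0=[init.beta, max(init.gamma, 1e-12)],
                sigma=ds.sigma, absolute_sigma=ds.sigma is not None,
                bounds=([-np.inf, 0.0], [np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise FitError(f"least-squares fit did not converge: {exc}") from exc
        if not np.all(np.isfinite(pcov)):
            raise FitError("degenerate covariance: parameters not identifiable")
        params = DoseResponseParams(beta=float(popt[0]), gamma=float(popt[1]))
        rss = float(np.sum((ds.dM - dm_theory(ds.N, params)) ** 2))
        return DoseResponseResults(
            params=params, residual_sum_sq=rss, covariance=pcov, n_points=len(ds)
        )


def fit(
    dataset: MetabolicDataset,
    init: DoseResponseParams | None = None,
    exclude_n: Sequence[float] | None = None,
) -> DoseResponseResults:
    """Functional wrapper: fit the dose-response curve to a dataset."""
    return DoseResponseModel(dataset, exclude_n=exclude_n).fit(init=init)
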