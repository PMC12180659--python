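"""Mean-field (deterministic) dynamics of gut occupancy.

A worm gut is modelled as ``V`` sites of which ``N`` are occupied by
bacteria.  Colonisation from the environment (rate ``c``), within-host
birth into empty sites (rate ``b``) and loss (rate ``d``) give, for the
mean occupancy density ``phi = <N/V>``, the logistic-type ODE

    dphi/dt = (1 - phi) * (b * phi + c) - d * phi.

With no migration (``c = 0``) and ``b > d`` the stable steady state is
``phi* = 1 - d/b``, i.e. an effective capacity ``N* = V (1 - d/b)``.

Rates are fitted to population snapshot data by least squares on
log10(mean load per time point) against log10 of the integrated model,
because fluctuations in these data are close to symmetric in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "LogisticRates",
    "DensityTrajectory",
    "meanfield_rhs",
    "solve_meanfield",
    "steady_state_load",
    "fit_meanfield",
    "MeanFieldModel",
    "DegenerateDataError",
]

#: default ODE solver tolerances (adaptive, stiff-capable)
RTOL = 1e-8
ATOL = 1e-10


class DegenerateDataError(ValueError):
    """Snapshot data carry no information for the requested fit."""


@dataclass(frozen=True)
class LogisticRates:
    """Per-isolate colonisation / birth / death rates and carrying capacity.

    Parameters
    ----------
    b : float
        Within-host birth rate (1/h).
    c : float
        Colonisation (migration) rate from the environment (1/h).
    d : float
        Death / loss rate (1/h).
    V : int
        Carrying capacity of the gut (cells, >= 1).
    """

    b: float
    c: float
    d: float
    V: int

    def __post_init__(self):
        if self.b < 0 or self.c < 0 or self.d < 0:
            raise ValueError("rates b, c, d must be nonnegative")
        if self.V < 1:
            raise ValueError("carrying capacity V must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, record: dict) -> "LogisticRates":
        return cls(b=record["b"], c=record["c"], d=record["d"], V=int(record["V"]))


@dataclass(frozen=True)
class DensityTrajectory:
    """Occupancy fraction ``phi(t)`` on a strictly increasing time grid."""

    times: np.ndarray
    phi: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "phi", phi)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("times must be a nonempty 1-D array")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if phi.shape != times.shape:
            raise ValueError("phi and times must have the same length")
        if np.any(phi < -1e-12) or np.any(phi > 1 + 1e-12):
            raise ValueError("phi must lie in [0, 1]")


def meanfield_rhs(phi: float, rates: LogisticRates) -> float:
    """Right-hand side of the mean-field occupancy ODE at density ``phi``.

    Returns ``(1 - phi) * (b*phi + c) - d*phi`` (units 1/h).
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValueError("phi must lie in [0, 1]")
    out = (1.0 - phi) * (rates.b * phi + rates.c) - rates.d * phi
    return float(out) if out.ndim == 0 else out


def solve_meanfield(rates: LogisticRates, phi0: float, times) -> DensityTrajectory:
    """Integrate the mean-field ODE from ``phi0`` over ``times`` (hours).

    Uses an adaptive stiff-capable solver (LSODA, rtol 1e-8 / atol 1e-10).
    The returned trajectory is clipped to [0, 1] only within solver
    tolerance; genuinely escaping trajectories raise.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not 0.0 <= phi0 <= 1.0:
        raise ValueError("phi0 must lie in [0, 1]")

    t0 = min(0.0, times[0])
    sol = solve_ivp(
        lambda t, y: [(1.0 - y[0]) * (rates.b * y[0] + rates.c) - rates.d * y[0]],
        (t0, times[-1]),
        [phi0],
        t_eval=times,
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"mean-field ODE integration failed: {sol.message}")
    phi = sol.y[0]
    if np.any(phi < -1e-6) or np.any(phi > 1 + 1e-6):
        raise RuntimeError("mean-field trajectory left [0, 1] beyond solver tolerance")
    return DensityTrajectory(times=times, phi=np.clip(phi, 0.0, 1.0))


def steady_state_load(rates: LogisticRates) -> float:
    """Migration-free effective steady-state load ``N* = V (1 - d/b)``.

    Valid in the ``c = 0`` regime with ``b > d``; raises otherwise because
    the only nonnegative steady state is extinction.
    """
    if rates.b <= rates.d:
        raise ValueError("steady_state_load requires b > d (migration-free regime)")
    return rates.V * (1.0 - rates.d / rates.b)


def _snapshot_time_means(snapshot: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Mean raw load per time point, sorted by time."""
    grouped = snapshot.groupby("time_h")["load"].mean().sort_index()
    return grouped.index.to_numpy(dtype=float), grouped.to_numpy(dtype=float)


def fit_meanfield(
    snapshot: pd.DataFrame,
    V_fixed: int | None = None,
    phi0: float = 0.0,
    x0: tuple[float, float, float] = (0.5, 0.01, 0.1),
):
    """Fit (b, c, d) to snapshot means by log-space least squares.

    Means are computed on raw loads per time point before logging; time
    points with zero mean load are excluded.  ``V`` is fixed to the maximum
    observed load unless supplied (``b`` and ``d`` partially compensate, so
    the net growth rate ``b - d`` is the robust quantity and is reported).

    Returns a fitted :class:`MeanFieldModel`.
    """
    model = MeanFieldModel(V=V_fixed, phi0=phi0, x0=x0)
    return model.fit(snapshot)


class MeanFieldModel(BaseEstimator):
    """Least-squares estimator for mean-field colonisation rates.

    Parameters
    ----------
    V : int, optional
        Carrying capacity.  Default: max observed load in the data.
    phi0 : float
        Initial occupancy density (germ-free worms start at 0).
    x0 : tuple
        Starting point ``(b, c, d)`` for the optimiser.

    Attributes
    ----------
    rates_ : LogisticRates
        Fitted rates.
    residual_ : float
        Residual norm of log10(mean load) vs log10(model load).
    net_growth_ : float
        ``b - d`` of the fit.
    n_points_ : int
        Number of time points entering the fit.
    """

    def __init__(self, V=None, phi0=0.0, x0=(0.5, 0.01, 0.1)):
        self.V = V
        self.phi0 = phi0
        self.x0 = x0

    def fit(self, X: pd.DataFrame, y=None):
        times, means = _snapshot_time_means(X)
        keep = means > 0
        times, means = times[keep], means[keep]
        if times.size == 0:
            raise DegenerateDataError("all time points have zero mean load")
        if times.size < 3:
            raise DegenerateDataError(
                f"need >= 3 time points with positive mean load, got {times.size}"
            )
        V = int(self.V) if self.V is not None else int(np.ceil(X["load"].max()))
        if V < 1:
            raise DegenerateDataError("carrying capacity resolved to < 1")
        log_target = np.log10(means)

        def residuals(theta):
            b, c, d = np.exp(theta)
            rates = LogisticRates(b=b, c=c, d=d, V=V)
            traj = solve_meanfield(rates, self.phi0, times)
            load = np.maximum(V * traj.phi, 1e-300)
            return np.log10(load) - log_target

        theta0 = np.log(np.asarray(self.x0, dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = least_squares(residuals, theta0, method="lm", max_nfev=2000)
        b, c, d = np.exp(result.x)
        self.rates_ = LogisticRates(b=float(b), c=float(c), d=float(d), V=V)
        self.residual_ = float(np.linalg.norm(result.fun))
        self.net_growth_ = float(b - d)
        self.n_points_ = int(times.size)
        return self

    def to_record(self) -> dict:
        """Flat JSON-ready record of the fit."""
        rec = self.rates_.to_dict()
        rec.update(
            residual=self.residual_,
            n_points=self.n_points_,
            net_growth=self.net_growth_,
        )
        return rec
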