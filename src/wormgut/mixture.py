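"""Two-component Gaussian mixture summaries of log-load distributions.

Snapshot distributions of log bacterial load are bimodal once alternative
colonisation states emerge.  A two-component GMM fitted in log-CFU space
summarises each time point; the weight of the high-mean component serves
as a proxy for the probability of the high-load state, and its time
series is the occupancy curve fitted by :mod:`wormgut.switching`.

The GMM is a summary statistic, not a partition of worms: no claim is
made that a component assigns individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from ._rng import as_rng

__all__ = ["GMM2", "OccupancyCurve", "fit_gmm2", "gmm_pdf", "weight_series", "LoadMixture"]

VARIANCE_FLOOR = 1e-4  # sigma^2 floor; prevents collapse onto duplicated values
DETECTION_FLOOR_LOG10 = 2.0  # log10 of the ~100-cells/worm detection threshold


@dataclass(frozen=True)
class GMM2:
    """Two-component mixture, components sorted so mu_L < mu_H."""

    w_L: float
    mu_L: float
    sigma_L: float
    w_H: float
    mu_H: float
    sigma_H: float
    log_likelihood: float = float("nan")
    degenerate: bool = False

    def __post_init__(self):
        if not np.isclose(self.w_L + self.w_H, 1.0, atol=1e-8):
            raise ValueError("weights must sum to 1")
        if self.w_L < 0 or self.w_H < 0:
            raise ValueError("weights must be nonnegative")
        if self.sigma_L <= 0 or self.sigma_H <= 0:
            raise ValueError("component sds must be positive")
        if self.mu_L > self.mu_H:
            raise ValueError("components must be ordered mu_L <= mu_H")

    def pdf(self, x):
        return gmm_pdf(self, x)

    def to_dict(self) -> dict:
        return {
            "w_L": self.w_L,
            "mu_L": self.mu_L,
            "sigma_L": self.sigma_L,
            "w_H": self.w_H,
            "mu_H": self.mu_H,
            "sigma_H": self.sigma_H,
        }


@dataclass(frozen=True)
class OccupancyCurve:
    """High-state occupancy fraction per time."""

    times: np.ndarray
    p_high: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        p = np.asarray(self.p_high, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "p_high", p)
        if times.shape != p.shape:
            raise ValueError("times and p_high must have the same shape")
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("p_high must lie in [0, 1]")


def fit_gmm2(
    values,
    seed=0,
    n_init: int = 10,
    variance_floor: float = VARIANCE_FLOOR,
) -> GMM2:
    """EM fit of a two-component Gaussian mixture to log-load values.

    Requires >= 4 finite values.  Multiple restarts (``n_init``), seeded
    and hence deterministic; components are returned sorted by mean.  A
    weight below 1e-3 or a variance at its floor triggers a degenerate-fit
    warning and flag.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("need >= 4 finite values to fit a 2-component mixture")
    rng = as_rng(seed)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        reg_covar=variance_floor,
        n_init=n_init,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    w = weights[order]
    mu = means[order]
    sd = sds[order]
    degenerate = bool(w.min() < 1e-3 or np.any(sd**2 <= 1.05 * variance_floor))
    if degenerate:
        warnings.warn(
            "degenerate 2-component mixture fit (vanishing weight or "
            "variance at floor)",
            RuntimeWarning,
            stacklevel=2,
        )
    return GMM2(
        w_L=float(w[0]),
        mu_L=float(mu[0]),
        sigma_L=float(sd[0]),
        w_H=float(w[1]),
        mu_H=float(mu[1]),
        sigma_H=float(sd[1]),
        log_likelihood=float(gm.score(x.reshape(-1, 1)) * x.size),
        degenerate=degenerate,
    )


def gmm_pdf(gmm: GMM2, x):
    """Mixture density ``w_L N(mu_L, s_L^2) + w_H N(mu_H, s_H^2)``."""
    x = np.asarray(x, dtype=float)
    out = gmm.w_L * norm.pdf(x, gmm.mu_L, gmm.sigma_L) + gmm.w_H * norm.pdf(
        x, gmm.mu_H, gmm.sigma_H
    )
    return float(out) if out.ndim == 0 else out


def weight_series(
    snapshot: pd.DataFrame,
    seed=0,
    zero_handling: str = "drop",
    n_init: int = 10,
) -> tuple[OccupancyCurve, pd.DataFrame]:
    """Per-time GMM fits; the high-mode weight series is the occupancy proxy.

    ``zero_handling``: ``"drop"`` excludes zero-load worms (log undefined);
    ``"floor"`` maps them to the detection-limit value log10(100) = 2.
    Returns the occupancy curve and the per-time parameter table
    (t, w_L, mu_L, sigma_L, w_H, mu_H, sigma_H).
    """
    if zero_handling not in ("drop", "floor"):
        raise ValueError("zero_handling must be 'drop' or 'floor'")
    times = np.sort(snapshot["time_h"].unique())
    if times.size < 2:
        raise ValueError("need >= 2 time points for a weight series")
    child_seeds = np.random.SeedSequence(seed).generate_state(times.size) >> np.uint32(1)
    rows = []
    p_high = []
    for t, s in zip(times, child_seeds):
        loads = snapshot.loc[snapshot["time_h"] == t, "load"].to_numpy(dtype=float)
        if zero_handling == "drop":
            loads = loads[loads > 0]
            logx = np.log10(loads)
        else:
            logx = np.where(loads > 0, np.log10(np.maximum(loads, 1e-300)), np.nan)
            logx = np.where(loads > 0, logx, DETECTION_FLOOR_LOG10)
            logx = np.maximum(logx, DETECTION_FLOOR_LOG10)
        gmm = fit_gmm2(logx, seed=int(s), n_init=n_init)
        p_high.append(gmm.w_H)
        rows.append({"time_h": float(t), **gmm.to_dict(), "degenerate": gmm.degenerate})
    table = pd.DataFrame(rows)
    return OccupancyCurve(times=times.astype(float), p_high=np.asarray(p_high)), table


class LoadMixture(BaseEstimator):
    """Estimator wrapper around :func:`fit_gmm2`.

    Attributes after ``fit``: ``weights_``, ``means_``, ``sds_`` (low
    component first), ``mixture_`` (the :class:`GMM2`), ``degenerate_``.
    """

    def __init__(self, n_init=10, variance_floor=VARIANCE_FLOOR, random_state=0):
        self.n_init = n_init
        self.variance_floor = variance_floor
        self.random_state = random_state

    def fit(self, X, y=None):
        gmm = fit_gmm2(
            np.asarray(X).ravel(),
            seed=self.random_state,
            n_init=self.n_init,
            variance_floor=self.variance_floor,
        )
        self.mixture_ = gmm
        self.weights_ = np.array([gmm.w_L, gmm.w_H])
        self.means_ = np.array([gmm.mu_L, gmm.mu_H])
        self.sds_ = np.array([gmm.sigma_L, gmm.sigma_H])
        self.degenerate_ = gmm.degenerate
        return self

    def pdf(self, x):
        return gmm_pdf(self.mixture_, x)
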