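"""Explicit two-state (telegraph) model of alternating colonisation states.

Each worm-bacteria system occupies a discrete state s in {low, high} and
switches randomly with rates alpha_H (low -> high) and alpha_L
(high -> low).  Within a state, log10 load ``phi`` relaxes logistically
toward a state-specific capacity with state-specific noise:

    dphi/dt = r_s * phi * (C_s - phi) + eta_s,
    <eta_s> = 0,  <eta_s(t) eta_s(t')> = 2 D_s delta(t - t').

The master equation for the state probabilities gives the occupancy
relaxation

    P(s_H, t) = A exp(-(a_H + a_L) t) + a_H / (a_H + a_L),

with A fixed by the initial occupancy; this closed form is what the rate
fit inverts.  When switching is fast relative to within-state relaxation,
the stationary load density is the rate-weighted mixture of the per-state
Boltzmann densities exp(-U_s/D_s) with U_s(phi) = -r_s phi^2 (C_s/2 - phi/3).

Noise convention: the Euler-Maruyama increment uses sqrt(2 D dt), the
unique choice consistent with the Boltzmann forms above.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from ._rng import as_rng
from .mixture import OccupancyCurve

__all__ = [
    "SwitchingModel",
    "occupancy_solution",
    "fit_switching_rates",
    "OccupancyRelaxation",
    "simulate_switching",
    "simulate_two_state_chains",
    "switching_stationary_pdf",
]

STATE_LOW, STATE_HIGH = 0, 1


@dataclass(frozen=True)
class SwitchingModel:
    """Per-state logistic parameters plus the two transition rates.

    Units: growth rates ``r_s`` in 1/h per log-load unit, capacities
    ``C_s`` in log10-load units, noise variances ``D_s`` in log-load^2/h,
    transition rates in 1/h.
    """

    r_low: float
    C_low: float
    D_low: float
    r_high: float
    C_high: float
    D_high: float
    alpha_h: float
    alpha_l: float

    def __post_init__(self):
        if min(self.r_low, self.r_high, self.alpha_h, self.alpha_l) < 0:
            raise ValueError("rates must be nonnegative")
        if self.D_low <= 0 or self.D_high <= 0:
            raise ValueError("noise variances must be positive")
        if not self.C_low < self.C_high:
            raise ValueError("C_low must be below C_high")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, record: dict) -> "SwitchingModel":
        return cls(**{k: record[k] for k in cls.__dataclass_fields__})


def occupancy_solution(alpha_h, alpha_l, p0, times) -> OccupancyCurve:
    """Closed-form relaxation of the high-state probability.

    ``P(s_H, t) = (p0 - p*) exp(-(a_H + a_L) t) + p*`` with
    ``p* = a_H / (a_H + a_L)``.
    """
    if alpha_h + alpha_l <= 0:
        raise ValueError("alpha_h + alpha_l must be positive")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    times = np.asarray(times, dtype=float)
    p_star = alpha_h / (alpha_h + alpha_l)
    p = (p0 - p_star) * np.exp(-(alpha_h + alpha_l) * times) + p_star
    return OccupancyCurve(times=times, p_high=np.clip(p, 0.0, 1.0))


class OccupancyRelaxation(BaseEstimator):
    """Least-squares estimator of (alpha_h, alpha_l) from an occupancy curve.

    ``p0`` is free by default (the data may include the transient from a
    low initial occupancy); pass ``p0`` to pin it.  A flat curve leaves
    only the ratio alpha_h/alpha_l identifiable, flagged via
    ``identifiable_``.

    Attributes: ``alpha_h_``, ``alpha_l_``, ``p0_``, ``residual_``,
    ``identifiable_``.
    """

    def __init__(self, p0=None):
        self.p0 = p0

    def fit(self, X, y=None):
        if isinstance(X, OccupancyCurve):
            times, p = X.times, X.p_high
        else:
            times = np.asarray(X, dtype=float).ravel()
            p = np.asarray(y, dtype=float).ravel()
        if times.size < 3:
            raise ValueError("need >= 3 time points to fit transition rates")

        free_p0 = self.p0 is None

        def model(theta):
            ah, al = theta[0], theta[1]
            q0 = theta[2] if free_p0 else self.p0
            s = ah + al
            p_star = ah / s if s > 0 else 0.0
            return (q0 - p_star) * np.exp(-s * times) + p_star

        def residuals(theta):
            return model(theta) - p

        p_end = float(np.clip(p[-1], 1e-3, 1 - 1e-3))
        s0 = max(1.0 / max(times.max(), 1e-6), 1e-3)
        x0 = [p_end * s0, (1 - p_end) * s0]
        lb, ub = [0.0, 0.0], [np.inf, np.inf]
        if free_p0:
            x0.append(float(np.clip(p[0], 0.0, 1.0)))
            lb.append(0.0)
            ub.append(1.0)
        result = least_squares(residuals, x0, bounds=(lb, ub), max_nfev=5000)
        if not result.success:
            raise RuntimeError(f"occupancy-relaxation fit failed: {result.message}")
        self.alpha_h_ = float(result.x[0])
        self.alpha_l_ = float(result.x[1])
        self.p0_ = float(result.x[2]) if free_p0 else float(self.p0)
        self.residual_ = float(np.linalg.norm(result.fun))
        # a flat curve carries no information on the relaxation time scale:
        # only the ratio alpha_h/alpha_l (through p*) is identifiable
        self.identifiable_ = bool(np.ptp(p) > 10 * (self.residual_ / np.sqrt(p.size) + 1e-12))
        return self


def fit_switching_rates(curve: OccupancyCurve, p0=None) -> OccupancyRelaxation:
    """Fit the occupancy relaxation; returns the fitted estimator."""
    return OccupancyRelaxation(p0=p0).fit(curve)


def simulate_switching(
    model: SwitchingModel,
    phi0: float,
    s0: int,
    t_end: float,
    dt: float = 0.01,
    seed=0,
    exact_switching: bool = False,
):
    """Euler-Maruyama trajectory of (log-load, state).

    Per step the state flips with probability ``alpha * dt`` (per-step
    Bernoulli; ``exact_switching=True`` draws exponential waiting times
    instead) and the load updates as
    ``dphi = r_s phi (C_s - phi) dt + sqrt(2 D_s dt) xi``.

    Returns ``(times, phi, state)`` arrays.  Raises if
    ``max(alpha) * dt > 0.1`` (discretisation too coarse).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if max(model.alpha_h, model.alpha_l) * dt > 0.1:
        raise ValueError("dt too large: max(alpha_h, alpha_l) * dt must be <= 0.1")
    if s0 not in (STATE_LOW, STATE_HIGH):
        raise ValueError("s0 must be 0 (low) or 1 (high)")
    rng = as_rng(seed)
    n_steps = int(np.ceil(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    phi = np.empty(n_steps + 1)
    state = np.empty(n_steps + 1, dtype=np.int8)
    phi[0] = phi0
    state[0] = s0

    r = (model.r_low, model.r_high)
    C = (model.C_low, model.C_high)
    amp = (np.sqrt(2.0 * model.D_low * dt), np.sqrt(2.0 * model.D_high * dt))
    flip_p = (model.alpha_h * dt, model.alpha_l * dt)  # indexed by current state

    xi = rng.standard_normal(n_steps)
    if exact_switching:
        next_switch = rng.exponential(1.0 / (model.alpha_h, model.alpha_l)[s0]) if (
            (model.alpha_h, model.alpha_l)[s0] > 0
        ) else np.inf
    else:
        u = rng.random(n_steps)

    s = int(s0)
    x = float(phi0)
    for k in range(n_steps):
        if exact_switching:
            if times[k + 1] >= next_switch:
                s = 1 - s
                rate = (model.alpha_h, model.alpha_l)[s]
                next_switch += rng.exponential(1.0 / rate) if rate > 0 else np.inf
        else:
            if u[k] < flip_p[s]:
                s = 1 - s
        x = x + r[s] * x * (C[s] - x) * dt + amp[s] * xi[k]
        phi[k + 1] = x
        state[k + 1] = s
    return times, phi, state


def simulate_two_state_chains(
    alpha_h: float,
    alpha_l: float,
    n_chains: int,
    times,
    seed=0,
    s0: int = STATE_LOW,
) -> np.ndarray:
    """Exact simulation of independent telegraph chains at snapshot times.

    Between consecutive observation times the two-state Markov chain is
    propagated with its exact transition probabilities, so no time
    discretisation error enters.  Returns the (n_chains, n_times) state
    matrix (0 = low, 1 = high).
    """
    rng = as_rng(seed)
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) < 0):
        raise ValueError("times must be nonempty and nondecreasing")
    s = alpha_h + alpha_l
    if s <= 0:
        raise ValueError("alpha_h + alpha_l must be positive")
    p_star = alpha_h / s
    states = np.empty((n_chains, times.size), dtype=np.int8)
    current = np.full(n_chains, s0, dtype=np.int8)
    t_prev = 0.0
    for j, t in enumerate(times):
        delta = t - t_prev
        if delta > 0:
            decay = np.exp(-s * delta)
            # P(high at t+delta | state now)
            p_from_low = p_star * (1.0 - decay)
            p_from_high = p_star + (1.0 - p_star) * decay
            p_high = np.where(current == STATE_HIGH, p_from_high, p_from_low)
            current = (rng.random(n_chains) < p_high).astype(np.int8)
        t_prev = t
        states[:, j] = current
    return states


def switching_stationary_pdf(model: SwitchingModel, support=None, n_grid: int = 2001):
    """Fast-switching stationary load density (mixture of Boltzmann factors).

    Each state alone has stationary density ``A_s exp(r_s phi^2 (C_s/2 -
    phi/3) / D_s)``; they are mixed with the stationary state weights
    alpha_h/(alpha_h+alpha_l) (high) and alpha_l/(alpha_h+alpha_l) (low),
    and normalised numerically on ``support`` (default
    ``[0, C_high + 4 sqrt(D_high / r_high)]``).

    Valid only when switching is fast compared with within-state
    relaxation.  Returns ``(grid, pdf)``.
    """
    if support is None:
        support = (0.0, model.C_high + 4.0 * np.sqrt(model.D_high / model.r_high))
    grid = np.linspace(support[0], support[1], n_grid)

    def boltzmann(r, C, D):
        logw = r * grid**2 * (C / 2.0 - grid / 3.0) / D
        w = np.exp(logw - logw.max())
        return w / np.trapezoid(w, grid)

    p_star = model.alpha_h / (model.alpha_h + model.alpha_l)
    pdf = p_star * boltzmann(model.r_high, model.C_high, model.D_high) + (
        1.0 - p_star
    ) * boltzmann(model.r_low, model.C_low, model.D_low)
    pdf = pdf / np.trapezoid(pdf, grid)
    return grid, pdf
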