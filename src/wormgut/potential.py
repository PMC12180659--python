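"""Multiwell-potential model of log bacterial load.

Overdamped Langevin dynamics on a scalar landscape U:

    dphi/dt = f(phi) + eta = -U'(phi) + eta,
    <eta> = 0,  <eta(t) eta(t')> = 2 D delta(t - t'),

whose stationary density is the Boltzmann form ``P(phi) = A exp(-U/D)``.
Two troughs of U are the alternative colonisation states; barrier
crossings follow the Kramers (Arrhenius-like) rates

    alpha_L = sqrt(K_H K_M) / (2 pi) * exp(-(U(C_M) - U(C_H)) / D),
    alpha_H = sqrt(K_L K_M) / (2 pi) * exp(-(U(C_M) - U(C_L)) / D),

with K = |U''| at the respective fixed points.  From snapshot data the
landscape is only identified up to the noise scale: the histogram gives
the effective potential ``R(phi) = -ln P(phi) = U(phi)/D``; combining a
fitted R with an independently measured high-to-low rate inverts the
Kramers formula for D:

    D = 2 pi alpha_L exp(R(C_M) - R(C_H)) / sqrt(R''(C_H) R''(C_M)),

after which U = D * R in absolute units.  Capturing both the mode
positions and their widths generally needs a 6th-order polynomial U
(5th-order force); a quartic can match the means only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from sklearn.base import BaseEstimator

from ._rng import as_rng

__all__ = [
    "PolyPotential",
    "FixedPoints",
    "EffectivePotential",
    "NotBistableError",
    "empirical_effective_potential",
    "fit_polynomial_potential",
    "find_fixed_points",
    "kramers_rates",
    "estimate_noise_D",
    "potential_stationary_pdf",
    "simulate_potential",
    "first_passage_rate",
    "PotentialLandscape",
]


class NotBistableError(ValueError):
    """The potential does not have exactly two minima on the support."""


@dataclass(frozen=True)
class PolyPotential:
    """Polynomial potential U(phi) with noise variance D.

    ``coefficients`` are ascending powers.  For R-scale potentials
    (U/D, fitted straight from a histogram) use ``D = 1``.
    """

    coefficients: tuple
    D: float = 1.0

    def __post_init__(self):
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        if self.D <= 0:
            raise ValueError("noise variance D must be positive")

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    @property
    def poly(self) -> Polynomial:
        return Polynomial(self.coefficients)

    def U(self, phi):
        out = self.poly(np.asarray(phi, dtype=float))
        return float(out) if np.ndim(out) == 0 else out

    def dU(self, phi):
        out = self.poly.deriv()(np.asarray(phi, dtype=float))
        return float(out) if np.ndim(out) == 0 else out

    def d2U(self, phi):
        out = self.poly.deriv(2)(np.asarray(phi, dtype=float))
        return float(out) if np.ndim(out) == 0 else out

    def force(self, phi):
        """f(phi) = -U'(phi)."""
        return -self.dU(phi)

    def with_D(self, D: float) -> "PolyPotential":
        return PolyPotential(coefficients=self.coefficients, D=D)

    def scaled(self, factor: float) -> "PolyPotential":
        """Multiply U by a scalar (e.g. convert R-scale to U = D * R)."""
        return PolyPotential(
            coefficients=tuple(factor * c for c in self.coefficients), D=self.D
        )

    def to_dict(self) -> dict:
        return {"order": self.order, "coefficients": list(self.coefficients), "D": self.D}


@dataclass(frozen=True)
class FixedPoints:
    """Stable states C_L < C_M < C_H with curvatures |U''| at each."""

    C_L: float
    C_M: float
    C_H: float
    K_L: float
    K_M: float
    K_H: float

    def __post_init__(self):
        if not self.C_L < self.C_M < self.C_H:
            raise ValueError("fixed points must be ordered C_L < C_M < C_H")
        if min(self.K_L, self.K_M, self.K_H) <= 0:
            raise ValueError("curvatures must be positive for a generic bistable well")


@dataclass(frozen=True)
class EffectivePotential:
    """R(phi) = -ln P(phi) on nonempty histogram bins."""

    phi: np.ndarray
    R: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if not (self.phi.shape == self.R.shape == self.counts.shape):
            raise ValueError("phi, R and counts must share a shape")
        if np.any(~np.isfinite(self.R)):
            raise ValueError("R must be finite on the retained bins")


def empirical_effective_potential(values, n_bins: int = 40) -> EffectivePotential:
    """Histogram-based effective potential ``R = -ln(density)``.

    Requires >= 50 values.  Empty bins are excluded, not imputed.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError("need >= 50 values for an effective potential")
    density, edges = np.histogram(x, bins=n_bins, density=True)
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return EffectivePotential(
        phi=centers[keep], R=-np.log(density[keep]), counts=counts[keep]
    )


def fit_polynomial_potential(eff: EffectivePotential, order: int) -> PolyPotential:
    """Count-weighted least-squares polynomial fit to R (returns R-scale U/D).

    ``order`` must be even and >= 4.  Weights are per-bin counts so that
    sparsely populated tails do not dominate.  A non-confining fit
    (leading coefficient <= 0) warns.
    """
    if order < 4 or order % 2:
        raise ValueError("polynomial order must be even and >= 4")
    # numpy's w multiplies residuals, so sqrt(counts) gives count weights
    fitted = Polynomial.fit(eff.phi, eff.R, deg=order, w=np.sqrt(eff.counts))
    coeffs = fitted.convert().coef
    if coeffs[-1] <= 0:
        warnings.warn(
            "leading coefficient <= 0: fitted potential is not confining",
            RuntimeWarning,
            stacklevel=2,
        )
    return PolyPotential(coefficients=tuple(coeffs), D=1.0)


def default_support(values_or_eff) -> tuple[float, float]:
    """Working support: data range padded by one log-load unit each side."""
    if isinstance(values_or_eff, EffectivePotential):
        x = values_or_eff.phi
    else:
        x = np.asarray(values_or_eff, dtype=float)
    return float(np.min(x) - 1.0), float(np.max(x) + 1.0)


def find_fixed_points(pot: PolyPotential, support: tuple[float, float]) -> FixedPoints:
    """Minima / barrier of U by real root-finding on U' within ``support``.

    Raises :class:`NotBistableError` unless exactly two minima bracket one
    interior maximum.
    """
    roots = pot.poly.deriv().roots()
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    real = real[(real >= support[0]) & (real <= support[1])]
    curv = pot.d2U(real)
    minima = real[curv > 0]
    maxima = real[curv < 0]
    if minima.size != 2:
        raise NotBistableError(
            f"expected exactly 2 minima on support, found {minima.size}"
        )
    c_l, c_h = minima
    interior = maxima[(maxima > c_l) & (maxima < c_h)]
    if interior.size != 1:
        raise NotBistableError("expected exactly one barrier between the minima")
    c_m = float(interior[0])
    return FixedPoints(
        C_L=float(c_l),
        C_M=c_m,
        C_H=float(c_h),
        K_L=float(abs(pot.d2U(c_l))),
        K_M=float(abs(pot.d2U(c_m))),
        K_H=float(abs(pot.d2U(c_h))),
    )


def kramers_rates(pot: PolyPotential, fp: FixedPoints) -> tuple[float, float]:
    """Kramers escape rates ``(alpha_h, alpha_l)`` of the double well.

    ``alpha_h`` is the low-to-high rate (escape from the low well),
    ``alpha_l`` the high-to-low rate.  Asymptotically valid for barriers
    a few times D.
    """
    dU_h = pot.U(fp.C_M) - pot.U(fp.C_H)
    dU_l = pot.U(fp.C_M) - pot.U(fp.C_L)
    if dU_h <= 0 or dU_l <= 0:
        raise ValueError("barrier heights must be positive")
    alpha_l = np.sqrt(fp.K_H * fp.K_M) / (2.0 * np.pi) * np.exp(-dU_h / pot.D)
    alpha_h = np.sqrt(fp.K_L * fp.K_M) / (2.0 * np.pi) * np.exp(-dU_l / pot.D)
    return float(alpha_h), float(alpha_l)


def estimate_noise_D(R_pot: PolyPotential, fp: FixedPoints, alpha_l: float) -> float:
    """Noise variance from a fitted R-scale potential and a measured rate.

    Inverts the Kramers high-to-low rate under ``U = D * R``:
    ``D = 2 pi alpha_l exp(R(C_M) - R(C_H)) / sqrt(R''(C_H) R''(C_M))``.
    ``fp`` must be the fixed points of R (curvatures on the R scale).
    """
    if alpha_l <= 0:
        raise ValueError("alpha_l must be positive")
    barrier = R_pot.U(fp.C_M) - R_pot.U(fp.C_H)
    return float(
        2.0 * np.pi * alpha_l * np.exp(barrier) / np.sqrt(fp.K_H * fp.K_M)
    )


def potential_stationary_pdf(
    pot: PolyPotential, support: tuple[float, float], n_grid: int = 2001
):
    """Boltzmann stationary density ``A exp(-U/D)`` on ``support``.

    Returns ``(grid, pdf)``; normalised by quadrature.
    """
    grid = np.linspace(support[0], support[1], n_grid)
    logw = -pot.U(grid) / pot.D
    w = np.exp(logw - logw.max())
    return grid, w / np.trapezoid(w, grid)


def simulate_potential(
    pot: PolyPotential,
    phi0: float,
    t_end: float,
    dt: float = 0.01,
    seed=0,
    support: tuple[float, float] | None = None,
    n_paths: int = 1,
    record_every: int = 1,
):
    """Euler-Maruyama Langevin trajectories on the landscape.

    Per step ``dphi = -U'(phi) dt + sqrt(2 D dt) xi``.  Aborts with a
    blow-up diagnostic if any path leaves ``support`` by more than 10
    support widths.  Returns ``(times, phi)`` with phi of shape
    (n_recorded,) for one path, else (n_paths, n_recorded).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = as_rng(seed)
    n_steps = int(np.ceil(t_end / dt))
    if support is None:
        lo, hi = phi0 - 10.0, phi0 + 10.0
    else:
        lo, hi = support
    width = hi - lo
    guard_lo, guard_hi = lo - 10.0 * width, hi + 10.0 * width

    amp = np.sqrt(2.0 * pot.D * dt)
    deriv = pot.poly.deriv()
    x = np.full(n_paths, float(phi0))
    n_rec = n_steps // record_every + 1
    out = np.empty((n_paths, n_rec))
    t_out = np.empty(n_rec)
    out[:, 0] = x
    t_out[0] = 0.0
    j = 1
    for k in range(1, n_steps + 1):
        x = x - deriv(x) * dt + amp * rng.standard_normal(n_paths)
        if np.any((x < guard_lo) | (x > guard_hi)):
            raise RuntimeError(
                f"Langevin path diverged beyond the working support at t={k * dt:.3f}"
            )
        if k % record_every == 0:
            out[:, j] = x
            t_out[j] = k * dt
            j += 1
    out = out[:, :j]
    t_out = t_out[:j]
    if n_paths == 1:
        return t_out, out[0]
    return t_out, out


def first_passage_rate(
    pot: PolyPotential,
    start: float,
    barrier: float,
    n_paths: int = 500,
    dt: float = 0.01,
    t_max: float = 5000.0,
    seed=0,
) -> float:
    """Empirical escape rate 1 / mean first-passage time to the barrier.

    Independent paths start at ``start`` and stop on first crossing of
    ``barrier`` (in either direction of approach).  Paths that never cross
    within ``t_max`` raise, since they would bias the mean.
    """
    rng = as_rng(seed)
    amp = np.sqrt(2.0 * pot.D * dt)
    deriv = pot.poly.deriv()
    n_steps = int(np.ceil(t_max / dt))
    x = np.full(n_paths, float(start))
    fpt = np.full(n_paths, np.nan)
    alive = np.ones(n_paths, dtype=bool)
    sign0 = np.sign(start - barrier)
    for k in range(1, n_steps + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        xa = x[idx]
        xa = xa - deriv(xa) * dt + amp * rng.standard_normal(idx.size)
        x[idx] = xa
        crossed = np.sign(xa - barrier) != sign0
        hit = idx[crossed]
        fpt[hit] = k * dt
        alive[hit] = False
    if np.any(np.isnan(fpt)):
        raise RuntimeError("some paths never reached the barrier within t_max")
    return float(1.0 / fpt.mean())


class PotentialLandscape(BaseEstimator):
    """Estimator: log-load sample -> fitted landscape, fixed points, D.

    Parameters: polynomial ``order`` (even, >= 4), histogram ``n_bins``,
    optional measured high-to-low rate ``alpha_l`` for noise estimation.

    Attributes after ``fit``: ``effective_`` (the histogram potential),
    ``potential_`` (R-scale polynomial), ``bistable_``, and when bistable
    ``fixed_points_``; with ``alpha_l`` also ``D_`` and
    ``absolute_potential_`` (U = D * R with that D attached).
    """

    def __init__(self, order=6, n_bins=40, alpha_l=None):
        self.order = order
        self.n_bins = n_bins
        self.alpha_l = alpha_l

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        self.support_ = default_support(x)
        self.effective_ = empirical_effective_potential(x, n_bins=self.n_bins)
        self.potential_ = fit_polynomial_potential(self.effective_, self.order)
        try:
            self.fixed_points_ = find_fixed_points(self.potential_, self.support_)
            self.bistable_ = True
        except NotBistableError:
            self.bistable_ = False
        if self.alpha_l is not None and self.bistable_:
            self.D_ = estimate_noise_D(self.potential_, self.fixed_points_, self.alpha_l)
            self.absolute_potential_ = self.potential_.scaled(self.D_).with_D(self.D_)
        return self
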