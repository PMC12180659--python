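"""Nonlinear log(CFU) <-> log(GFP) measurement calibration.

Whole-worm fluorescence is a saturating, floor-limited proxy for the true
bacterial load.  The forward map from x = log10 CFU to y = log10 GFP is a
hyperbolic tangent,

    y(x) = a * tanh((x - b) / c),

linear near the centre ``b`` and saturating at ``+-a`` near the sorter's
limits.  Its exact inverse,

    x(y) = (c/2) * ln((1 + y/a) / (1 - y/a)) + b,

is defined for |y| < a.  Densities fitted in log-CFU space transform to
log-GFP space by the change of variables

    P(y) = P(x(y)) * (c/a) / (1 - (y/a)^2),

which compresses the right tail — the skew seen in fluorescence data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CalibrationMap",
    "fit_calibration",
    "TanhCalibration",
    "logcfu_to_loggfp",
    "loggfp_to_logcfu",
    "transform_density",
]

_CLIP_EPS = 1e-9


@dataclass(frozen=True)
class CalibrationMap:
    """Constants of the tanh calibration: amplitude a, centre b, width c."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.a <= 0 or self.c <= 0:
            raise ValueError("calibration requires a > 0 and c > 0")

    def forward(self, x):
        """log-CFU -> log-GFP; strictly increasing, bounded in (-a, a)."""
        x = np.asarray(x, dtype=float)
        out = self.a * np.tanh((x - self.b) / self.c)
        return float(out) if out.ndim == 0 else out

    def inverse(self, y, clip: bool = True):
        """log-GFP -> log-CFU, the exact inverse of :meth:`forward`.

        Measured fluorescence can exceed the fitted asymptote; by default
        such values are clipped to ``+-(a - 1e-9)`` with a warning.  With
        ``clip=False`` out-of-domain values raise.
        """
        y = np.asarray(y, dtype=float)
        limit = self.a - _CLIP_EPS
        if np.any(np.abs(y) >= self.a):
            if not clip:
                raise ValueError("|y| >= a is outside the inverse-map domain")
            warnings.warn(
                "log-GFP values at or beyond the saturation asymptote were "
                "clipped before inversion",
                RuntimeWarning,
                stacklevel=2,
            )
        yc = np.clip(y, -limit, limit)
        out = 0.5 * self.c * np.log((1.0 + yc / self.a) / (1.0 - yc / self.a)) + self.b
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, record: dict) -> "CalibrationMap":
        return cls(a=record["a"], b=record["b"], c=record["c"])


def logcfu_to_loggfp(x, cal: CalibrationMap):
    """Forward calibration map ``y = a tanh((x - b)/c)``."""
    return cal.forward(x)


def loggfp_to_logcfu(y, cal: CalibrationMap, clip: bool = True):
    """Inverse calibration map; see :meth:`CalibrationMap.inverse`."""
    return cal.inverse(y, clip=clip)


def fit_calibration(log_cfu, log_gfp):
    """Nonlinear least squares of the tanh map to (log-CFU, log-GFP) pairs.

    Requires >= 4 pairs.  Returns a fitted :class:`TanhCalibration` whose
    ``map_`` holds the constants, ``rms_`` the RMS residual, and
    ``param_sd_`` the one-sigma parameter uncertainties (identifiability
    diagnostics; a wide interval on ``a`` flags data confined to the
    linear regime).
    """
    return TanhCalibration().fit(np.asarray(log_cfu), np.asarray(log_gfp))


class TanhCalibration(BaseEstimator, TransformerMixin):
    """sklearn-style estimator for the tanh fluorescence calibration.

    ``fit(X, y)`` takes log-CFU values ``X`` and log-GFP values ``y``;
    ``transform`` applies the forward map, ``inverse_transform`` the
    inverse.  Construct with explicit ``a, b, c`` to use known constants
    without fitting.
    """

    def __init__(self, a=None, b=None, c=None, clip=True):
        self.a = a
        self.b = b
        self.c = c
        self.clip = clip

    def _map(self) -> CalibrationMap:
        if hasattr(self, "map_"):
            return self.map_
        if self.a is None:
            raise RuntimeError("TanhCalibration is neither fitted nor parameterised")
        return CalibrationMap(a=self.a, b=self.b, c=self.c)

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        yv = np.asarray(y, dtype=float).ravel()
        if x.size != yv.size:
            raise ValueError("X and y must have the same length")
        if x.size < 4:
            raise ValueError("need >= 4 calibration pairs")
        a0 = max(np.abs(yv).max(), 1e-3)
        b0 = float(np.median(x))
        c0 = max((x.max() - x.min()) / 2.0, 1e-3)

        def model(x, a, b, c):
            return a * np.tanh((x - b) / c)

        try:
            popt, pcov = curve_fit(
                model,
                x,
                yv,
                p0=(a0, b0, c0),
                bounds=((1e-12, -np.inf, 1e-12), (np.inf, np.inf, np.inf)),
                maxfev=20_000,
            )
        except RuntimeError as err:  # pragma: no cover - optimizer pathology
            raise RuntimeError(f"calibration fit did not converge: {err}") from err
        self.map_ = CalibrationMap(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]))
        resid = yv - model(x, *popt)
        self.rms_ = float(np.sqrt(np.mean(resid**2)))
        with np.errstate(invalid="ignore"):
            sd = np.sqrt(np.diag(pcov))
        self.param_sd_ = {"a": float(sd[0]), "b": float(sd[1]), "c": float(sd[2])}
        # saturation unconstrained when all data sit in the linear regime
        self.weak_identifiability_ = bool(
            not np.isfinite(sd[0]) or sd[0] > 0.5 * self.map_.a
        )
        return self

    def transform(self, X):
        return self._map().forward(np.asarray(X, dtype=float))

    def inverse_transform(self, y):
        return self._map().inverse(np.asarray(y, dtype=float), clip=self.clip)

    def to_record(self) -> dict:
        m = self._map()
        rec = m.to_dict()
        if hasattr(self, "rms_"):
            rec["rms"] = self.rms_
        return rec


def transform_density(density_x, cal: CalibrationMap):
    """Push a log-CFU density through the calibration to log-GFP space.

    ``density_x`` is a callable density in x; the returned callable is the
    corresponding density in y on (-a, a):
    ``P(y) = P(x(y)) * (c/a) / (1 - (y/a)^2)``.
    """

    def density_y(y):
        y = np.asarray(y, dtype=float)
        inside = np.abs(y) < cal.a
        out = np.zeros_like(y, dtype=float)
        ys = y[inside]
        x = cal.inverse(ys, clip=True)
        jac = (cal.c / cal.a) / (1.0 - (ys / cal.a) ** 2)
        out[inside] = np.asarray(density_x(x), dtype=float) * jac
        return float(out) if out.ndim == 0 else out

    return density_y
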