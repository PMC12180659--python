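"""Synthetic snapshot data with known ground truth for every pipeline stage.

The generators emulate the two experimental designs:

* destructive CFU sampling — independent worms at each time point,
  produced by the colonisation/birth/death SSA, optionally with host
  heterogeneity;
* longitudinal fluorescence sorting — the same worms re-measured over
  time, produced by the two-state switching SDE, with true states kept.

The fluorescence measurement model applies the tanh calibration to
log10 load, adds Gaussian measurement noise, and masks weak signal with
an autofluorescence background draw (worms below the ~100-cells
detection floor report pure background); saturation comes from the
calibration asymptote.  Sorted low/high fluorescence bins with a gap
emulate the sorter separation experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_rng, spawn_rngs
from .calibration import CalibrationMap
from .gillespie import HeterogeneitySpec, simulate_ensemble
from .meanfield import LogisticRates
from .switching import STATE_HIGH, STATE_LOW, SwitchingModel, simulate_switching

__all__ = [
    "MeasurementModel",
    "DEFAULT_CALIBRATION",
    "gen_logistic_snapshot",
    "gen_switching_population",
    "apply_measurement",
    "gen_sorted_bins",
]

# fitted fluorescence calibration constants (amplitude, centre, width)
DEFAULT_CALIBRATION = CalibrationMap(a=4.00, b=0.884, c=3.064)


@dataclass(frozen=True)
class MeasurementModel:
    """Fluorescence measurement model: calibration + autofluorescence floor.

    ``autofluorescence_floor`` is the load (cells) below which only
    background is reported; ``background_level``/``background_sd``
    parameterise the log10-GFP autofluorescence of uncolonised worms.
    They are synthetic fixture choices — the underlying experiments report
    the floor only qualitatively.
    """

    calibration: CalibrationMap = field(default_factory=lambda: DEFAULT_CALIBRATION)
    autofluorescence_floor: float = 100.0
    background_level: float = 1.4
    background_sd: float = 0.1

    def __post_init__(self):
        if self.autofluorescence_floor < 0:
            raise ValueError("autofluorescence_floor must be >= 0")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")


def gen_logistic_snapshot(
    rates: LogisticRates,
    het: HeterogeneitySpec | None,
    n_worms: int,
    times,
    seed,
    condition: str = "synthetic",
) -> pd.DataFrame:
    """Destructive-sampling snapshot: independent worms at every time point.

    Wraps the SSA ensemble once per time point (fresh worms each time, the
    CFU design) and attaches ground-truth parameter columns.
    """
    times = np.asarray(times, dtype=float)
    frames = []
    child_seeds = np.random.SeedSequence(seed).generate_state(max(times.size, 1)) >> np.uint32(1)
    for j, t in enumerate(times):
        snap, params = simulate_ensemble(
            rates,
            het,
            n_worms,
            [t],
            int(child_seeds[j]),
            condition=condition,
            return_params=True,
        )
        snap = snap.merge(params.rename(columns={"b": "true_b", "c": "true_c", "V": "true_V"}), on="worm_id")
        snap["worm_id"] = [f"t{j}_{w}" for w in snap["worm_id"]]
        frames.append(snap.drop(columns=["d"]))
    if not frames:
        frames = [
            pd.DataFrame(
                columns=["worm_id", "time_h", "load", "condition", "true_b", "true_c", "true_V"]
            )
        ]
    out = pd.concat(frames, ignore_index=True)
    out["modality"] = "cfu"
    return out


def gen_switching_population(
    model: SwitchingModel,
    n_worms: int,
    times,
    p0_high: float,
    seed,
    dt: float = 0.01,
    condition: str = "synthetic",
) -> pd.DataFrame:
    """Longitudinal population under the two-state switching SDE.

    The same worms are measured at every time (the sorter design); true
    state is recorded per worm-time.  Each worm starts in its initial
    state's stationary neighbourhood — log-load drawn from the Gaussian
    approximation N(C_s, D_s / (r_s C_s)) around the state capacity.  The
    measurement column holds the load in cells (10**phi, phi clipped at 0).
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not 0.0 <= p0_high <= 1.0:
        raise ValueError("p0_high must lie in [0, 1]")
    rngs = spawn_rngs(seed, max(n_worms, 1))
    records = []
    for w in range(n_worms):
        rng = rngs[w]
        s0 = STATE_HIGH if rng.random() < p0_high else STATE_LOW
        if s0 == STATE_HIGH:
            r, C, D = model.r_high, model.C_high, model.D_high
        else:
            r, C, D = model.r_low, model.C_low, model.D_low
        spread = np.sqrt(D / (r * C)) if r > 0 else 0.0
        phi0 = C + spread * rng.standard_normal()
        t, phi, state = simulate_switching(
            model, phi0, s0, float(times.max()), dt=dt, seed=rng
        )
        idx = np.clip(np.searchsorted(t, times, side="right") - 1, 0, len(t) - 1)
        for tj, k in zip(times, idx):
            records.append(
                (
                    f"w{w:04d}",
                    float(tj),
                    float(10.0 ** max(phi[k], 0.0)),
                    condition,
                    int(state[k]),
                )
            )
    df = pd.DataFrame(
        records, columns=["worm_id", "time_h", "load", "condition", "true_state"]
    )
    df["modality"] = "cfu"
    return df


def apply_measurement(
    snapshot: pd.DataFrame, mm: MeasurementModel, seed
) -> pd.DataFrame:
    """Map a CFU snapshot through the fluorescence measurement model.

    Output rows carry log10 GFP in the ``load`` column with modality
    ``"gfp"``.  Loads below the autofluorescence floor report a pure
    background draw; otherwise the calibrated signal (plus measurement
    noise of sd ``background_sd``) is masked by an independent background
    draw via max(), reflecting that autofluorescence hides weak signal.
    """
    if "modality" in snapshot.columns and not (snapshot["modality"] == "cfu").all():
        raise ValueError("apply_measurement expects a CFU-modality snapshot")
    rng = as_rng(seed)
    out = snapshot.copy()
    loads = out["load"].to_numpy(dtype=float)
    n = loads.size
    background = rng.normal(mm.background_level, mm.background_sd, size=n)
    noise = rng.normal(0.0, mm.background_sd, size=n)
    with np.errstate(divide="ignore"):
        logload = np.log10(np.maximum(loads, 1e-300))
    signal = mm.calibration.forward(logload) + noise
    measured = np.where(
        loads < mm.autofluorescence_floor, background, np.maximum(signal, background)
    )
    measured = np.minimum(measured, mm.calibration.a)
    out["load"] = measured
    out["modality"] = "gfp"
    return out


def gen_sorted_bins(
    snapshot: pd.DataFrame, low_range: tuple, high_range: tuple
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a GFP snapshot into low/high fluorescence bins.

    Ranges are in raw fluorescence units (the measurement column holds
    log10 GFP) and must be disjoint with a gap; worms falling in the gap
    or outside both ranges are discarded, emulating the sorter gates.
    """
    lo1, hi1 = low_range
    lo2, hi2 = high_range
    if not (lo1 < hi1 and lo2 < hi2):
        raise ValueError("each range must be increasing")
    if hi1 >= lo2:
        raise ValueError("ranges must be disjoint with a gap (low below high)")
    gfp = 10.0 ** snapshot["load"].to_numpy(dtype=float)
    low_bin = snapshot[(gfp >= lo1) & (gfp <= hi1)].reset_index(drop=True)
    high_bin = snapshot[(gfp >= lo2) & (gfp <= hi2)].reset_index(drop=True)
    return low_bin, high_bin
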