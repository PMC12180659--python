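# wormgut

Stochastic models of gut bacterial load in mono-colonized *C. elegans*.

Populations of isogenic, age-synchronized worms colonized from a shared
inoculum still show order-of-magnitude variation in bacterial load per
host. `wormgut` implements the model ladder used to dissect that
variance in snapshot data (per-worm CFU counts, or whole-worm GFP
fluorescence as a saturating proxy):

1. **Null model** — colonization/birth/death dynamics on a gut of `V`
   sites: reactions `E → N` (rate *c*·E), `N + E → 2N` (rate *b*·N·E/V),
   `N → E` (rate *d*·N), simulated exactly (Gillespie SSA), with the
   mean-field occupancy ODE
   `dφ/dt = (1 − φ)(bφ + c) − dφ`, steady state `N* = V(1 − d/b)`,
   and log-space least-squares fitting of the rates to snapshot means.
2. **Static host heterogeneity** — per-worm rates drawn from truncated
   normals and/or carrying capacities resampled from data; fitted by a
   simulated likelihood on three bacterial-load levels
   (`ℒ = −Σᵢⱼ nᵢⱼ ln Pᵢⱼ`) with a grid search and a parametric-bootstrap
   rejection check.
3. **Measurement model** — the saturating fluorescence calibration
   `y = a·tanh((x − b)/c)` between log₁₀ CFU and log₁₀ GFP, its exact
   inverse, and the change-of-variables for densities; plus an
   autofluorescence floor (~100 cells/worm) in the synthetic generator.
4. **Mixture summaries** — two-component Gaussian mixtures in log-CFU
   space per time point; the high-mode weight series is the occupancy
   proxy for the high-load state.
5. **Multistable dynamics** — two interchangeable models of alternative
   load states: an explicit two-state (telegraph) switching model with
   per-state logistic SDEs and master-equation occupancy relaxation
   `P(s_H,t) = A e^{−(α_H+α_L)t} + α_H/(α_H+α_L)`, and a multiwell
   potential `dφ/dt = −U′(φ) + η` with Boltzmann stationary density
   `∝ exp(−U/D)`, Kramers escape rates, and noise-amplitude estimation
   from the histogram-based effective potential `R(φ) = −ln P̂(φ)`.

A synthetic-data module generates destructive-sampling (CFU-style) and
longitudinal (sorter-style) snapshot datasets with ground truth, so the
entire ladder runs and is tested with no external data.

## Worked example

Simulate a longitudinal population relaxing from the low state under
switching rates α_H = 0.08/h and α_L = 0.02/h, summarize each time point
with a mixture fit, and re-estimate the rates from the weight series:

```python
import numpy as np
from wormgut import (SwitchingModel, gen_switching_population,
                     weight_series, fit_switching_rates)

model = SwitchingModel(r_low=1.0, C_low=2.0, D_low=0.05,
                       r_high=1.0, C_high=5.5, D_high=0.05,
                       alpha_h=0.08, alpha_l=0.02)
snap = gen_switching_population(model, n_worms=300,
                                times=[6.0, 12, 24, 36, 48, 72],
                                p0_high=0.0, seed=42)
curve, table = weight_series(snap, seed=0)
fit = fit_switching_rates(curve)
print(table[["time_h", "w_L", "mu_L", "w_H", "mu_H"]].round(3).to_string(index=False))
print(f"alpha_h = {fit.alpha_h_:.4f} /h   alpha_l = {fit.alpha_l_:.4f} /h   p0 = {fit.p0_:.3f}")
```

prints

```
 time_h   w_L  mu_L   w_H  mu_H
    6.0 0.683 2.004 0.317 5.472
   12.0 0.463 2.045 0.537 5.487
   24.0 0.277 2.103 0.723 5.481
   36.0 0.210 2.046 0.790 5.490
   48.0 0.240 2.162 0.760 5.490
   72.0 0.193 2.147 0.807 5.496
alpha_h = 0.0725 /h   alpha_l = 0.0179 /h   p0 = 0.000
```

The two mixture modes sit at the state capacities (log₁₀ load ≈ 2.0 and
≈ 5.5); the high-mode weight `w_H` relaxes toward the stationary
occupancy α_H/(α_H + α_L) = 0.8, and the refitted rates land within
~10% of the generating values from 300 worms at six time points.

The same stages are available from the shell:

```bash
wormgut synth --config scenario.yaml --seed 3 --out snap.csv
wormgut fit-gmm --input snap.csv --seed 3 --out gmm.csv
wormgut fit-switching --input gmm.csv --seed 3 --out rates.json
```

Every output gets a `.runlog.json` sidecar with the seed, parameters and
a config hash for exact re-runs.

## Layout

```
src/wormgut/
  meanfield.py    mean-field ODE, steady states, rate fitting
  gillespie.py    exact SSA, heterogeneity, level likelihood, grid search
  calibration.py  tanh CFU<->GFP map, fitting, density transform
  mixture.py      2-component GMM summaries, weight series
  switching.py    telegraph model, occupancy relaxation, per-state SDE
  potential.py    effective potential, Kramers rates, Langevin simulation
  synth.py        synthetic snapshot generators + measurement model
  cli.py, io.py   command-line orchestration and plain-text I/O
docs/methods.md   modelling assumptions, conventions, limitations
```
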