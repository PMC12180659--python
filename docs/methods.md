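# Methods notes

This note records the modelling assumptions, parameter conventions and
numerical choices behind `wormgut`, and what the synthetic-data tests do
and do not establish about real measurements.

## The model ladder

**Null model.** A worm gut is `V` exchangeable sites; `N` are occupied.
Three reactions — colonization from the environment (`E → N`, propensity
*c*·E), within-host birth (`N + E → 2N`, propensity *b*·N·E/V) and loss
(`N → E`, propensity *d*·N) — are simulated exactly with the direct
Gillespie method. The birth propensity carries the `/V` scaling so that
the large-`V` mean-field limit is exactly
`dφ/dt = (1 − φ)(bφ + c) − dφ` for the occupancy density `φ = ⟨N/V⟩`.
All hosts share one parameter set; the only variance source is
demographic noise. With `c = 0` and `b > d` the stable state is
`N* = V(1 − d/b)`.

The SSA ensemble mean deviates from the mean-field ODE by a genuine
O(1/V) term proportional to the ensemble variance (the mean-field
closure drops `Cov(N, E)`), largest on the growth shoulder of the
trajectory. Cross-checks between the SSA and the ODE therefore compare
at time points away from the shoulder, where the measured deviation is
well below Monte-Carlo resolution at the ensemble sizes used.

**Host heterogeneity.** Two stationary-heterogeneity extensions: (i)
per-worm carrying capacities resampled with replacement from an
empirical pool (by default the 48 h saturation snapshot of the
highest-inoculum condition; a 36 h source is equally supported via
`capacity_pool_from_snapshot(..., source_time_h=36.0)`); (ii) per-worm
birth and colonization rates drawn from normal distributions. Negative
rate draws are rejected and redrawn rather than clipped, so no
probability atom accumulates at zero.

**Discretized likelihood.** Loads are binned into three levels
(low/medium/high) by two thresholds; boundary values belong to the lower
level. The data likelihood uses simulated level probabilities
`P_ij` with `ℒ = −Σ_ij n_ij ln P_ij` (natural log). Cells the
simulation misses are floored at `1/(2·n_sim)` and columns renormalized
— without the floor a single missed level makes `ℒ` infinite. The grid
search evaluates each candidate heterogeneity spec with common random
numbers (same child seed), so grid comparisons are not washed out by
simulation noise, and reports a parametric-bootstrap `ℒ` distribution at
the optimum; data beyond its 97.5th percentile are flagged rejected.

**Fluorescence calibration.** Between `x = log10 CFU` and
`y = log10 GFP`: `y = a·tanh((x − b)/c)`, inverse
`x = (c/2)·ln((1 + y/a)/(1 − y/a)) + b`, density change of variables
`P(y) = P(x(y))·(c/a)/(1 − (y/a)²)`. Both axes are log base 10; the
`ln` inside the inverse is the analytic inverse of tanh. Measured
fluorescence can exceed the fitted asymptote, so the inverse clips `y`
to ±(a − 1e−9) by default, with a warning. Fitting runs in the forward
direction with uniform weights; parameter standard errors from the
curvature flag amplitude non-identifiability when all pairs sit in the
linear regime.

**Mixture summaries.** A two-component Gaussian mixture is fitted per
time point in log-CFU space (EM, 10 seeded restarts, variance floor
σ² ≥ 1e−4 via the covariance regularizer), components sorted by mean.
The mixture is a summary statistic, not a partition of worms; the only
downstream product is the high-mode weight series, the proxy for
high-state occupancy. Zero-load worms are excluded by default (log
undefined); an alternative mode maps them to the detection-limit value
log10(100) = 2. At time points where the population is effectively
unimodal the two components overlap and the weight split is arbitrary —
such fits are flagged degenerate and occupancy fitting should use time
points where both modes exist.

**Two-state switching model.** A telegraph state `s ∈ {low, high}` with
rates α_H (low→high) and α_L (high→low); within a state, log-load obeys
`dφ/dt = r_s φ(C_s − φ) + η_s`. The master equation gives
`P(s_H,t) = (p0 − p*)e^{−(α_H+α_L)t} + p*`, `p* = α_H/(α_H+α_L)`; the
rate fit inverts this closed form by bounded least squares with `p0`
free by default (snapshot series usually include the transient). A flat
occupancy curve identifies only the ratio α_H/α_L; this is detected and
flagged rather than guessed around. Switching in the SDE simulation uses
per-step Bernoulli flips (probability α·dt, with a hard error when
max(α)·dt > 0.1); an exact exponential-waiting-time mode exists and is
used as the oracle in tests. The stationary load density is approximated
by the rate-weighted mixture of per-state Boltzmann densities
`∝ exp(r_s φ²(C_s/2 − φ/3)/D_s)`, normalized numerically on
`[0, C_high + 4√(D_high/r_high)]`. The mixture form treats the load
distribution conditional on the state as equilibrated; the tests probe
it in the regime where within-state relaxation (~1/(r·C) hours) is fast
against switching (~1/α hours), and its accuracy outside that regime is
not claimed.

**Potential landscape.** Overdamped Langevin dynamics
`dφ/dt = −U′(φ) + η` on a polynomial `U` of order 4 or 6. From snapshot
data only `R(φ) = −ln P̂(φ) = U/D` is identified (histogram, default 40
equal-width bins, empty bins excluded; count-weighted polynomial fit so
sparse tails do not dominate). Fixed points come from real roots of
`U′` inside the working support (data range ± 1 log unit), classified by
the sign of `U″`; exactly two minima and one interior barrier define
bistability. Kramers rates
`α = √(K_well K_barrier)/(2π)·exp(−ΔU/D)` use curvatures `K = |U″|`.
The noise amplitude is recovered by inverting the high→low rate under
`U = D·R`:

    D = 2π α_L · exp(R(C_M) − R(C_H)) / √(R″(C_H) R″(C_M)),

an algebraic identity enforced by a round-trip property test (rate →
noise → rate, exact to 1e−8) rather than by any particular printed
rendering. Order-6 fits are never worse than order-4 on the same
effective potential (nested models); in practice order 4 captures mode
positions but not widths.

## Noise convention

Throughout, a noise term written `⟨η(t)η(t′)⟩ ∝ D δ(t − t′)` is
implemented in Euler–Maruyama form as `dφ = drift·dt + √(2 D dt)·ξ`
with standard-normal ξ. This is the unique convention under which the
three closed forms used for cross-checks — the Boltzmann density
`exp(−U/D)`, its two-state mixture analogue, and the Kramers rates with
barrier `ΔU/D` — are mutually consistent, and the package's oracle
tests (stationary histogram vs Boltzmann, first passage vs Kramers)
enforce exactly that consistency. Time step 0.01 h by default; halving
it changes stationary moments by well under 2% in the configurations
tested.

## Mean-field rate fitting

The fit target is log10 of the per-time mean raw load (means before
logging); time points with zero mean load are excluded, and all-zero
data raise a degenerate-data error. The alternative target — the mean
of log10 of positive loads — is a defensible choice that weights low
worms more heavily; it is not the default. `V` is fixed to the maximum
observed load unless supplied: `b` and `d` compensate along the fit's
soft direction, so the net growth rate `b − d` is reported alongside the
individual rates and is the quantity recovered reliably (within 20% at
24 worms × 7 time points under 0.2-dex lognormal noise in the
simulation study shipped as a test).

## Synthetic data and the measurement model

The generators emulate: destructive CFU sampling (independent worms per
time point, SSA-generated, ground-truth parameters attached);
longitudinal sorter measurements (same worms across times, switching
SDE, true states recorded, initial log-load drawn from the initial
state's Gaussian stationary neighbourhood `N(C_s, D_s/(r_s C_s))`); and
the fluorescence readout — calibrated tanh signal plus Gaussian
measurement noise, masked by an independent autofluorescence draw via
`max(signal, background)`, and bounded by the saturation asymptote.
Loads under the ~100-cell detection floor report pure background.
Background level 1.4 and sd 0.1 (log10 GFP) are fixture choices — the
underlying experiments describe the autofluorescence floor only
qualitatively. Sorter gates in the generator are raw machine units
compared against `10^(log10 GFP)`.

What passing tests show: every estimator recovers the parameters of
data generated by its own (or the companion) model at desk scale, and
the independent closed-form/simulation oracles agree. What they do not
show: that real worm data satisfy these models — the generators omit
worm loss during handling, sorter optics beyond the background model,
day effects, and any load- or time-dependence of switching rates.

## Problem sizes and defaults

Defaults mirror the study designs: 24 worms × {3, 12, 18, 24, 36, 42,
48} h for CFU-style snapshots; 150 worms per sorted bin measured at
{0, 24, 48} h for sorter-style experiments; mixture fits with k = 2
fixed. Simulation-backed checks use 200–500 SSA runs, 5,000 Markov
chains, 10⁴-hour SDE runs or 100–200 parallel Langevin paths with ~10⁵
retained samples, and a 5 × 5 heterogeneity grid with 50 bootstrap
replicates — sizes at which the recovery tolerances above are met with
comfortable Monte-Carlo margins on a single CPU in minutes.

## Known limitations

- Exact SSA likelihoods are out of scope; inference on the stochastic
  model is simulation-based only.
- The Kramers formula is asymptotic; agreement with first-passage
  simulations is within a factor of ~2 at barrier/D ≥ 3 and degrades for
  shallow barriers.
- The effective potential inherits histogram binning bias; bin count is
  exposed and the default (40) is a compromise between resolution and
  per-bin counts at n ≈ 10³–10⁴ samples.
- Multi-species competition, host demography, spatial structure within
  the gut, and time-dependent transition rates are not modelled.
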