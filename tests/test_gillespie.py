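"""Exact SSA of colonisation/birth/death, level likelihood, grid search."""

import numpy as np
import pytest

from wormgut import (
    HeterogeneitySpec,
    LogisticRates,
    discretize_loads,
    gillespie_run,
    grid_search_heterogeneous,
    negative_log_likelihood,
    simulate_ensemble,
    solve_meanfield,
    zero_occupancy,
)
from wormgut.gillespie import EventCapError, het_grid, level_probabilities

RATES = LogisticRates(b=1.0, c=0.05, d=0.2, V=1000)


def test_no_source_reactions_stay_empty():
    traj = gillespie_run(LogisticRates(b=1, c=0, d=0.2, V=100), 0, 50.0, seed=0)
    assert np.all(traj.counts == 0)


def test_pure_death_is_monotone_to_extinction():
    traj = gillespie_run(LogisticRates(b=0, c=0, d=0.5, V=100), 50, 200.0, seed=1)
    assert np.all(np.diff(traj.counts) <= 0)
    assert traj.counts[-1] == 0


def test_counts_stay_within_capacity_on_random_parameters():
    rng = np.random.default_rng(7)
    for k in range(20):
        rates = LogisticRates(
            b=rng.uniform(0, 2),
            c=rng.uniform(0, 0.5),
            d=rng.uniform(0, 1),
            V=int(rng.integers(10, 300)),
        )
        traj = gillespie_run(rates, int(rng.integers(0, rates.V)), 20.0, seed=k)
        assert traj.counts.min() >= 0
        assert traj.counts.max() <= rates.V


def test_event_cap_raises():
    with pytest.raises(EventCapError):
        gillespie_run(LogisticRates(b=5, c=1, d=5, V=500), 0, 1e6, seed=0, max_events=1000)


def test_reproducible_given_seed():
    a = gillespie_run(RATES, 0, 10.0, seed=11)
    b = gillespie_run(RATES, 0, 10.0, seed=11)
    assert np.array_equal(a.counts, b.counts)
    assert np.array_equal(a.event_times, b.event_times)


def test_ensemble_mean_tracks_meanfield_ode():
    """SSA ensemble mean agrees with the ODE within 3 Monte-Carlo SE."""
    times = np.array([2.0, 12, 16, 22, 30])
    n_runs = 200
    loads = np.empty((n_runs, times.size))
    for k in range(n_runs):
        loads[k] = gillespie_run(RATES, 0, float(times[-1]), seed=1000 + k).at(times)
    mean = loads.mean(axis=0)
    se = loads.std(axis=0, ddof=1) / np.sqrt(n_runs)
    ode = RATES.V * solve_meanfield(RATES, 0.0, times).phi
    assert np.all(np.abs(mean - ode) < 3 * se)


def test_homogeneous_saturation_variance_is_demographic():
    # across-worm variance at saturation shrinks relative to mean^2 as V grows
    out = {}
    for V in (100, 10_000):
        rates = LogisticRates(b=1.0, c=0.1, d=0.2, V=V)
        snap = simulate_ensemble(rates, None, 40, [40.0], seed=3)
        loads = snap["load"].to_numpy()
        out[V] = loads.var(ddof=1) / loads.mean() ** 2
    assert out[10_000] < out[100] / 10
    assert out[10_000] < 0.01


def test_capacity_pool_produces_bimodal_saturation():
    het = HeterogeneitySpec(
        birth_mean=1.0, colonization_mean=0.1, capacity_pool=(100, 100_000)
    )
    snap = simulate_ensemble(RATES, het, 16, [30.0], seed=5)
    loads = snap["load"].to_numpy()
    assert (loads < 500).sum() >= 3
    assert (loads > 50_000).sum() >= 3
    assert not np.any((loads > 1000) & (loads < 20_000))


def test_colonization_rate_orders_first_colonisation_times():
    # stochastic ordering: higher c -> earlier first colonist
    mean_first = []
    for scale in (0.1, 1.0, 10.0):
        first = []
        for k in range(200):
            rates = LogisticRates(b=0.0, c=0.05 * scale, d=0.0, V=50)
            traj = gillespie_run(rates, 0, 400.0, seed=int(10_000 * scale) + k)
            colonised = traj.counts > 0
            assert colonised.any()
            first.append(traj.event_times[colonised][0])
        mean_first.append(np.mean(first))
    assert mean_first[0] > mean_first[1] > mean_first[2]


def test_zero_occupancy_decreases_with_colonization_rate():
    times = [6.0, 12.0]
    p_zero = []
    for scale in (0.1, 1.0, 10.0):
        rates = LogisticRates(b=0.5, c=0.02 * scale, d=0.2, V=200)
        snap = simulate_ensemble(rates, None, 200, times, seed=8)
        p_zero.append(zero_occupancy(snap)["p_zero"].to_numpy())
    p_zero = np.array(p_zero)
    assert np.all(np.diff(p_zero, axis=0) <= 0)


def test_zero_occupancy_binomial_arithmetic(snapshot_factory):
    snap = snapshot_factory([12], {12: [0] * 6 + [100] * 18})
    out = zero_occupancy(snap)
    assert out.loc[0, "p_zero"] == pytest.approx(0.25)
    assert out.loc[0, "sd"] == pytest.approx(np.sqrt(24 * 0.25 * 0.75) / 24, abs=1e-12)
    assert out.loc[0, "sd_pct"] == pytest.approx(100 * out.loc[0, "sd"])

    all_zero = snapshot_factory([3], {3: [0] * 24})
    out = zero_occupancy(all_zero)
    assert out.loc[0, "p_zero"] == 1.0 and out.loc[0, "sd"] == 0.0

    none_zero = snapshot_factory([3], {3: [5] * 24})
    out = zero_occupancy(none_zero)
    assert out.loc[0, "p_zero"] == 0.0 and out.loc[0, "sd"] == 0.0


def test_discretize_levels_and_boundary_rule(snapshot_factory):
    thresholds = (10**1.5, 10**4)
    snap = snapshot_factory(
        [12], {12: [0.0, 10**1.5, 31.7, 10**4, 10**5, 2.0]}
    )
    counts = discretize_loads(snap, thresholds)
    # boundary values (0, 10**1.5 and 10**4 here) belong to the lower level
    assert counts.n_ij[:, 0].tolist() == [3, 2, 1]
    assert counts.totals.tolist() == [6]


def test_discretize_conserves_worm_counts():
    snap = simulate_ensemble(RATES, None, 30, [3.0, 12.0, 24.0], seed=2)
    counts = discretize_loads(snap, (10**1.5, 10**4))
    per_time = snap.groupby("time_h").size().to_numpy()
    assert np.array_equal(counts.totals, per_time)


def test_discretize_empty_snapshot(snapshot_factory):
    snap = snapshot_factory([], {})
    counts = discretize_loads(snap, (10, 100))
    assert counts.n_ij.size == 0


def test_nll_uniform_and_gibbs_inequality(snapshot_factory):
    snap = snapshot_factory([12], {12: [1] * 8 + [100] * 10 + [10**5] * 6})
    counts = discretize_loads(snap, (10**1.5, 10**4))
    uniform = np.full((3, 1), 1 / 3)
    nll_uniform = negative_log_likelihood(counts, uniform)
    assert nll_uniform == pytest.approx(24 * np.log(3), rel=1e-12)
    empirical = counts.n_ij / counts.totals
    assert negative_log_likelihood(counts, empirical) < nll_uniform
    # empirical frequencies are the unique NLL minimiser (Gibbs inequality)
    rng = np.random.default_rng(0)
    for _ in range(20):
        probs = rng.dirichlet(np.ones(3)).reshape(3, 1)
        assert negative_log_likelihood(counts, empirical) <= negative_log_likelihood(
            counts, probs
        )


def test_nll_zero_counts_is_zero(snapshot_factory):
    snap = snapshot_factory([3], {3: [1.0]})
    counts = discretize_loads(snap, (10, 100))
    counts.n_ij[:] = 0
    assert negative_log_likelihood(counts, np.full((3, 1), 1 / 3)) == 0.0


def test_level_probabilities_floor_keeps_likelihood_finite():
    snap = simulate_ensemble(LogisticRates(b=1, c=0.5, d=0.1, V=100), None, 50, [30.0], seed=4)
    probs = level_probabilities(snap, (10, 50))
    assert np.all(probs > 0)
    assert probs.sum(axis=0) == pytest.approx(1.0)


def test_grid_search_single_point_is_trivial_best():
    base = LogisticRates(b=0.6, c=0.02, d=0.2, V=200)
    spec = HeterogeneitySpec(birth_mean=0.6, birth_sd=0.1, colonization_mean=0.02)
    data = simulate_ensemble(base, spec, 24, [6.0, 24.0], seed=9)
    result = grid_search_heterogeneous(
        data, [spec], base, (10.0, 80.0), n_rep=10, n_worms_sim=50, seed=1
    )
    assert result.best_index == 0
    assert result.nll_distribution.shape == (10,)


def test_grid_search_flags_misspecified_data():
    """A homogeneous model is rejected on strongly bimodal data."""
    base = LogisticRates(b=0.8, c=0.2, d=0.1, V=1000)
    het_truth = HeterogeneitySpec(
        birth_mean=0.8, colonization_mean=0.2, capacity_pool=(5, 1000)
    )
    data = simulate_ensemble(base, het_truth, 48, [12.0, 24.0], seed=13)
    homogeneous = HeterogeneitySpec(birth_mean=0.8, colonization_mean=0.2)
    result = grid_search_heterogeneous(
        data, [homogeneous], base, (10.0, 300.0), n_rep=30, n_worms_sim=100, seed=2
    )
    assert result.rejected


def test_truncated_normal_draws_are_nonnegative():
    het = HeterogeneitySpec(
        birth_mean=0.1, birth_sd=0.5, colonization_mean=0.05, colonization_sd=0.2
    )
    _, params = simulate_ensemble(
        LogisticRates(b=0.1, c=0.05, d=0.1, V=50),
        het,
        100,
        [1.0],
        seed=6,
        return_params=True,
    )
    assert (params["b"] >= 0).all() and (params["c"] >= 0).all()


def test_capacity_pool_extraction_by_source_time(snapshot_factory):
    from wormgut.gillespie import capacity_pool_from_snapshot

    snap = snapshot_factory(
        [36, 48], {36: [0, 500, 800], 48: [0, 1000, 2000, 3000]}
    )
    assert capacity_pool_from_snapshot(snap) == (1000, 2000, 3000)
    assert capacity_pool_from_snapshot(snap, source_time_h=36.0) == (500, 800)
    with pytest.raises(ValueError):
        capacity_pool_from_snapshot(snap, source_time_h=12.0)


def test_het_grid_cartesian_product():
    grid = het_grid(birth_mean=[0.4, 0.6], birth_sd=[0.0, 0.1, 0.2])
    assert len(grid) == 6
    with pytest.raises(ValueError):
        HeterogeneitySpec(birth_mean=-1.0)
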