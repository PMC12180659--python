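"""Multiwell potential landscape: effective potential, Kramers rates, Langevin."""

import numpy as np
import pytest

from wormgut import (
    PolyPotential,
    PotentialLandscape,
    empirical_effective_potential,
    estimate_noise_D,
    find_fixed_points,
    fit_polynomial_potential,
    kramers_rates,
    potential_stationary_pdf,
    simulate_potential,
)
from wormgut.potential import NotBistableError, first_passage_rate

# symmetric quartic double well U = (phi^2 - 1)^2 / 4
QUARTIC = PolyPotential(coefficients=(0.25, 0.0, -0.5, 0.0, 0.25), D=0.0625)


def test_effective_potential_of_gaussian_sample_is_quadratic():
    rng = np.random.default_rng(1)
    x = rng.normal(0.0, 1.0, 100_000)
    eff = empirical_effective_potential(x, n_bins=40)
    keep = np.abs(eff.phi) < 2
    resid = eff.R[keep] - eff.phi[keep] ** 2 / 2
    resid -= resid.mean()  # R is defined up to an additive constant
    assert np.sqrt(np.mean(resid**2)) < 0.05


def test_effective_potential_of_bimodal_sample_has_two_minima():
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(2, 0.3, 5000), rng.normal(5.5, 0.4, 5000)])
    eff = empirical_effective_potential(x, n_bins=40)
    interior = eff.R[1:-1]
    minima = np.sum((interior < eff.R[:-2]) & (interior <= eff.R[2:]))
    assert minima >= 2


def test_effective_potential_requires_enough_points():
    with pytest.raises(ValueError):
        empirical_effective_potential(np.arange(10), n_bins=5)


def test_polynomial_fit_recovers_known_sextic():
    coeffs = np.array([0.0, 0.1, -2.0, 0.3, 1.0, -0.05, 0.08])
    truth = PolyPotential(coefficients=tuple(coeffs))
    rng = np.random.default_rng(3)
    phi = np.linspace(-2, 2, 60)
    from wormgut.potential import EffectivePotential

    eff = EffectivePotential(
        phi=phi, R=truth.U(phi) + rng.normal(0, 0.01, phi.size), counts=np.full(phi.size, 100.0)
    )
    fitted = fit_polynomial_potential(eff, order=6)
    np.testing.assert_allclose(fitted.coefficients[1:], coeffs[1:], atol=0.05)


def test_polynomial_fit_rejects_odd_or_low_order():
    rng = np.random.default_rng(4)
    eff = empirical_effective_potential(rng.normal(0, 1, 1000), n_bins=20)
    for order in (3, 5, 2):
        with pytest.raises(ValueError):
            fit_polynomial_potential(eff, order=order)


def test_unimodal_data_classified_single_minimum():
    rng = np.random.default_rng(5)
    est = PotentialLandscape(order=4, n_bins=30).fit(rng.normal(4, 1, 20_000))
    assert not est.bistable_


def test_fixed_points_closed_form_quartic():
    fp = find_fixed_points(QUARTIC, (-3, 3))
    assert fp.C_L == pytest.approx(-1.0, abs=1e-10)
    assert fp.C_M == pytest.approx(0.0, abs=1e-10)
    assert fp.C_H == pytest.approx(1.0, abs=1e-10)
    assert fp.K_L == pytest.approx(2.0) and fp.K_H == pytest.approx(2.0)
    assert fp.K_M == pytest.approx(1.0)


def test_single_well_raises_not_bistable():
    with pytest.raises(NotBistableError):
        find_fixed_points(PolyPotential(coefficients=(0, 0, 0.5)), (-3, 3))


def test_random_bistable_sextics_match_grid_oracle():
    rng = np.random.default_rng(6)
    for _ in range(10):
        # build U' with five real roots -> three minima candidates; scale U
        roots = np.sort(rng.uniform(-2, 2, 5))
        lead = rng.uniform(0.5, 2.0)
        dU = lead * np.polynomial.Polynomial.fromroots(roots)
        U = dU.integ()
        pot = PolyPotential(coefficients=tuple(U.convert().coef))
        support = (roots[0] - 0.5, roots[-1] + 0.5)
        # keep only genuinely bistable draws (no near-degenerate stationary pts)
        if np.min(np.diff(roots)) < 0.15:
            continue
        try:
            fp = find_fixed_points(pot, support)
        except NotBistableError:
            continue
        grid = np.linspace(*support, 400_001)
        u = pot.U(grid)
        for c in (fp.C_L, fp.C_H):
            window = np.abs(grid - c) < 0.1
            assert abs(grid[window][np.argmin(u[window])] - c) < 1e-4


def test_kramers_symmetry_and_barrier_monotonicity():
    fp = find_fixed_points(QUARTIC, (-3, 3))
    ah, al = kramers_rates(QUARTIC, fp)
    assert ah == pytest.approx(al, rel=1e-12)
    # scaling the barrier up at fixed D strictly decreases both rates
    taller = PolyPotential(
        coefficients=tuple(2 * c for c in QUARTIC.coefficients), D=QUARTIC.D
    )
    ah2, al2 = kramers_rates(taller, find_fixed_points(taller, (-3, 3)))
    assert ah2 < ah and al2 < al


def test_noise_estimation_round_trip_is_exact():
    """estimate_noise_D inverts kramers_rates: the module keystone."""
    for D in (0.05, 0.0625, 0.11):
        pot = QUARTIC.with_D(D)
        fp = find_fixed_points(pot, (-3, 3))
        _, alpha_l = kramers_rates(pot, fp)
        R = pot.scaled(1.0 / D)
        fp_R = find_fixed_points(R, (-3, 3))
        assert estimate_noise_D(R, fp_R, alpha_l) == pytest.approx(D, abs=1e-8)


def test_noise_estimate_proportional_to_rate():
    fp = find_fixed_points(QUARTIC, (-3, 3))
    R = QUARTIC.scaled(1.0 / QUARTIC.D)
    fp_R = find_fixed_points(R, (-3, 3))
    d1 = estimate_noise_D(R, fp_R, 0.01)
    d2 = estimate_noise_D(R, fp_R, 0.02)
    assert d2 == pytest.approx(2 * d1, rel=1e-12)


def test_stationary_pdf_gaussian_limit():
    k, D = 2.0, 0.1
    pot = PolyPotential(coefficients=(0.0, 0.0, k / 2), D=D)
    grid, pdf = potential_stationary_pdf(pot, (-3, 3), 8001)
    assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-6)
    var = np.trapezoid(grid**2 * pdf, grid)
    assert var == pytest.approx(D / k, rel=1e-3)


def test_stationary_pdf_matches_exponential_of_minus_R():
    # definitional identity: with R = U/D the Boltzmann density is exp(-R)
    pot = QUARTIC
    R = pot.scaled(1.0 / pot.D).with_D(1.0)
    g1, p1 = potential_stationary_pdf(pot, (-2.5, 2.5), 2001)
    g2, p2 = potential_stationary_pdf(R, (-2.5, 2.5), 2001)
    np.testing.assert_allclose(p1, p2, atol=1e-10)


def test_order6_fit_never_worse_than_order4():
    rng = np.random.default_rng(7)
    x = np.concatenate([rng.normal(2, 0.35, 6000), rng.normal(5.5, 0.5, 6000)])
    eff = empirical_effective_potential(x, n_bins=40)

    def wrss(pot):
        return float(np.sum(eff.counts * (pot.U(eff.phi) - eff.R) ** 2))

    assert wrss(fit_polynomial_potential(eff, 6)) <= wrss(fit_polynomial_potential(eff, 4))


def test_langevin_gradient_descent_limit():
    pot = QUARTIC.with_D(1e-14)
    _, phi = simulate_potential(pot, 0.6, t_end=50, dt=0.01, seed=0, support=(-3, 3))
    assert phi[-1] == pytest.approx(1.0, abs=1e-4)


def test_langevin_blow_up_guard():
    runaway = PolyPotential(coefficients=(0.0, 0.0, -5.0), D=0.01)  # inverted well
    with pytest.raises(RuntimeError):
        simulate_potential(runaway, 0.5, t_end=100, dt=0.01, seed=1, support=(-1, 1))


def test_langevin_basin_occupancy_matches_kramers_ratio():
    # asymmetric double well: tilt the quartic so the high basin is favoured
    tilted = PolyPotential(
        coefficients=(0.25, -0.05, -0.5, 0.0, 0.25), D=0.125
    )
    fp = find_fixed_points(tilted, (-3, 3))
    ah, al = kramers_rates(tilted, fp)
    expected = ah / (ah + al)
    times, paths = simulate_potential(
        tilted, fp.C_H, 800.0, dt=0.01, seed=3, support=(-3, 3), n_paths=60, record_every=50
    )
    times2, paths2 = simulate_potential(
        tilted, fp.C_L, 800.0, dt=0.01, seed=4, support=(-3, 3), n_paths=60, record_every=50
    )
    samples = np.concatenate(
        [paths[:, times > 200].ravel(), paths2[:, times2 > 200].ravel()]
    )
    frac_high = (samples > fp.C_M).mean()
    # block SE over paths
    per_path = np.concatenate(
        [(paths[:, times > 200] > fp.C_M).mean(axis=1), (paths2[:, times2 > 200] > fp.C_M).mean(axis=1)]
    )
    se = per_path.std(ddof=1) / np.sqrt(per_path.size)
    assert abs(frac_high - expected) < 3 * se + 0.02


def test_langevin_step_halving_stationary_variance():
    k, D = 2.0, 0.1
    pot = PolyPotential(coefficients=(0.0, 0.0, k / 2), D=D)
    variances = []
    for dt, seed in ((0.01, 5), (0.005, 6)):
        times, paths = simulate_potential(
            pot, 0.0, 600.0, dt=dt, seed=seed, support=(-3, 3), n_paths=100, record_every=20
        )
        variances.append(paths[:, times > 10].var())
    assert abs(variances[0] - variances[1]) / variances[1] < 0.02


def test_kramers_vs_first_passage_within_factor_two():
    fp = find_fixed_points(QUARTIC, (-3, 3))
    _, alpha_l = kramers_rates(QUARTIC, fp)  # barrier/D = 4
    emp = first_passage_rate(
        QUARTIC, start=fp.C_H, barrier=fp.C_M, n_paths=200, dt=0.01, t_max=20_000, seed=7
    )
    assert 0.5 < alpha_l / emp < 2.0


def test_landscape_estimator_end_to_end():
    rng = np.random.default_rng(9)
    x = np.concatenate([rng.normal(2, 0.3, 4000), rng.normal(5.5, 0.4, 8000)])
    est = PotentialLandscape(order=6, n_bins=40, alpha_l=0.02).fit(x)
    assert est.bistable_
    assert est.fixed_points_.C_L == pytest.approx(2.0, abs=0.3)
    assert est.fixed_points_.C_H == pytest.approx(5.5, abs=0.3)
    assert est.D_ > 0
    assert est.absolute_potential_.D == pytest.approx(est.D_)
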