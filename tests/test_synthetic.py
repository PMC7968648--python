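"""Synthetic generator: populations, covariates, counts, thinning."""

import numpy as np
import pytest

from bymap import (
    CovariatePanel,
    EventPanel,
    ExpectedCounts,
    TruthRecord,
    build_lattice,
    simulate_counts,
    simulate_covariates,
    simulate_populations,
    simulate_scenario,
    simulate_truth,
    thin_counts,
)
from bymap.exceptions import InputError


# -- populations -----------------------------------------------------------


def test_zero_growth_gives_identical_censuses():
    g = build_lattice(6, "grid")
    pop = simulate_populations(g, (2000, 2010), growth_range=(0.0, 0.0), seed=3)
    assert np.allclose(pop.sel_year(2000), pop.sel_year(2010))


def test_populations_are_deterministic_under_a_seed():
    g = build_lattice(6, "grid")
    a = simulate_populations(g, (2000, 2010), seed=9)
    b = simulate_populations(g, (2000, 2010), seed=9)
    assert np.array_equal(a.values, b.values)


def test_compound_growth_matches_closed_form():
    g = build_lattice(5, "ring")
    pop = simulate_populations(
        g, (2000, 2010), base_size=10_000, growth_range=(0.02, 0.02), seed=0
    )
    assert np.allclose(pop.region_totals(2000), 10_000.0)
    assert np.allclose(pop.region_totals(2010), 10_000 * 1.02**10)  # ~12189.9


def test_single_census_rejected():
    g = build_lattice(4, "grid")
    with pytest.raises(InputError):
        simulate_populations(g, (2006,))


def test_region_totals_vary_with_nondegenerate_growth():
    g = build_lattice(8, "grid")
    pop = simulate_populations(g, (2000, 2010), growth_range=(0.0, 0.05), seed=1)
    assert np.std(pop.region_totals(2010)) > 0


# -- covariates ------------------------------------------------------------


def test_completeness_interpolates_between_endpoints():
    g = build_lattice(6, "grid")
    cov = simulate_covariates(g, ("p1", "p2", "p3"), (0.22, 0.75), seed=0)
    assert np.allclose(cov.completeness[:, 0], 0.22)
    assert np.allclose(cov.completeness[:, -1], 0.75)
    assert np.allclose(cov.completeness[:, 1], (0.22 + 0.75) / 2)


def test_full_registration_endpoints():
    g = build_lattice(6, "grid")
    cov = simulate_covariates(g, ("p1", "p2"), (1.0, 1.0), seed=0)
    assert np.all(cov.completeness == 1.0)


def test_bad_completeness_endpoint_rejected():
    g = build_lattice(6, "grid")
    with pytest.raises(InputError):
        simulate_covariates(g, ("p1",), (0.0, 0.5))


def test_wealth_smoothing_one_on_ring_equals_neighbour_mean(ring4):
    seed = 42
    cov = simulate_covariates(ring4, ("p1",), (0.5, 0.5), wealth_smoothing=1.0, seed=seed)
    # the raw field is the first normal draw of the operation's stream
    z = np.random.default_rng(seed).normal(size=4)
    w = ring4.adjacency_matrix(row_standardised=True)
    assert np.allclose(cov.wealth_index, w @ z)


# -- counts and thinning ---------------------------------------------------


def _flat_setup(n, e_value, alpha):
    g = build_lattice(n, "ring")
    periods = ("p1",)
    expected = ExpectedCounts(g.region_ids, periods, np.full((n, 1), float(e_value)))
    cov = simulate_covariates(g, periods, (0.5, 0.5), seed=0)
    truth = TruthRecord(
        alpha=alpha, beta=np.zeros(0), covariate_names=(),
        u=np.zeros(n), v=np.zeros(n), tau_u=1.0, tau_v=1.0,
    )
    return g, expected, cov, truth


def test_unit_relative_risk_ratio_near_one():
    g, e, cov, truth = _flat_setup(1000, 10.0, alpha=0.0)
    o = simulate_counts(e, cov, truth, g, seed=5)
    ratio = o.totals().sum() / e.values.sum()
    assert 0.95 < ratio < 1.05


def test_zero_expectation_forces_zero_counts():
    g, e, cov, truth = _flat_setup(20, 0.0, alpha=0.0)
    o = simulate_counts(e, cov, truth, g, seed=5)
    assert np.all(o.counts == 0)


def test_doubled_intercept_doubles_the_poisson_mean():
    # alpha = log 2, E = 10: pooled mean over many regions ~ 20 +- 3 SE
    n = 10_000
    g, e, cov, truth = _flat_setup(n, 10.0, alpha=np.log(2.0))
    o = simulate_counts(e, cov, truth, g, seed=5)
    se = np.sqrt(20.0 / n)
    assert abs(o.totals().mean() - 20.0) < 3 * se


def test_thinning_with_full_completeness_is_identity():
    g, e, cov, truth = _flat_setup(50, 30.0, alpha=0.0)
    cov.completeness[:] = 1.0
    o = simulate_counts(e, cov, truth, g, seed=2)
    assert np.array_equal(thin_counts(o, cov, seed=3).counts, o.counts)


def test_thinning_to_nothing():
    g = build_lattice(5, "ring")
    panel = EventPanel(g.region_ids, ("all",), ("p1",), np.full((5, 1, 1), 100.0))
    cov = simulate_covariates(g, ("p1",), (1e-9, 1e-9), seed=0)
    assert thin_counts(panel, cov, seed=0).counts.sum() == 0


def test_thinning_mean_matches_binomial_expectation():
    # O = 1000, c = 0.22 over 1000 cells: mean within 3 SE of 220
    n = 1000
    g = build_lattice(n, "ring")
    panel = EventPanel(g.region_ids, ("all",), ("p1",), np.full((n, 1, 1), 1000.0))
    cov = simulate_covariates(g, ("p1",), (0.22, 0.22), seed=0)
    thinned = thin_counts(panel, cov, seed=8)
    se = np.sqrt(1000 * 0.22 * 0.78 / n)
    assert abs(thinned.counts.mean() - 220.0) < 3 * se
    assert np.all(thinned.counts <= panel.counts)


def test_thinning_is_stochastically_monotone_in_completeness():
    n = 400
    g = build_lattice(n, "ring")
    panel = EventPanel(g.region_ids, ("all",), ("p1",), np.full((n, 1, 1), 200.0))
    means = []
    for c in (0.3, 0.6, 0.9):
        cov = simulate_covariates(g, ("p1",), (c, c), seed=0)
        means.append(thin_counts(panel, cov, seed=4).counts.mean())
    assert means[0] < means[1] < means[2]


def test_pooled_null_ratio_concentrates_at_one():
    # O/(E*c) with null effects, pooled over many regions, -> 1
    n = 500
    g, e, cov, truth = _flat_setup(n, 50.0, alpha=0.0)
    o = simulate_counts(e, cov, truth, g, seed=6)
    thinned = thin_counts(o, cov, seed=7)
    ratio = thinned.totals().sum() / (e.values * cov.completeness).sum()
    assert 0.95 < ratio < 1.05


# -- truth and scenarios ---------------------------------------------------


def test_truth_spatial_field_is_centred_and_scaled():
    g = build_lattice(25, "grid")
    t = simulate_truth(g, sigma_u=0.4, sigma_v=0.15, seed=3)
    assert abs(t.u.mean()) < 1e-10
    assert np.isclose(t.u.std(), 0.4)
    assert t.tau_u == pytest.approx(1 / 0.4**2)


def test_scenario_is_bitwise_reproducible(tmp_path):
    a = simulate_scenario(seed=123, n_regions=12)
    b = simulate_scenario(seed=123, n_regions=12)
    assert np.array_equal(a.counts_observed.counts, b.counts_observed.counts)
    assert np.array_equal(a.expected.values, b.expected.values)
    assert np.array_equal(a.truth.u, b.truth.u)
    # round-trips through tidy CSV/JSON
    a.write(tmp_path)
    c = type(a).read(tmp_path)
    assert np.allclose(c.counts_observed.counts, a.counts_observed.counts)
    assert np.allclose(c.covariates.wealth_index, a.covariates.wealth_index)
    assert c.graph.neighbours == a.graph.neighbours


def test_scenario_drop_year_reduces_expected():
    full = simulate_scenario(seed=5, n_regions=9)
    dropped = simulate_scenario(seed=5, n_regions=9, drop_years=(2006,))
    k = list(full.period_years).index("2004-2007")
    assert np.all(dropped.expected.values[:, k] < full.expected.values[:, k])
    other = [i for i in range(3) if i != k]
    assert np.allclose(dropped.expected.values[:, other], full.expected.values[:, other])
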