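"""Interpolation, reference rates, indirect standardisation, completeness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bymap import (
    CovariatePanel,
    EventPanel,
    ExpectedCounts,
    PopulationGrid,
    ReferenceRates,
    adjust_for_completeness,
    asr_from_relative_risk,
    build_reference_rates,
    compute_expected,
    inflate_counts,
    interpolate_population,
)
from bymap.demography import MAX_EXTRAPOLATION_YEARS
from bymap.exceptions import ContractError, DegenerateGrowthError, InputError, RangeError
from bymap.model import BYMState, poisson_loglik


def _grid(values, years=(1996, 2006), regions=("A",), bands=("30-34",)):
    arr = np.asarray(values, dtype=float).reshape(len(regions), len(bands), len(years))
    return PopulationGrid(regions, bands, years, arr)


# -- interpolation ---------------------------------------------------------


def test_interpolation_is_exact_at_census_years():
    g = _grid([1000.0, 2000.0])
    assert interpolate_population(g, 1996).values[0, 0, 0] == 1000.0
    assert interpolate_population(g, 2006).values[0, 0, 0] == 2000.0


def test_geometric_midpoint():
    g = _grid([1000.0, 2000.0])
    val = interpolate_population(g, 2001).values[0, 0, 0]
    assert val == pytest.approx(1000 * 2**0.5)  # ~1414.21


def test_flat_population_stays_flat():
    g = _grid([500.0, 500.0])
    assert interpolate_population(g, 2003).values[0, 0, 0] == 500.0


def test_degenerate_growth_from_zero():
    g = _grid([0.0, 100.0])
    with pytest.raises(DegenerateGrowthError):
        interpolate_population(g, 2000)


def test_range_limits():
    g = _grid([1000.0, 2000.0])
    with pytest.raises(RangeError):
        interpolate_population(g, 1990)
    with pytest.raises(RangeError):
        interpolate_population(g, 2006 + MAX_EXTRAPOLATION_YEARS + 1)
    # extrapolation carries the last intercensal growth forward
    val = interpolate_population(g, 2008).values[0, 0, 0]
    assert val == pytest.approx(1000 * 2 ** (12 / 10))


@given(
    pa=st.floats(min_value=1.0, max_value=1e6),
    pb=st.floats(min_value=1.0, max_value=1e6),
    t=st.integers(min_value=1996, max_value=2006),
)
def test_interpolation_agrees_with_log_linear_fit(pa, pb, t):
    g = _grid([pa, pb])
    val = interpolate_population(g, t).values[0, 0, 0]
    loglin = np.exp(np.interp(t, [1996, 2006], np.log([pa, pb])))
    assert val == pytest.approx(loglin, rel=1e-12)


# -- reference rates -------------------------------------------------------


def _one_band_inputs(events, pop):
    counts = EventPanel(("A",), ("30-34",), ("2010",), np.array([[[float(events)]]]))
    grid = _grid([pop, pop], years=(2006, 2010))
    return counts, grid


def test_null_epidemic_gives_zero_rates():
    counts, grid = _one_band_inputs(0, 100_000)
    ref = build_reference_rates(counts, grid, 2010)
    assert np.all(ref.rates == 0)
    assert ref.reference_asr == 0.0


def test_single_band_rate_arithmetic():
    counts, grid = _one_band_inputs(50, 100_000)
    ref = build_reference_rates(counts, grid, 2010)
    assert ref.rates[0] == pytest.approx(5e-4)
    assert ref.reference_asr == pytest.approx(50.0)


def test_reference_rates_scale_invariant():
    c1, g1 = _one_band_inputs(50, 100_000)
    c2, g2 = _one_band_inputs(100, 200_000)
    r1 = build_reference_rates(c1, g1, 2010)
    r2 = build_reference_rates(c2, g2, 2010)
    assert np.allclose(r1.rates, r2.rates)


# -- expected counts -------------------------------------------------------


def _two_band_pop(p1, p2):
    return PopulationGrid(
        ("A",), ("30-34", "35-39"), (2000, 2001),
        np.array([[[p1, p1], [p2, p2]]], dtype=float),
    )


def test_zero_rates_give_zero_expected():
    pop = _two_band_pop(1e5, 1e5)
    ref = ReferenceRates(pop.age_bands, [0.0, 0.0], [1.0, 1.0])
    e = compute_expected(pop, ref, {"p": (2000,)})
    assert np.all(e.values == 0)


def test_single_cell_product():
    pop = PopulationGrid(("A",), ("30-34",), (2000, 2001),
                         np.array([[[100_000.0, 100_000.0]]]))
    ref = ReferenceRates(("30-34",), [1e-3], [1.0])
    e = compute_expected(pop, ref, {"p": (2000,)})
    assert e.values[0, 0] == pytest.approx(100.0)


def test_two_band_hand_sum():
    pop = _two_band_pop(50_000, 50_000)
    ref = ReferenceRates(pop.age_bands, [1e-3, 2e-3], [1.0, 1.0])
    e = compute_expected(pop, ref, {"p": (2000,)})
    assert e.values[0, 0] == pytest.approx(150.0)  # 50 + 100


def test_expected_is_additive_over_years_and_linear_in_rates():
    pop = _two_band_pop(40_000, 60_000)
    ref = ReferenceRates(pop.age_bands, [1e-3, 2e-3], [1.0, 1.0])
    both = compute_expected(pop, ref, {"p": (2000, 2001)})
    y1 = compute_expected(pop, ref, {"p": (2000,)})
    y2 = compute_expected(pop, ref, {"p": (2001,)})
    assert np.allclose(both.values, y1.values + y2.values)
    ref2 = ReferenceRates(pop.age_bands, [2e-3, 4e-3], [1.0, 1.0])
    assert np.allclose(
        compute_expected(pop, ref2, {"p": (2000,)}).values, 2 * y1.values
    )


@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_expected_superposition_in_populations(scale):
    pop1 = _two_band_pop(30_000, 20_000)
    pop2 = _two_band_pop(10_000 * scale, 5_000 * scale)
    summed = PopulationGrid(
        pop1.region_ids, pop1.age_bands, pop1.years, pop1.values + pop2.values
    )
    ref = ReferenceRates(pop1.age_bands, [1e-3, 3e-3], [1.0, 1.0])
    pmap = {"p": (2000,)}
    assert np.allclose(
        compute_expected(summed, ref, pmap).values,
        compute_expected(pop1, ref, pmap).values + compute_expected(pop2, ref, pmap).values,
    )


# -- completeness ----------------------------------------------------------


def _cov(regions, periods, c):
    shape = (len(regions), len(periods))
    return CovariatePanel(
        regions, periods, np.full(shape, c), np.full(shape, 0.5),
        np.full(shape, 6.0), np.zeros(len(regions)),
    )


def test_full_completeness_leaves_expected_unchanged():
    e = ExpectedCounts(("A",), ("p",), np.array([[100.0]]))
    out = adjust_for_completeness(e, _cov(("A",), ("p",), 1.0))
    assert out.values[0, 0] == 100.0


def test_offset_mode_scales_expected_by_completeness():
    e = ExpectedCounts(("A",), ("p",), np.array([[100.0]]))
    out = adjust_for_completeness(e, _cov(("A",), ("p",), 0.75))
    assert out.values[0, 0] == pytest.approx(75.0)


def test_inflate_mode_counts_rejected_by_likelihood():
    e = ExpectedCounts(("A",), ("p",), np.array([[100.0]]))
    cov = _cov(("A",), ("p",), 0.75)
    assert np.array_equal(
        adjust_for_completeness(e, cov, mode="inflate").values, e.values
    )
    panel = EventPanel(("A",), ("all",), ("p",), np.array([[[80.0]]]))
    inflated = inflate_counts(panel, cov)
    assert not inflated.is_integer
    state = BYMState(0.0, np.zeros(0), np.zeros(1), np.zeros(1), 1.0, 1.0)
    with pytest.raises(ContractError):
        poisson_loglik(state, inflated, e)


# -- ASR scaling -----------------------------------------------------------


def test_asr_scaling():
    ref = ReferenceRates(("30-34",), [22.8e-5], [1.0])
    assert ref.reference_asr == pytest.approx(22.8)
    assert asr_from_relative_risk(1.0, ref) == pytest.approx(22.8)
    assert asr_from_relative_risk(0.0, ref) == 0.0
    assert asr_from_relative_risk(2.0, ref) == pytest.approx(45.6)
    with pytest.raises(ContractError):
        asr_from_relative_risk(np.array([-0.1]), ref)
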