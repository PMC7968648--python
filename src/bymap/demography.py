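"""Demographic building blocks: intercensal interpolation, reference rates,
indirect standardisation and registry-completeness adjustment.

Expected counts follow the indirect-standardisation convention: national
age-specific reference rates (here, the reference year's national rates)
are applied to each region's age structure and summed over the calendar
years of each reporting interval,

    E[i, p] = sum_{t in p} sum_a rate_a * P[i, a, t].

The smoothed relative risk theta from the spatial model then scales the
reference age-standardised rate into a region ASR per 100,000.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .containers import (
    CovariatePanel,
    EventPanel,
    ExpectedCounts,
    PopulationGrid,
    ReferenceRates,
)
from .exceptions import (
    ContractError,
    DegenerateGrowthError,
    InputError,
    RangeError,
    SchemaError,
)

__all__ = [
    "interpolate_population",
    "interpolate_years",
    "build_reference_rates",
    "compute_expected",
    "adjust_for_completeness",
    "inflate_counts",
    "asr_from_relative_risk",
]

#: how far beyond the last census geometric extrapolation is allowed (years)
MAX_EXTRAPOLATION_YEARS = 5


def interpolate_population(grid: PopulationGrid, target_year: int) -> PopulationGrid:
    """Geometric (constant-exponential-growth) interpolation to one year.

    Between the bracketing censuses a <= t <= b each cell follows
    ``P_t = P_a * (P_b / P_a) ** ((t - a) / (b - a))``, which is exact at
    census years and equivalent to log-linear interpolation wherever both
    endpoints are positive.  Up to ``MAX_EXTRAPOLATION_YEARS`` beyond the
    last census the growth rate of the final intercensal interval is
    carried forward.
    """
    t = int(target_year)
    years = grid.years
    if len(years) < 2:
        raise InputError("interpolation requires at least two census years")
    if t < years[0]:
        raise RangeError(f"target year {t} precedes the first census {years[0]}")
    if t > years[-1] + MAX_EXTRAPOLATION_YEARS:
        raise RangeError(
            f"target year {t} is more than {MAX_EXTRAPOLATION_YEARS} years "
            f"beyond the last census {years[-1]}"
        )
    if t in years:
        return PopulationGrid(grid.region_ids, grid.age_bands, (t,), grid.sel_year(t)[:, :, None])

    if t > years[-1]:  # extrapolate with the last intercensal growth
        a, b = years[-2], years[-1]
    else:
        a = max(y for y in years if y < t)
        b = min(y for y in years if y > t)
    pa, pb = grid.sel_year(a), grid.sel_year(b)
    if np.any((pa == 0) & (pb > 0)):
        raise DegenerateGrowthError(
            "zero population at the earlier census with positive later census: "
            "geometric growth is undefined"
        )
    frac = (t - a) / (b - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pa > 0, pb / np.where(pa > 0, pa, 1.0), 0.0)
        vals = np.where(pa > 0, pa * ratio**frac, 0.0)
    return PopulationGrid(grid.region_ids, grid.age_bands, (t,), vals[:, :, None])


def interpolate_years(grid: PopulationGrid, years: Iterable[int]) -> PopulationGrid:
    """Stack :func:`interpolate_population` over several target years."""
    years = sorted({int(y) for y in years})
    vals = np.stack([interpolate_population(grid, y).values[:, :, 0] for y in years], axis=-1)
    return PopulationGrid(grid.region_ids, grid.age_bands, tuple(years), vals)


def build_reference_rates(
    national_counts: EventPanel,
    national_pop: PopulationGrid,
    reference_year: int,
) -> ReferenceRates:
    """National age-specific rates for the reference year.

    Counts are pooled over regions; the standard-population weights default
    to the national female population of the reference year, so the implied
    reference ASR is the national crude rate of that year re-expressed per
    100,000.
    """
    if national_counts.age_bands != national_pop.age_bands:
        raise SchemaError("counts and populations must share age bands")
    key = str(reference_year)
    if key not in national_counts.periods:
        raise SchemaError(f"no counts stored for reference year {reference_year}")
    p = national_counts.periods.index(key)
    counts_a = national_counts.counts[:, :, p].sum(axis=0)  # pool regions
    pop_a = national_pop.national(reference_year)
    if np.any(pop_a <= 0):
        raise InputError("every age band needs a positive national population")
    return ReferenceRates(national_counts.age_bands, counts_a / pop_a, pop_a)


def compute_expected(
    pop: PopulationGrid,
    ref: ReferenceRates,
    period_years: Mapping[str, Iterable[int]],
    drop_years: Iterable[int] = (),
) -> ExpectedCounts:
    """Indirectly standardised expected counts per region x period.

    Populations for the years pooled by each period are interpolated from
    the census grid; ``drop_years`` removes person-years for years with no
    event reporting (e.g. a missing registry year) so E stays comparable
    with the observed counts.
    """
    if tuple(ref.age_bands) != tuple(pop.age_bands):
        raise SchemaError("population grid does not cover the reference age bands")
    if not period_years:
        raise InputError("period_years must be non-empty")
    drop = {int(y) for y in drop_years}
    periods = tuple(period_years)
    need = sorted({int(y) for ys in period_years.values() for y in ys if int(y) not in drop})
    annual = interpolate_years(pop, need)
    e = np.zeros((len(pop.region_ids), len(periods)))
    for k, (per, ys) in enumerate(period_years.items()):
        for y in ys:
            if int(y) in drop:
                continue
            e[:, k] += annual.sel_year(int(y)) @ ref.rates
    return ExpectedCounts(pop.region_ids, periods, e)


def adjust_for_completeness(
    expected: ExpectedCounts, covariates: CovariatePanel, mode: str = "offset"
) -> ExpectedCounts:
    """Fold registry completeness into the expected counts.

    ``offset`` (default) multiplies E by the completeness fraction c so the
    Poisson mean refers to *observed* (under-registered) counts.  ``inflate``
    leaves E untouched — that variant divides the observed counts by c
    upstream instead (see :func:`inflate_counts`); the resulting non-integer
    counts are rejected by the Poisson likelihood, so it exists for
    comparison only.
    """
    if mode not in ("offset", "inflate"):
        raise InputError(f"unknown completeness mode {mode!r}")
    if expected.region_ids != covariates.region_ids or expected.periods != covariates.periods:
        raise SchemaError("expected counts and covariates must share regions and periods")
    if np.any(covariates.completeness <= 0):
        raise InputError("completeness must be positive")
    if mode == "inflate":
        return ExpectedCounts(expected.region_ids, expected.periods, expected.values.copy())
    return ExpectedCounts(
        expected.region_ids, expected.periods, expected.values * covariates.completeness
    )


def inflate_counts(panel: EventPanel, covariates: CovariatePanel) -> EventPanel:
    """Divide observed counts by completeness (the ``inflate`` variant).

    Produces generally non-integer counts, which the Poisson likelihood
    rejects by contract; provided so the two adjustment conventions can be
    compared outside the model.
    """
    if panel.region_ids != covariates.region_ids or panel.periods != covariates.periods:
        raise SchemaError("panel and covariates must share regions and periods")
    c = covariates.completeness[:, None, :]
    return EventPanel(panel.region_ids, panel.age_bands, panel.periods, panel.counts / c)


def asr_from_relative_risk(theta_draws: np.ndarray, ref: ReferenceRates) -> np.ndarray:
    """Scale relative-risk draws into age-standardised rates per 100,000.

    ASR draw = theta draw x reference ASR; monotone in theta.
    """
    theta = np.asarray(theta_draws, dtype=float)
    if np.any(theta < 0):
        raise ContractError("relative risks must be non-negative")
    return theta * ref.reference_asr
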