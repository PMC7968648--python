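"""Synthetic data generation for the disease-mapping pipeline.

Everything downstream — standardisation, the BYM fit, diagnostics and
reporting — is exercised against panels produced here, emulating a
31-region province panel of female breast-cancer events for women aged 30+
over the intervals 2000–2003, 2004–2007 and 2008–2010: censuses in 1996,
2006 and 2011, registry completeness rising linearly from 0.22 to 0.75,
spatially correlated wealth, and counts drawn from the generative BYM model
and then binomially thinned to mimic under-registration.

A single scenario seed fans out into independent per-operation substreams
(`numpy` ``SeedSequence.spawn``), so each stage is individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay

from . import demography
from .containers import (
    AGE_BANDS_30PLUS,
    STUDY_PERIODS,
    AdjacencyGraph,
    CovariatePanel,
    EventPanel,
    ExpectedCounts,
    PopulationGrid,
    ReferenceRates,
    TruthRecord,
)
from .exceptions import InputError, SchemaError
from .model import design_matrix

__all__ = [
    "build_lattice",
    "simulate_populations",
    "simulate_covariates",
    "simulate_truth",
    "age_rate_template",
    "simulate_counts",
    "thin_counts",
    "Scenario",
    "simulate_scenario",
]


def _region_ids(n: int) -> tuple[str, ...]:
    width = max(2, len(str(n - 1)))
    return tuple(f"R{i:0{width}d}" for i in range(n))


# ---------------------------------------------------------------------------
# Lattices
# ---------------------------------------------------------------------------


def build_lattice(n_regions: int, topology: str = "grid", seed: int = 0) -> AdjacencyGraph:
    """Build a connected synthetic region lattice.

    ``grid`` packs regions row-major into a near-square rectangle with rook
    (edge-sharing) adjacency; ``ring`` is a cycle; ``random-planar``
    triangulates uniform random points (Delaunay), which is planar and
    connected by construction.
    """
    if n_regions < 1:
        raise InputError("n_regions must be positive")
    ids = _region_ids(n_regions)
    g = nx.Graph()
    g.add_nodes_from(range(n_regions))
    if topology == "grid":
        cols = int(np.ceil(np.sqrt(n_regions)))
        for i in range(n_regions):
            r, c = divmod(i, cols)
            if c + 1 < cols and i + 1 < n_regions:
                g.add_edge(i, i + 1)
            if i + cols < n_regions:
                g.add_edge(i, i + cols)
    elif topology == "ring":
        if n_regions == 2:
            g.add_edge(0, 1)
        elif n_regions > 2:
            g.add_edges_from((i, (i + 1) % n_regions) for i in range(n_regions))
    elif topology == "random-planar":
        rng = np.random.default_rng(seed)
        if n_regions == 2:
            g.add_edge(0, 1)
        elif n_regions >= 3:
            pts = rng.uniform(size=(n_regions, 2))
            tri = Delaunay(pts)
            for simplex in tri.simplices:
                for a in range(3):
                    g.add_edge(int(simplex[a]), int(simplex[(a + 1) % 3]))
    else:
        raise InputError(f"unknown topology {topology!r}")
    if n_regions > 1 and not nx.is_connected(g):
        raise InputError("generated lattice is unexpectedly disconnected")
    relabel = {i: ids[i] for i in range(n_regions)}
    return AdjacencyGraph.from_networkx(nx.relabel_nodes(g, relabel), ids)


# ---------------------------------------------------------------------------
# Populations and covariates
# ---------------------------------------------------------------------------

#: declining 5-year age-band shares for women 30+ (normalised at use)
_AGE_TEMPLATE_DECAY = 0.25


def simulate_populations(
    graph: AdjacencyGraph,
    census_years: Sequence[int] = (1996, 2006, 2011),
    base_size: float = 300_000.0,
    growth_range: tuple[float, float] = (0.005, 0.025),
    age_bands: Sequence[str] = AGE_BANDS_30PLUS,
    seed: int = 0,
) -> PopulationGrid:
    """Female populations at census years only.

    Each region starts at ``base_size`` women 30+ at the first census,
    spread over the age bands by a Dirichlet perturbation of a declining
    age template, and grows geometrically at a region-specific annual rate
    drawn uniformly from ``growth_range`` (so totals diverge across regions
    at later censuses whenever the range is non-degenerate).
    """
    years = tuple(sorted(int(y) for y in census_years))
    if len(years) < 2:
        raise InputError("at least two census years are required")
    if base_size <= 0:
        raise InputError("base_size must be positive")
    rng = np.random.default_rng(seed)
    bands = tuple(age_bands)
    template = np.exp(-_AGE_TEMPLATE_DECAY * np.arange(len(bands)))
    template /= template.sum()
    R = graph.n_regions
    shares = rng.dirichlet(template * 300.0, size=R)  # (R, A), mild regional variation
    growth = rng.uniform(growth_range[0], growth_range[1], size=R)
    vals = np.empty((R, len(bands), len(years)))
    for k, y in enumerate(years):
        factor = (1.0 + growth) ** (y - years[0])
        vals[:, :, k] = base_size * shares * factor[:, None]
    return PopulationGrid(graph.region_ids, bands, years, vals)


def simulate_covariates(
    graph: AdjacencyGraph,
    periods: Sequence[str] = tuple(STUDY_PERIODS),
    completeness_endpoints: tuple[float, float] = (0.22, 0.75),
    wealth_smoothing: float = 0.7,
    seed: int = 0,
) -> CovariatePanel:
    """Region x period covariates with a spatially smoothed wealth index.

    Completeness interpolates linearly over periods between the two
    endpoints (identical across regions, as for a national registry).  The
    wealth index is a standard-normal draw shrunk towards the neighbour
    mean with weight ``wealth_smoothing`` so quintiles form contiguous-ish
    blocks; urbanisation and schooling are built around the wealth index
    (richer regions more urban and more schooled) with an upward time
    trend.
    """
    c0, c1 = completeness_endpoints
    if not (0 < c0 <= 1 and 0 < c1 <= 1):
        raise InputError("completeness endpoints must lie in (0, 1]")
    periods = tuple(str(p) for p in periods)
    P, R = len(periods), graph.n_regions
    rng = np.random.default_rng(seed)

    frac = np.linspace(0.0, 1.0, P) if P > 1 else np.zeros(1)
    completeness = np.tile(c0 + (c1 - c0) * frac, (R, 1))

    z = rng.normal(size=R)
    w = graph.adjacency_matrix(row_standardised=True)
    nbr_mean = w @ z
    nbr_mean[graph.degrees == 0] = z[graph.degrees == 0]  # isolated: keep own draw
    wealth = (1.0 - wealth_smoothing) * z + wealth_smoothing * nbr_mean

    urb_base = np.clip(0.55 + 0.18 * wealth + rng.normal(0.0, 0.08, R), 0.05, 0.95)
    urbanisation = np.clip(urb_base[:, None] + 0.025 * np.arange(P), 0.0, 1.0)
    yos_base = np.maximum(0.5, 5.5 + 1.2 * wealth + rng.normal(0.0, 0.8, R))
    yos = yos_base[:, None] + 0.6 * np.arange(P)

    return CovariatePanel(
        graph.region_ids, periods, completeness, urbanisation, yos, wealth
    )


# ---------------------------------------------------------------------------
# Truth and counts
# ---------------------------------------------------------------------------


def simulate_truth(
    graph: AdjacencyGraph,
    alpha: float = 0.0,
    beta: Sequence[float] = (0.5, -0.3),
    covariate_names: Sequence[str] = ("urbanisation", "yos"),
    sigma_u: float = 0.4,
    sigma_v: float = 0.15,
    seed: int = 0,
) -> TruthRecord:
    """Draw generating BYM parameters.

    The spatial field is sampled from the intrinsic CAR distribution
    restricted to its proper subspace (eigenvectors of the graph Laplacian
    with positive eigenvalue), then rescaled so its empirical sd equals
    ``sigma_u``; the unstructured field is iid Normal(0, sigma_v^2),
    recentred.  Recorded precisions are ``1/sigma^2``.
    """
    if sigma_u <= 0 or sigma_v <= 0:
        raise InputError("sigma_u and sigma_v must be positive")
    rng = np.random.default_rng(seed)
    R = graph.n_regions
    lap = np.diag(graph.degrees) - graph.adjacency_matrix()
    evals, evecs = np.linalg.eigh(lap)
    pos = evals > 1e-10
    if pos.any():
        z = rng.normal(size=pos.sum())
        u = evecs[:, pos] @ (z / np.sqrt(evals[pos]))
        sd = u.std()
        u = u * (sigma_u / sd) if sd > 0 else u
    else:
        u = np.zeros(R)
    comp = graph.component_labels
    for k in range(graph.n_components):
        sel = comp == k
        u[sel] -= u[sel].mean()
    v = rng.normal(0.0, sigma_v, R)
    v -= v.mean()
    return TruthRecord(
        alpha=alpha,
        beta=np.asarray(beta, dtype=float),
        covariate_names=tuple(covariate_names),
        u=u,
        v=v,
        tau_u=1.0 / sigma_u**2,
        tau_v=1.0 / sigma_v**2,
    )


def age_rate_template(
    age_bands: Sequence[str] = AGE_BANDS_30PLUS, peak_rate: float = 1.0e-3
) -> np.ndarray:
    """Deterministic age-specific rate curve (events per person-year).

    Rates rise from age 30, peak around the 60s and plateau — the shape of
    female breast-cancer incidence — with ``peak_rate`` setting the scale.
    """
    a = np.arange(len(age_bands))
    shape = np.minimum(a + 1.0, 7.0) / 7.0
    return peak_rate * shape


def simulate_counts(
    expected: ExpectedCounts,
    covariates: CovariatePanel,
    truth: TruthRecord,
    graph: AdjacencyGraph,
    seed: int = 0,
) -> EventPanel:
    """Draw true counts from the generative BYM model.

    ``O[i, p] ~ Poisson(E[i, p] * exp(alpha + x'beta + u_i + v_i))`` with
    the covariates standardised exactly as the model standardises them, so
    ``truth.beta`` lives on the same scale the sampler estimates.
    """
    e = expected.values
    if np.any(e < 0):
        raise InputError("expected counts must be non-negative")
    if truth.u.shape != (graph.n_regions,):
        raise SchemaError("truth dimensions do not match the graph")
    if expected.region_ids != covariates.region_ids or expected.periods != covariates.periods:
        raise SchemaError("expected counts and covariates must share regions and periods")
    x, _, _ = design_matrix(covariates, truth.covariate_names)
    eta = truth.alpha + x @ truth.beta + (truth.u + truth.v)[:, None]
    rng = np.random.default_rng(seed)
    counts = rng.poisson(e * np.exp(eta)).astype(float)
    return EventPanel(
        expected.region_ids, ("all",), expected.periods, counts[:, None, :]
    )


def thin_counts(panel: EventPanel, covariates: CovariatePanel, seed: int = 0) -> EventPanel:
    """Binomial under-registration: each count is thinned with the
    completeness fraction as retention probability."""
    if panel.region_ids != covariates.region_ids or panel.periods != covariates.periods:
        raise SchemaError("panel and covariates must share regions and periods")
    c = covariates.completeness
    if np.any(c <= 0) or np.any(c > 1):
        raise InputError("completeness must lie in (0, 1]")
    if not panel.is_integer:
        raise InputError("thinning requires integer counts")
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(
        panel.counts.astype(int), np.broadcast_to(c[:, None, :], panel.counts.shape)
    ).astype(float)
    return EventPanel(panel.region_ids, panel.age_bands, panel.periods, thinned)


# ---------------------------------------------------------------------------
# Whole scenarios
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A complete synthetic study: inputs, truth and both count panels."""

    graph: AdjacencyGraph
    populations: PopulationGrid  # census years
    covariates: CovariatePanel
    reference: ReferenceRates
    national_counts: EventPanel  # age-specific, reference year, for rebuilding rates
    truth: TruthRecord
    expected: ExpectedCounts  # unadjusted E (full registration)
    counts_true: EventPanel
    counts_observed: EventPanel  # after binomial thinning
    period_years: dict[str, tuple[int, ...]]
    reference_year: int

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.graph.to_edge_frame().to_csv(out / "adjacency.csv", index=False)
        self.populations.to_frame().to_csv(out / "population.csv", index=False)
        self.covariates.to_frame().to_csv(out / "covariates.csv", index=False)
        self.national_counts.to_frame().to_csv(out / "national_counts.csv", index=False)
        self.counts_true.to_frame().to_csv(out / "counts_true.csv", index=False)
        self.counts_observed.to_frame().to_csv(out / "counts_observed.csv", index=False)
        self.expected.to_frame().to_csv(out / "expected_full.csv", index=False)
        (out / "reference_rates.json").write_text(self.reference.to_json())
        (out / "truth.json").write_text(self.truth.to_json())
        import json

        meta = {
            "region_ids": list(self.graph.region_ids),
            "period_years": {k: list(v) for k, v in self.period_years.items()},
            "reference_year": self.reference_year,
        }
        (out / "scenario.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, indir: str | Path) -> "Scenario":
        import json

        import pandas as pd

        d = Path(indir)
        meta = json.loads((d / "scenario.json").read_text())
        regions = tuple(meta["region_ids"])
        graph = AdjacencyGraph.from_edge_frame(pd.read_csv(d / "adjacency.csv"), regions)
        return cls(
            graph=graph,
            populations=PopulationGrid.from_frame(pd.read_csv(d / "population.csv")),
            covariates=CovariatePanel.from_frame(pd.read_csv(d / "covariates.csv")),
            reference=ReferenceRates.from_json((d / "reference_rates.json").read_text()),
            national_counts=EventPanel.from_frame(pd.read_csv(d / "national_counts.csv")),
            truth=TruthRecord.from_json((d / "truth.json").read_text()),
            expected=ExpectedCounts.from_frame(pd.read_csv(d / "expected_full.csv")),
            counts_true=EventPanel.from_frame(pd.read_csv(d / "counts_true.csv")),
            counts_observed=EventPanel.from_frame(pd.read_csv(d / "counts_observed.csv")),
            period_years={k: tuple(v) for k, v in meta["period_years"].items()},
            reference_year=meta["reference_year"],
        )


def simulate_scenario(
    seed: int = 0,
    n_regions: int = 31,
    topology: str = "grid",
    periods: Mapping[str, Iterable[int]] | None = None,
    census_years: Sequence[int] = (1996, 2006, 2011),
    reference_year: int = 2010,
    completeness_endpoints: tuple[float, float] = (0.22, 0.75),
    base_size: float = 300_000.0,
    alpha: float = 0.0,
    beta: Sequence[float] = (0.5, -0.3),
    sigma_u: float = 0.4,
    sigma_v: float = 0.15,
    drop_years: Iterable[int] = (),
) -> Scenario:
    """Generate a full synthetic study at the study's own dimensions.

    Defaults mirror the emulated panel: 31 regions, 11 five-year age bands
    from 30–34 to 80+, three reporting intervals pooling 4, 4 and 3
    calendar years, censuses in 1996/2006/2011, registry completeness
    rising from 0.22 to 0.75, and covariate effects beta = (0.5, -0.3) on
    standardised urbanisation and schooling.  ``drop_years`` removes
    reporting years (e.g. ``(2006,)`` emulates the missing incidence year).
    """
    if periods is None:
        periods = {k: v for k, v in STUDY_PERIODS.items()}
    period_years = {str(k): tuple(int(y) for y in v) for k, v in periods.items()}

    ss = np.random.SeedSequence(seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    graph = build_lattice(n_regions, topology, seed=sub[0])
    pop = simulate_populations(
        graph, census_years=census_years, base_size=base_size, seed=sub[1]
    )
    cov = simulate_covariates(
        graph,
        periods=tuple(period_years),
        completeness_endpoints=completeness_endpoints,
        seed=sub[2],
    )

    # national age-specific counts in the reference year -> reference rates
    rates = age_rate_template(pop.age_bands)
    nat_pop_a = demography.interpolate_population(pop, reference_year)
    rng = np.random.default_rng(sub[3])
    nat_counts_a = rng.poisson(rates * nat_pop_a.values[:, :, 0])
    national_counts = EventPanel(
        graph.region_ids, pop.age_bands, (str(reference_year),), nat_counts_a[:, :, None].astype(float)
    )
    reference = demography.build_reference_rates(national_counts, nat_pop_a, reference_year)

    expected = demography.compute_expected(pop, reference, period_years, drop_years=drop_years)
    truth = simulate_truth(
        graph, alpha=alpha, beta=beta, sigma_u=sigma_u, sigma_v=sigma_v, seed=sub[4]
    )
    counts_true = simulate_counts(expected, cov, truth, graph, seed=sub[5])
    counts_observed = thin_counts(counts_true, cov, seed=sub[5] + 1)

    return Scenario(
        graph=graph,
        populations=pop,
        covariates=cov,
        reference=reference,
        national_counts=national_counts,
        truth=truth,
        expected=expected,
        counts_true=counts_true,
        counts_observed=counts_observed,
        period_years=period_years,
        reference_year=reference_year,
    )
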