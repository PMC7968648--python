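"""Core data containers for small-area disease mapping.

The containers are thin, validated wrappers around labelled numpy arrays:

* :class:`AdjacencyGraph` — symmetric region neighbourhood structure used by
  the intrinsic CAR prior and by Moran's I;
* :class:`PopulationGrid` — female population by region x age-band x year;
* :class:`EventPanel` — observed event counts by region x age-band x period;
* :class:`CovariatePanel` — region x period covariates (registry
  completeness, urbanisation, mean years of schooling) plus a per-region
  wealth index;
* :class:`ReferenceRates` — national age-specific reference rates and the
  standard-population weights that define the reference ASR;
* :class:`ExpectedCounts` — expected events from indirect standardisation;
* :class:`TruthRecord` — generating parameters of a synthetic scenario.

All containers serialise to tidy ``pandas`` frames (one row per cell) or to
plain JSON so every pipeline stage can be driven from flat files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InputError, SchemaError

#: 5-year age bands for women aged 30 and above (open-ended top band).
AGE_BANDS_30PLUS: tuple[str, ...] = (
    "30-34", "35-39", "40-44", "45-49", "50-54", "55-59",
    "60-64", "65-69", "70-74", "75-79", "80+",
)

#: The three study intervals and the calendar years they pool.
STUDY_PERIODS: dict[str, tuple[int, ...]] = {
    "2000-2003": (2000, 2001, 2002, 2003),
    "2004-2007": (2004, 2005, 2006, 2007),
    "2008-2010": (2008, 2009, 2010),
}


def _as_tuple(x: Iterable) -> tuple:
    return tuple(x)


# ---------------------------------------------------------------------------
# Adjacency structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbourhood structure over a fixed, ordered set of regions.

    Invariants (checked at construction): neighbour sets are symmetric,
    contain no self-loops, and only reference known regions; region ids are
    unique.
    """

    region_ids: tuple[str, ...]
    neighbours: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        ids = self.region_ids
        if len(set(ids)) != len(ids):
            raise InputError("region_ids must be unique")
        nbrs = {r: frozenset(self.neighbours.get(r, frozenset())) for r in ids}
        known = set(ids)
        for r, ns in nbrs.items():
            if r in ns:
                raise InputError(f"self-loop at region {r!r}")
            unknown = ns - known
            if unknown:
                raise SchemaError(f"unknown neighbours of {r!r}: {sorted(unknown)}")
            for j in ns:
                if r not in nbrs[j]:
                    raise InputError(f"asymmetric adjacency: {r!r} -> {j!r}")
        object.__setattr__(self, "region_ids", _as_tuple(ids))
        object.__setattr__(self, "neighbours", nbrs)

    # -- basic geometry ----------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @cached_property
    def index_of(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.region_ids)}

    @cached_property
    def edges(self) -> np.ndarray:
        """Unordered edges as an (m, 2) array of region indices, i < j."""
        idx = self.index_of
        out = sorted(
            (min(idx[a], idx[b]), max(idx[a], idx[b]))
            for a in self.region_ids
            for b in self.neighbours[a]
            if idx[a] < idx[b]
        )
        return np.asarray(out, dtype=int).reshape(-1, 2)

    @cached_property
    def degrees(self) -> np.ndarray:
        return np.array([len(self.neighbours[r]) for r in self.region_ids], dtype=float)

    @cached_property
    def component_labels(self) -> np.ndarray:
        """Connected-component label per region (0-based, arbitrary order)."""
        g = self.to_networkx()
        labels = np.empty(self.n_regions, dtype=int)
        for k, comp in enumerate(nx.connected_components(g)):
            for r in comp:
                labels[self.index_of[r]] = k
        return labels

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n_regions else 0

    def adjacency_matrix(self, row_standardised: bool = False) -> np.ndarray:
        """Dense 0/1 (or row-standardised) weight matrix in region order."""
        n = self.n_regions
        w = np.zeros((n, n))
        if len(self.edges):
            w[self.edges[:, 0], self.edges[:, 1]] = 1.0
            w[self.edges[:, 1], self.edges[:, 0]] = 1.0
        if row_standardised:
            rs = w.sum(axis=1, keepdims=True)
            np.divide(w, rs, out=w, where=rs > 0)
        return w

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        for a in self.region_ids:
            for b in self.neighbours[a]:
                g.add_edge(a, b)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, region_ids: Sequence[str] | None = None) -> "AdjacencyGraph":
        ids = tuple(region_ids) if region_ids is not None else tuple(g.nodes())
        nbrs = {r: frozenset(g.neighbors(r)) for r in ids}
        return cls(ids, nbrs)

    def to_edge_frame(self) -> pd.DataFrame:
        ids = self.region_ids
        rows = [(ids[i], ids[j]) for i, j in self.edges]
        return pd.DataFrame(rows, columns=["region_a", "region_b"])

    @classmethod
    def from_edge_frame(cls, frame: pd.DataFrame, region_ids: Sequence[str]) -> "AdjacencyGraph":
        g = nx.Graph()
        g.add_nodes_from(region_ids)
        g.add_edges_from(frame[["region_a", "region_b"]].itertuples(index=False))
        return cls.from_networkx(g, region_ids)


# ---------------------------------------------------------------------------
# Population / counts / covariates panels
# ---------------------------------------------------------------------------


def _check_axis(name: str, labels: Sequence) -> tuple:
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise SchemaError(f"duplicate labels on axis {name!r}")
    if not labels:
        raise SchemaError(f"empty axis {name!r}")
    return labels


@dataclass
class PopulationGrid:
    """Female population (persons) indexed region x age-band x year."""

    region_ids: tuple[str, ...]
    age_bands: tuple[str, ...]
    years: tuple[int, ...]
    values: np.ndarray  # (R, A, Y), persons >= 0

    def __post_init__(self) -> None:
        self.region_ids = _check_axis("region", self.region_ids)
        self.age_bands = _check_axis("age_band", self.age_bands)
        self.years = tuple(int(y) for y in _check_axis("year", self.years))
        if list(self.years) != sorted(self.years):
            raise SchemaError("years must be strictly increasing")
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.region_ids), len(self.age_bands), len(self.years))
        if self.values.shape != expect:
            raise SchemaError(f"values shape {self.values.shape} != {expect}")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise InputError("populations must be finite and non-negative")

    def sel_year(self, year: int) -> np.ndarray:
        """(R, A) slice at a stored year."""
        try:
            k = self.years.index(int(year))
        except ValueError:
            raise SchemaError(f"year {year} not stored (have {self.years})") from None
        return self.values[:, :, k]

    def region_totals(self, year: int) -> np.ndarray:
        return self.sel_year(year).sum(axis=1)

    def national(self, year: int) -> np.ndarray:
        """Age-specific national population: sum over regions at ``year``."""
        return self.sel_year(year).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        r, a, y = np.meshgrid(
            np.arange(len(self.region_ids)),
            np.arange(len(self.age_bands)),
            np.arange(len(self.years)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "region": np.asarray(self.region_ids)[r.ravel()],
                "age_band": np.asarray(self.age_bands)[a.ravel()],
                "year": np.asarray(self.years)[y.ravel()],
                "population": self.values.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationGrid":
        regions = tuple(pd.unique(frame["region"]))
        bands = tuple(pd.unique(frame["age_band"]))
        years = tuple(sorted(int(y) for y in pd.unique(frame["year"])))
        pivot = frame.set_index(["region", "age_band", "year"])["population"]
        values = np.empty((len(regions), len(bands), len(years)))
        for i, r in enumerate(regions):
            for j, a in enumerate(bands):
                for k, y in enumerate(years):
                    values[i, j, k] = pivot[(r, a, y)]
        return cls(regions, bands, years, values)


@dataclass
class EventPanel:
    """Observed (or simulated) event counts by region x age-band x period.

    ``age_bands`` may be the single pseudo-band ``("all",)`` when counts have
    already been pooled over ages, which is how the spatial model consumes
    them.
    """

    region_ids: tuple[str, ...]
    age_bands: tuple[str, ...]
    periods: tuple[str, ...]
    counts: np.ndarray  # (R, A, P)

    def __post_init__(self) -> None:
        self.region_ids = _check_axis("region", self.region_ids)
        self.age_bands = _check_axis("age_band", self.age_bands)
        self.periods = tuple(str(p) for p in _check_axis("period", self.periods))
        self.counts = np.asarray(self.counts, dtype=float)
        expect = (len(self.region_ids), len(self.age_bands), len(self.periods))
        if self.counts.shape != expect:
            raise SchemaError(f"counts shape {self.counts.shape} != {expect}")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise InputError("counts must be finite and non-negative")

    @property
    def is_integer(self) -> bool:
        return bool(np.allclose(self.counts, np.round(self.counts)))

    def totals(self) -> np.ndarray:
        """(R, P) counts pooled over age bands."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        r, a, p = np.meshgrid(
            np.arange(len(self.region_ids)),
            np.arange(len(self.age_bands)),
            np.arange(len(self.periods)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "region": np.asarray(self.region_ids)[r.ravel()],
                "age_band": np.asarray(self.age_bands)[a.ravel()],
                "period": np.asarray(self.periods)[p.ravel()],
                "count": self.counts.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventPanel":
        regions = tuple(pd.unique(frame["region"]))
        bands = tuple(pd.unique(frame["age_band"]))
        periods = tuple(pd.unique(frame["period"].astype(str)))
        pivot = frame.assign(period=frame["period"].astype(str)).set_index(
            ["region", "age_band", "period"]
        )["count"]
        counts = np.empty((len(regions), len(bands), len(periods)))
        for i, r in enumerate(regions):
            for j, a in enumerate(bands):
                for k, p in enumerate(periods):
                    counts[i, j, k] = pivot[(r, a, p)]
        return cls(regions, bands, periods, counts)


@dataclass
class CovariatePanel:
    """Region x period covariates plus the per-region wealth index.

    ``completeness`` is the fraction of true events captured by the registry
    (0 < c <= 1); ``urbanisation`` the fraction of women living in urban
    areas; ``yos`` the mean years of schooling; ``wealth_index`` a unitless
    asset-based score used only for stratification, never as a regression
    column.
    """

    region_ids: tuple[str, ...]
    periods: tuple[str, ...]
    completeness: np.ndarray  # (R, P) in (0, 1]
    urbanisation: np.ndarray  # (R, P) in [0, 1]
    yos: np.ndarray  # (R, P) >= 0 years
    wealth_index: np.ndarray  # (R,)

    def __post_init__(self) -> None:
        self.region_ids = _check_axis("region", self.region_ids)
        self.periods = tuple(str(p) for p in _check_axis("period", self.periods))
        shape = (len(self.region_ids), len(self.periods))
        for name in ("completeness", "urbanisation", "yos"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise SchemaError(f"{name} shape {arr.shape} != {shape}")
            setattr(self, name, arr)
        self.wealth_index = np.asarray(self.wealth_index, dtype=float)
        if self.wealth_index.shape != (len(self.region_ids),):
            raise SchemaError("wealth_index must have one value per region")
        if np.any(self.completeness <= 0) or np.any(self.completeness > 1):
            raise InputError("completeness must lie in (0, 1]")
        if np.any(self.urbanisation < 0) or np.any(self.urbanisation > 1):
            raise InputError("urbanisation must lie in [0, 1]")
        if np.any(self.yos < 0):
            raise InputError("years of schooling must be non-negative")
        if not np.all(np.isfinite(self.wealth_index)):
            raise InputError("wealth index must be finite")

    def to_frame(self) -> pd.DataFrame:
        r, p = np.meshgrid(
            np.arange(len(self.region_ids)), np.arange(len(self.periods)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "region": np.asarray(self.region_ids)[r.ravel()],
                "period": np.asarray(self.periods)[p.ravel()],
                "completeness": self.completeness.ravel(),
                "urbanisation": self.urbanisation.ravel(),
                "yos": self.yos.ravel(),
                "wealth_index": self.wealth_index[r.ravel()],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CovariatePanel":
        regions = tuple(pd.unique(frame["region"]))
        periods = tuple(pd.unique(frame["period"].astype(str)))
        frame = frame.assign(period=frame["period"].astype(str))
        pivot = frame.set_index(["region", "period"])
        shape = (len(regions), len(periods))
        arrs = {k: np.empty(shape) for k in ("completeness", "urbanisation", "yos")}
        wealth = np.empty(len(regions))
        for i, r in enumerate(regions):
            for k, p in enumerate(periods):
                row = pivot.loc[(r, p)]
                for name in arrs:
                    arrs[name][i, k] = row[name]
            wealth[i] = pivot.loc[(r, periods[0])]["wealth_index"]
        return cls(regions, periods, wealth_index=wealth, **arrs)


@dataclass
class ReferenceRates:
    """National age-specific reference rates and standard-population weights.

    ``rates`` are events per person-year per age band; ``standard_weights``
    are the standard population (persons) per band.  The implied reference
    age-standardised rate (per 100,000) is the weight-averaged rate.
    """

    age_bands: tuple[str, ...]
    rates: np.ndarray  # (A,) events / person-year
    standard_weights: np.ndarray  # (A,) persons

    def __post_init__(self) -> None:
        self.age_bands = _check_axis("age_band", self.age_bands)
        self.rates = np.asarray(self.rates, dtype=float)
        self.standard_weights = np.asarray(self.standard_weights, dtype=float)
        a = len(self.age_bands)
        if self.rates.shape != (a,) or self.standard_weights.shape != (a,):
            raise SchemaError("rates/weights must have one value per age band")
        if np.any(self.rates < 0):
            raise InputError("rates must be non-negative")
        if np.any(self.standard_weights <= 0):
            raise InputError("standard weights must be positive")

    @property
    def reference_asr(self) -> float:
        """Standardised rate per 100,000 implied by rates and weights."""
        w = self.standard_weights
        return float(1e5 * np.sum(self.rates * w) / np.sum(w))

    def to_json(self) -> str:
        return json.dumps(
            {
                "age_bands": list(self.age_bands),
                "rates": self.rates.tolist(),
                "standard_weights": self.standard_weights.tolist(),
                "reference_asr": self.reference_asr,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceRates":
        d = json.loads(text)
        return cls(tuple(d["age_bands"]), np.array(d["rates"]), np.array(d["standard_weights"]))


@dataclass
class ExpectedCounts:
    """Expected events per region x period from indirect standardisation."""

    region_ids: tuple[str, ...]
    periods: tuple[str, ...]
    values: np.ndarray  # (R, P) person-events >= 0

    def __post_init__(self) -> None:
        self.region_ids = _check_axis("region", self.region_ids)
        self.periods = tuple(str(p) for p in _check_axis("period", self.periods))
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.region_ids), len(self.periods))
        if self.values.shape != expect:
            raise SchemaError(f"values shape {self.values.shape} != {expect}")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise InputError("expected counts must be finite and non-negative")

    def to_frame(self) -> pd.DataFrame:
        r, p = np.meshgrid(
            np.arange(len(self.region_ids)), np.arange(len(self.periods)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "region": np.asarray(self.region_ids)[r.ravel()],
                "period": np.asarray(self.periods)[p.ravel()],
                "expected": self.values.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpectedCounts":
        regions = tuple(pd.unique(frame["region"]))
        periods = tuple(pd.unique(frame["period"].astype(str)))
        pivot = frame.assign(period=frame["period"].astype(str)).set_index(
            ["region", "period"]
        )["expected"]
        values = np.empty((len(regions), len(periods)))
        for i, r in enumerate(regions):
            for k, p in enumerate(periods):
                values[i, k] = pivot[(r, p)]
        return cls(regions, periods, values)


@dataclass
class TruthRecord:
    """Generating parameters of a synthetic scenario (log-linear scale).

    ``beta`` applies to covariates standardised to mean 0 / sd 1 within the
    panel; ``u`` is the spatially structured effect (mean zero within each
    graph component), ``v`` the unstructured effect; ``tau_u``/``tau_v`` the
    corresponding precisions.
    """

    alpha: float
    beta: np.ndarray
    covariate_names: tuple[str, ...]
    u: np.ndarray
    v: np.ndarray
    tau_u: float
    tau_v: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.covariate_names = tuple(self.covariate_names)
        if self.beta.shape != (len(self.covariate_names),):
            raise SchemaError("beta must have one coefficient per covariate name")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise SchemaError("u and v must have the same length")
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise InputError("precisions must be positive")

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "beta": self.beta.tolist(),
                "covariate_names": list(self.covariate_names),
                "u": self.u.tolist(),
                "v": self.v.tolist(),
                "tau_u": self.tau_u,
                "tau_v": self.tau_v,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(
            d["alpha"], np.array(d["beta"]), tuple(d["covariate_names"]),
            np.array(d["u"]), np.array(d["v"]), d["tau_u"], d["tau_v"],
        )
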