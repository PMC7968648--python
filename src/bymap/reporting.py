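"""Posterior summaries, percentage changes, wealth-quintile stratification
and region rankings.

Summaries follow the 2.5th/97.5th-percentile credible-interval convention,
percentiles computed by linear interpolation between order statistics
(numpy's default rule).  Percentage change between two intervals is
computed draw-wise by default — the ratio is formed per posterior draw and
then summarised — which is what makes the reported change intervals
asymmetric around the ratio of the point estimates; ``point`` mode applies
the same formula to two point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = [
    "RateSummary",
    "summarize_draws",
    "percent_change",
    "assign_quintiles",
    "quintile_summary",
    "rank_regions",
]

QUINTILE_LABELS = ("Q1", "Q2", "Q3", "Q4", "Q5")


@dataclass(frozen=True)
class RateSummary:
    """Posterior mean with a 95% credible interval (2.5th–97.5th pct)."""

    mean: float
    lo: float
    hi: float
    region: str | None = None
    period: str | None = None


def summarize_draws(
    draws: np.ndarray, region: str | None = None, period: str | None = None
) -> RateSummary:
    """Mean and 95% credible interval of a per-draw quantity."""
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size < 2:
        raise InputError("need at least 2 draws to summarise")
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return RateSummary(
        mean=float(arr.mean()), lo=float(lo), hi=float(hi), region=region, period=period
    )


def percent_change(r1, r2, mode: str = "per-draw"):
    """Percentage change ``100 * (r2 - r1) / r1`` between two intervals.

    ``per-draw``: both arguments are equal-length draw vectors; the change
    is formed draw-wise and summarised (mean + 95% CrI), returning a
    :class:`RateSummary`.  ``point``: both arguments are point estimates and
    a plain float is returned.
    """
    if mode == "point":
        r1 = float(np.asarray(r1))
        r2 = float(np.asarray(r2))
        if r1 <= 0:
            raise InputError("percentage change undefined for a non-positive baseline")
        return 100.0 * (r2 - r1) / r1
    if mode != "per-draw":
        raise InputError(f"unknown mode {mode!r}")
    a = np.asarray(r1, dtype=float).ravel()
    b = np.asarray(r2, dtype=float).ravel()
    if a.size != b.size:
        raise InputError("per-draw change needs equal draw counts")
    if np.any(a <= 0):
        raise InputError("percentage change undefined: non-positive baseline draw")
    return summarize_draws(100.0 * (b - a) / a)


def assign_quintiles(wealth_index: Mapping[str, float] | pd.Series) -> dict[str, str]:
    """Split regions into wealth quintiles Q1 (poorest) … Q5 (wealthiest).

    Regions are sorted ascending by wealth index (ties broken by region
    identifier, so assignment is deterministic) and cut into 5 contiguous
    groups; when n is not divisible by 5 the extra regions go to the
    poorest quintiles first, e.g. n=31 gives sizes (7, 6, 6, 6, 6).
    """
    items = sorted(dict(wealth_index).items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    if n < 5:
        raise InputError("need at least 5 regions to form quintiles")
    if any(not np.isfinite(v) for _, v in items):
        raise InputError("wealth index must be finite")
    base, rem = divmod(n, 5)
    sizes = [base + (1 if q < rem else 0) for q in range(5)]
    out: dict[str, str] = {}
    pos = 0
    for label, size in zip(QUINTILE_LABELS, sizes):
        for r, _ in items[pos : pos + size]:
            out[r] = label
        pos += size
    return out

def quintile_summary(
    rate_draws: Mapping[str, np.ndarray],
    quintiles: Mapping[str, str],
    weighting: str = "unweighted",
    populations: Mapping[str, float] | None = None,
) -> dict[str, RateSummary]:
    """Per-quintile rate summaries from per-region draw vectors.

    Per posterior draw, a quintile's rate is the (un)weighted mean of its
    member regions' rates; the draw vector of each quintile is then
    summarised as mean + 95% CrI.  ``population`` weighting requires a
    per-region weight mapping.
    """
    if weighting not in ("unweighted", "population"):
        raise InputError(f"unknown weighting {weighting!r}")
    if weighting == "population" and populations is None:
        raise InputError("population weighting needs per-region populations")
    members: dict[str, list[str]] = {q: [] for q in QUINTILE_LABELS}
    for r in rate_draws:
        if r not in quintiles:
            raise InputError(f"region {r!r} has no quintile assignment")
        members[quintiles[r]].append(r)
    out: dict[str, RateSummary] = {}
    for q, regs in members.items():
        if not regs:
            raise InputError(f"empty quintile {q}")
        mat = np.stack([np.asarray(rate_draws[r], dtype=float).ravel() for r in regs])
        if weighting == "population":
            w = np.array([populations[r] for r in regs], dtype=float)
            pooled = (w[:, None] * mat).sum(axis=0) / w.sum()
        else:
            pooled = mat.mean(axis=0)
        out[q] = summarize_draws(pooled, region=q)
    return out


def rank_regions(
    summaries: pd.DataFrame, period_first: str, period_last: str
) -> pd.DataFrame:
    """Rank regions by descending mean rate in two periods.

    ``summaries`` needs columns ``region``, ``period``, ``mean``.  Ranks
    are dense (ties share a rank); ``display_rank`` breaks ties by region
    id so it is always a permutation of 1..n.  ``delta`` is
    ``rank(first) - rank(last)``: positive means the region moved up the
    table over time.
    """
    out = {}
    for which, per in (("first", period_first), ("last", period_last)):
        sub = summaries[summaries["period"].astype(str) == str(per)]
        if sub.empty:
            raise InputError(f"no summaries for period {per!r}")
        sub = sub.set_index("region")["mean"]
        dense = sub.rank(method="dense", ascending=False).astype(int)
        order = sorted(sub.index, key=lambda r: (-sub[r], r))
        display = pd.Series({r: k + 1 for k, r in enumerate(order)})
        out[which] = (dense, display)
    regions = sorted(out["first"][0].index)
    frame = pd.DataFrame(
        {
            "region": regions,
            "rank_first": [out["first"][0][r] for r in regions],
            "rank_last": [out["last"][0][r] for r in regions],
            "display_rank_first": [out["first"][1][r] for r in regions],
            "display_rank_last": [out["last"][1][r] for r in regions],
        }
    )
    frame["delta"] = frame["rank_first"] - frame["rank_last"]
    return frame.sort_values("display_rank_last").reset_index(drop=True)
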