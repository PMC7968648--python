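"""Besag–York–Mollié (BYM) Poisson model and its MCMC sampler.

Model
-----
Observed counts ``O[i, p]`` (region i, period p) are modelled as

    O[i, p] ~ Poisson(mu[i, p]),
    mu[i, p] = E_adj[i, p] * exp(alpha + x[i, p]' beta + u[i] + v[i]),

where ``E_adj`` are completeness-adjusted expected counts (so the mean
refers to *observed* counts), ``u`` is a spatially structured effect with an
intrinsic conditional autoregressive (ICAR) prior on the region adjacency
graph, and ``v`` an exchangeable Gaussian effect.  ``exp(alpha + x'beta +
u + v)`` is the relative risk theta smoothing the raw standardised ratio
O/E.

Priors: ``alpha, beta ~ Normal(0, sd_fixed^2)`` on internally standardised
covariates; ``u | tau_u ~ ICAR(tau_u)`` (improper, rank-deficient by one per
graph component); ``v_i ~ Normal(0, 1/tau_v)``; ``tau_u, tau_v ~
Gamma(shape, rate)`` with the disease-mapping convention Gamma(0.5, 0.0005)
by default.

Sampling is Metropolis-within-Gibbs: conjugate Gibbs draws for the two
precisions; adaptive random-walk Metropolis for ``alpha``, each ``beta_k``,
and element-wise for ``u`` (updated in graph-colouring blocks so vectorised
updates remain exact) and ``v``.  After every sweep ``u`` is recentred to
mean zero within each graph component; for a connected graph the removed
mean is absorbed into ``alpha`` so the linear predictor is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .containers import AdjacencyGraph, CovariatePanel, EventPanel, ExpectedCounts
from .exceptions import ContractError, InitialisationError, InputError, SchemaError

__all__ = [
    "BYMState",
    "MCMCConfig",
    "PosteriorDraws",
    "design_matrix",
    "poisson_loglik",
    "icar_logprior",
    "sample_tau_u",
    "sample_tau_v",
    "run_mcmc",
    "monitor_theta",
]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

_COVARIATE_FIELDS = {
    "completeness": "completeness",
    "urbanisation": "urbanisation",
    "yos": "yos",
    "log_completeness": "completeness",
}


def design_matrix(
    cov: CovariatePanel,
    columns: Sequence[str] = ("urbanisation", "yos"),
    standardise: bool = True,
) -> tuple[np.ndarray, tuple[str, ...], tuple[np.ndarray, np.ndarray]]:
    """Build the (R, P, K) regression design from a covariate panel.

    ``columns`` may name any of ``urbanisation``, ``yos``, ``completeness``
    or ``log_completeness`` (the last taking log of the completeness
    fraction, for the model variant that treats registry completeness as a
    free regression column instead of an offset).

    With ``standardise`` each column is centred and scaled to unit sd across
    all region x period cells (the mapping is returned), which is also what
    makes posterior relative risks exactly invariant to shifting a raw
    covariate by a constant.
    """
    cols, names = [], []
    for name in columns:
        if name not in _COVARIATE_FIELDS:
            raise SchemaError(f"unknown covariate column {name!r}")
        arr = np.asarray(getattr(cov, _COVARIATE_FIELDS[name]), dtype=float)
        if name == "log_completeness":
            arr = np.log(arr)
        cols.append(arr)
        names.append(name)
    if not cols:
        x = np.zeros((len(cov.region_ids), len(cov.periods), 0))
        return x, (), (np.zeros(0), np.ones(0))
    x = np.stack(cols, axis=-1).astype(float)  # (R, P, K)
    means = x.reshape(-1, x.shape[-1]).mean(axis=0)
    sds = x.reshape(-1, x.shape[-1]).std(axis=0)
    if standardise:
        if np.any(sds == 0):
            raise InputError("cannot standardise a constant covariate column")
        x = (x - means) / sds
    return x, tuple(names), (means, sds)


# ---------------------------------------------------------------------------
# States, config, draws
# ---------------------------------------------------------------------------


@dataclass
class BYMState:
    """One point in BYM parameter space (log-relative-risk scale)."""

    alpha: float
    beta: np.ndarray  # (K,)
    u: np.ndarray  # (R,) spatial effects
    v: np.ndarray  # (R,) exchangeable effects
    tau_u: float
    tau_v: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise InputError("precisions must be positive")


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``proposal_sd`` seeds the adaptive random-walk scales for the four
    Metropolis blocks; during burn-in each scale is tuned every 50 sweeps
    towards roughly 20–50% acceptance and then frozen.  ``hyper_tau_u`` /
    ``hyper_tau_v`` are Gamma(shape, rate) hyperpriors on the precisions.
    """

    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 5
    n_chains: int = 3
    seed: int = 0
    proposal_sd: dict = field(
        default_factory=lambda: {"alpha": 0.1, "beta": 0.1, "u": 0.3, "v": 0.3}
    )
    hyper_tau_u: tuple[float, float] = (0.5, 0.0005)
    hyper_tau_v: tuple[float, float] = (0.5, 0.0005)
    prior_sd_fixed: float = 10.0
    adapt: bool = True
    include_spatial: bool = True
    include_unstructured: bool = True

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_burnin:
            raise InputError("n_iter must exceed n_burnin")
        if self.thin < 1 or self.n_chains < 1:
            raise InputError("thin and n_chains must be positive")
        if any(s <= 0 for s in self.proposal_sd.values()) or self.prior_sd_fixed <= 0:
            raise InputError("all proposal/prior sds must be positive")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (chains, kept, ...) per quantity.

    ``design`` stores the standardised (R, P, K) design actually used, so
    relative risks can be reconstructed from the parameter draws alone.
    """

    region_ids: tuple[str, ...]
    periods: tuple[str, ...]
    covariate_names: tuple[str, ...]
    alpha: np.ndarray  # (C, S)
    beta: np.ndarray  # (C, S, K)
    u: np.ndarray  # (C, S, R)
    v: np.ndarray  # (C, S, R)
    tau_u: np.ndarray  # (C, S)
    tau_v: np.ndarray  # (C, S)
    theta: np.ndarray  # (C, S, R, P)
    design: np.ndarray  # (R, P, K)
    acceptance: dict = field(default_factory=dict)
    config: MCMCConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_kept(self) -> int:
        return self.alpha.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws with the chain axis folded into the draw axis."""
        arr = getattr(self, name)
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])

    def theta_draws(self, region: str, period: str | None = None) -> np.ndarray:
        return monitor_theta(self, region=region, period=period)

    def posterior_mean_state(self) -> BYMState:
        return BYMState(
            alpha=float(self.stacked("alpha").mean()),
            beta=self.stacked("beta").mean(axis=0),
            u=self.stacked("u").mean(axis=0),
            v=self.stacked("v").mean(axis=0),
            tau_u=float(self.stacked("tau_u").mean()),
            tau_v=float(self.stacked("tau_v").mean()),
        )

    def to_frame(self):
        """One row per retained draw: chain, draw, scalars, then vectors."""
        import pandas as pd

        c, s = self.n_chains, self.n_kept
        chain = np.repeat(np.arange(c), s)
        draw = np.tile(np.arange(s), c)
        data = {"chain": chain, "draw": draw,
                "alpha": self.stacked("alpha"),
                "tau_u": self.stacked("tau_u"), "tau_v": self.stacked("tau_v")}
        for k, name in enumerate(self.covariate_names):
            data[f"beta_{name}"] = self.stacked("beta")[:, k]
        for i, r in enumerate(self.region_ids):
            data[f"u_{r}"] = self.stacked("u")[:, i]
            data[f"v_{r}"] = self.stacked("v")[:, i]
        th = self.stacked("theta")
        for i, r in enumerate(self.region_ids):
            for p_, per in enumerate(self.periods):
                data[f"theta_{r}_{per}"] = th[:, i, p_]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Log-likelihood and priors
# ---------------------------------------------------------------------------


def _as_counts(O) -> np.ndarray:
    if isinstance(O, EventPanel):
        arr = O.totals()
        if not O.is_integer:
            raise ContractError("Poisson likelihood requires integer counts")
        return arr
    return np.asarray(O, dtype=float)


def _as_expected(E) -> np.ndarray:
    if isinstance(E, ExpectedCounts):
        return E.values
    return np.asarray(E, dtype=float)


def _as_design(X, shape_rp: tuple[int, int]) -> np.ndarray:
    if X is None:
        return np.zeros(shape_rp + (0,))
    if isinstance(X, CovariatePanel):
        x, _, _ = design_matrix(X)
        return x
    x = np.asarray(X, dtype=float)
    if x.ndim == 2:  # (R, K) constant over periods
        x = np.repeat(x[:, None, :], shape_rp[1], axis=1)
    return x


def poisson_loglik(state: BYMState, O, E_adj, X=None) -> float:
    """Poisson log-likelihood, the constant ``log O!`` omitted.

    Cells with ``E_adj == 0`` and ``O == 0`` contribute nothing; a positive
    count against a zero expectation yields ``-inf`` (signalled, not
    raised), since no finite relative risk can produce it.
    """
    o = _as_counts(O)
    e = _as_expected(E_adj)
    if o.shape != e.shape:
        raise SchemaError(f"counts shape {o.shape} != expected shape {e.shape}")
    if np.any(e < 0):
        raise InputError("expected counts must be non-negative")
    x = _as_design(X, e.shape)
    if np.any((e == 0) & (o > 0)):
        warnings.warn("positive count with zero expectation: log-likelihood is -inf")
        return float("-inf")
    mask = e > 0
    eta = state.alpha + x @ state.beta + (state.u + state.v)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = e * np.exp(eta)
        terms = o * np.log(mu) - mu
        # O == 0 cells contribute -mu even though log mu may be anything finite
        terms = np.where(o == 0, -mu, terms)
    return float(terms[mask].sum())


def icar_logprior(u: np.ndarray, tau_u: float, graph: AdjacencyGraph) -> float:
    """Improper ICAR log-density, up to an additive constant.

    ((n - k)/2) log tau_u - (tau_u/2) * sum over unordered neighbour pairs
    of (u_i - u_j)^2, with k the number of graph components (the prior's
    rank deficiency).  Invariant to adding a constant within a component.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (graph.n_regions,):
        raise InputError(f"u has length {u.size}, graph has {graph.n_regions} regions")
    if tau_u <= 0:
        raise InputError("tau_u must be positive")
    e = graph.edges
    quad = float(np.sum((u[e[:, 0]] - u[e[:, 1]]) ** 2)) if len(e) else 0.0
    n, k = graph.n_regions, graph.n_components
    return 0.5 * (n - k) * np.log(tau_u) - 0.5 * tau_u * quad


def sample_tau_u(
    u: np.ndarray, graph: AdjacencyGraph, prior: tuple[float, float], rng: np.random.Generator
) -> float:
    """Conjugate Gamma draw for the ICAR precision."""
    e = graph.edges
    quad = float(np.sum((u[e[:, 0]] - u[e[:, 1]]) ** 2)) if len(e) else 0.0
    shape = prior[0] + 0.5 * (graph.n_regions - graph.n_components)
    rate = prior[1] + 0.5 * quad
    return float(rng.gamma(shape, 1.0 / rate))


def sample_tau_v(
    v: np.ndarray, prior: tuple[float, float], rng: np.random.Generator
) -> float:
    """Conjugate Gamma draw for the exchangeable-effect precision."""
    shape = prior[0] + 0.5 * v.size
    rate = prior[1] + 0.5 * float(np.sum(v**2))
    return float(rng.gamma(shape, 1.0 / rate))


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


def _colour_classes(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Partition region indices into independent sets (no internal edges).

    Within a colour class no two regions are neighbours, so element-wise
    Metropolis updates of u over the whole class are mutually independent
    conditionals and can be vectorised without breaking detailed balance.
    """
    colours = nx.greedy_color(graph.to_networkx(), strategy="largest_first")
    idx = graph.index_of
    by_colour: dict[int, list[int]] = {}
    for r, c in colours.items():
        by_colour.setdefault(c, []).append(idx[r])
    return [np.sort(np.array(v, dtype=int)) for _, v in sorted(by_colour.items())]


class _Adapter:
    """Robbins–Monro style scale tuning towards a target acceptance rate."""

    def __init__(self, sd: float, target: float = 0.35):
        self.sd = sd
        self.target = target
        self.acc = 0.0
        self.att = 0.0

    def record(self, accepted: float, attempted: float) -> None:
        self.acc += accepted
        self.att += attempted

    def adapt(self) -> None:
        if self.att == 0:
            return
        rate = self.acc / self.att
        self.sd = float(np.clip(self.sd * np.exp(0.8 * (rate - self.target)), 1e-4, 20.0))
        self.acc = self.att = 0.0

    def rate(self) -> float:
        return self.acc / self.att if self.att else float("nan")


def run_mcmc(O, E_adj, X, graph: AdjacencyGraph, config: MCMCConfig) -> PosteriorDraws:
    """Fit the BYM model by Metropolis-within-Gibbs.

    ``O`` may be an :class:`EventPanel` (pooled over ages) or an (R, P)
    array; ``E_adj`` an :class:`ExpectedCounts` or array; ``X`` a
    :class:`CovariatePanel` (standardised internally with the default
    columns), an (R, P, K) array assumed already standardised, or ``None``.

    Cells with ``E_adj == 0`` are excluded from the likelihood (warned);
    the run is bitwise-reproducible for a fixed config and seed.
    """
    o = _as_counts(O)
    e = _as_expected(E_adj)
    if isinstance(O, EventPanel):
        region_ids, periods = O.region_ids, O.periods
    elif isinstance(E_adj, ExpectedCounts):
        region_ids, periods = E_adj.region_ids, E_adj.periods
    else:
        region_ids = graph.region_ids
        periods = tuple(f"p{k}" for k in range(o.shape[1]))
    if o.ndim != 2 or o.shape != e.shape:
        raise SchemaError("counts and expected counts must share an (R, P) shape")
    if o.shape[0] != graph.n_regions:
        raise SchemaError("region dimension does not match the adjacency graph")

    cov_names: tuple[str, ...] = ()
    if isinstance(X, CovariatePanel):
        x, cov_names, _ = design_matrix(X)
    else:
        x = _as_design(X, o.shape)
        cov_names = tuple(f"x{k}" for k in range(x.shape[-1]))
    R, P = o.shape
    K = x.shape[-1]

    mask = e > 0
    if np.any((~mask) & (o > 0)):
        raise InitialisationError(
            "positive counts with zero expected counts: likelihood is -inf"
        )
    if not mask.all():
        warnings.warn(f"{int((~mask).sum())} cells with E=0 excluded from the likelihood")
    om = np.where(mask, o, 0.0)
    loge = np.where(mask, np.log(np.where(mask, e, 1.0)), 0.0)

    classes = _colour_classes(graph)
    wmat = graph.adjacency_matrix()
    degrees = graph.degrees
    comp = graph.component_labels
    comps = [np.flatnonzero(comp == k) for k in range(graph.n_components)]
    prior_var = config.prior_sd_fixed**2

    def region_ll(alpha, xb, uv):
        # per-region log-likelihood contributions, (R,)
        eta = alpha + xb + uv[:, None] + loge
        mu = np.exp(eta)
        return np.where(mask, om * eta - mu, 0.0).sum(axis=1)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    S = config.n_kept
    out = {
        "alpha": np.empty((config.n_chains, S)),
        "beta": np.empty((config.n_chains, S, K)),
        "u": np.empty((config.n_chains, S, R)),
        "v": np.empty((config.n_chains, S, R)),
        "tau_u": np.empty((config.n_chains, S)),
        "tau_v": np.empty((config.n_chains, S)),
        "theta": np.empty((config.n_chains, S, R, P)),
    }
    acceptance: dict[str, list[float]] = {k: [] for k in ("alpha", "beta", "u", "v")}

    for chain, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)

        # data-driven start: intercept at the pooled log-SIR, effects split
        # from the per-region residual log-ratio
        tot_o, tot_e = om[mask].sum(), e[mask].sum()
        alpha = float(np.log(tot_o / tot_e)) if tot_o > 0 else 0.0
        beta = np.zeros(K)
        resid = np.log((om.sum(axis=1) + 0.5) / (np.where(mask, e, 0).sum(axis=1) + 0.5)) - alpha
        u = 0.5 * resid if config.include_spatial else np.zeros(R)
        v = 0.5 * resid if config.include_unstructured else np.zeros(R)
        for ci in comps:
            u[ci] -= u[ci].mean()
        tau_u, tau_v = 10.0, 10.0
        xb = x @ beta

        ll0 = region_ll(alpha, xb, u + v).sum()
        if not np.isfinite(ll0):
            raise InitialisationError(f"non-finite log-likelihood at initial state ({ll0})")

        ad = {k: _Adapter(config.proposal_sd[k], target=0.35 if k in ("alpha", "beta") else 0.40)
              for k in ("alpha", "beta", "u", "v")}
        tally = {k: [0.0, 0.0] for k in ad}  # post-burn-in acceptance bookkeeping

        for it in range(config.n_iter):
            burn = it < config.n_burnin

            # alpha: scalar random walk
            delta = rng.normal(0.0, ad["alpha"].sd)
            cur = region_ll(alpha, xb, u + v).sum()
            prop = region_ll(alpha + delta, xb, u + v).sum()
            dlp = prop - cur + (alpha**2 - (alpha + delta) ** 2) / (2 * prior_var)
            accept = np.log(rng.uniform()) < dlp
            if accept:
                alpha += delta
            ad["alpha"].record(accept, 1)
            if not burn:
                tally["alpha"][0] += accept
                tally["alpha"][1] += 1

            # beta: scalar random walk per coefficient
            for k in range(K):
                delta = rng.normal(0.0, ad["beta"].sd)
                xb_prop = xb + x[:, :, k] * delta
                cur = region_ll(alpha, xb, u + v).sum()
                prop = region_ll(alpha, xb_prop, u + v).sum()
                dlp = prop - cur + (beta[k] ** 2 - (beta[k] + delta) ** 2) / (2 * prior_var)
                accept = np.log(rng.uniform()) < dlp
                if accept:
                    beta[k] += delta
                    xb = xb_prop
                ad["beta"].record(accept, 1)
                if not burn:
                    tally["beta"][0] += accept
                    tally["beta"][1] += 1

            # u: element-wise Metropolis in colouring blocks
            if config.include_spatial:
                for cls in classes:
                    delta = rng.normal(0.0, ad["u"].sd, cls.size)
                    logu = np.log(rng.uniform(size=cls.size))
                    s_nbr = wmat[cls] @ u  # neighbour sums; neighbours never share a colour
                    u_new = u[cls] + delta
                    dprior = -0.5 * tau_u * (
                        degrees[cls] * (u_new**2 - u[cls] ** 2) - 2.0 * delta * s_nbr
                    )
                    ll_cur = region_ll(alpha, xb, u + v)[cls]
                    u_prop = u.copy()
                    u_prop[cls] = u_new
                    ll_prop = region_ll(alpha, xb, u_prop + v)[cls]
                    acc = logu < (ll_prop - ll_cur + dprior)
                    u[cls[acc]] = u_new[acc]
                    ad["u"].record(acc.sum(), acc.size)
                    if not burn:
                        tally["u"][0] += acc.sum()
                        tally["u"][1] += acc.size

                # recentre per component; a connected graph lets the shift be
                # absorbed into alpha so the linear predictor is untouched
                if len(comps) == 1:
                    m = u.mean()
                    u -= m
                    alpha += m
                else:
                    for ci in comps:
                        u[ci] -= u[ci].mean()
                tau_u = sample_tau_u(u, graph, config.hyper_tau_u, rng)

            # v: element-wise Metropolis, all regions at once (independent
            # conditionals given u)
            if config.include_unstructured:
                delta = rng.normal(0.0, ad["v"].sd, R)
                logu = np.log(rng.uniform(size=R))
                ll_cur = region_ll(alpha, xb, u + v)
                v_new = v + delta
                ll_prop = region_ll(alpha, xb, u + v_new)
                dprior = -0.5 * tau_v * (v_new**2 - v**2)
                acc = logu < (ll_prop - ll_cur + dprior)
                v[acc] = v_new[acc]
                ad["v"].record(acc.sum(), acc.size)
                if not burn:
                    tally["v"][0] += acc.sum()
                    tally["v"][1] += acc.size
                tau_v = sample_tau_v(v, config.hyper_tau_v, rng)

            if burn and config.adapt and (it + 1) % 50 == 0:
                for a in ad.values():
                    a.adapt()

            if not burn and (it - config.n_burnin) % config.thin == 0:
                s = (it - config.n_burnin) // config.thin
                out["alpha"][chain, s] = alpha
                out["beta"][chain, s] = beta
                out["u"][chain, s] = u
                out["v"][chain, s] = v
                out["tau_u"][chain, s] = tau_u
                out["tau_v"][chain, s] = tau_v
                out["theta"][chain, s] = np.exp(alpha + xb + (u + v)[:, None])

        for k, (a, n) in tally.items():
            acceptance[k].append(a / n if n else float("nan"))

    return PosteriorDraws(
        region_ids=tuple(region_ids),
        periods=tuple(periods),
        covariate_names=cov_names,
        design=x,
        acceptance={k: v for k, v in acceptance.items()},
        config=config,
        **out,
    )


def monitor_theta(
    draws: PosteriorDraws, region: str | None = None, period: str | None = None
) -> np.ndarray:
    """Relative-risk draws theta = exp(alpha + x'beta + u + v).

    Recomputed from the parameter draws and the stored design (rather than
    read back from the cached theta array).  Returns a 1-D array of stacked
    draws for a single region (optionally a single period), or the full
    (draws, R, P) array when ``region`` is None.
    """
    alpha = draws.stacked("alpha")  # (N,)
    beta = draws.stacked("beta")  # (N, K)
    u = draws.stacked("u")
    v = draws.stacked("v")
    x = draws.design  # (R, P, K)
    eta = alpha[:, None, None] + np.einsum("rpk,nk->nrp", x, beta) + (u + v)[:, :, None]
    theta = np.exp(eta)
    if region is None:
        return theta
    try:
        i = draws.region_ids.index(region)
    except ValueError:
        raise SchemaError(f"unknown region {region!r}") from None
    if period is None:
        return theta[:, i, :]
    try:
        p = draws.periods.index(str(period))
    except ValueError:
        raise SchemaError(f"unknown period {period!r}") from None
    return theta[:, i, p]
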