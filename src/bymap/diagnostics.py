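"""Model diagnostics: residual spatial autocorrelation, DIC, convergence.

Moran's I is computed on per-region Pearson residuals against the same
adjacency structure the ICAR prior used, with a permutation null (random
relabelling of regions).  A well-specified BYM fit should leave residuals
with I near its null expectation -1/(n-1) and a non-significant p-value.

DIC follows the BUGS convention: deviance D = -2 log-likelihood (same
constant-omission as the model's Poisson log-likelihood throughout),
``dbar`` the posterior mean deviance, ``d_hat`` the deviance at the
posterior means of alpha, beta, u, v (plug-in focus at the relative-risk
level), ``p_d = dbar - d_hat`` and ``dic = dbar + p_d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AdjacencyGraph
from .exceptions import DiagnosticError, InputError
from .model import BYMState, PosteriorDraws, poisson_loglik, _as_counts, _as_expected

__all__ = [
    "MoranResult",
    "DICResult",
    "pearson_residuals",
    "deviance_residuals",
    "morans_i",
    "compute_dic",
    "convergence_summary",
]


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_perm: int


@dataclass(frozen=True)
class DICResult:
    dbar: float
    d_hat: float
    p_d: float
    dic: float


def pearson_residuals(O, draws: PosteriorDraws, E_adj) -> np.ndarray:
    """Per-region Pearson residuals on posterior-mean fitted values.

    ``r[i, p] = (O[i, p] - mu_hat[i, p]) / sqrt(mu_hat[i, p])`` with
    ``mu_hat = E_adj * posterior mean theta``, averaged over periods.
    """
    o = _as_counts(O)
    e = _as_expected(E_adj)
    theta_hat = draws.stacked("theta").mean(axis=0)  # (R, P)
    mu_hat = e * theta_hat
    if np.any((mu_hat == 0) & (o > 0)):
        raise DiagnosticError("zero fitted value against a positive count")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mu_hat > 0, (o - mu_hat) / np.sqrt(np.where(mu_hat > 0, mu_hat, 1.0)), 0.0)
    return r.mean(axis=1)


def deviance_residuals(O, draws: PosteriorDraws, E_adj) -> np.ndarray:
    """Signed Poisson deviance residuals on posterior-mean fitted values.

    ``sign(O - mu_hat) * sqrt(2 * [O log(O/mu_hat) - (O - mu_hat)])`` (the
    O = 0 limit is ``-sqrt(2 * mu_hat)``), averaged over periods.  An
    alternative to the default Pearson form for the residual Moran test.
    """
    o = _as_counts(O)
    e = _as_expected(E_adj)
    mu_hat = e * draws.stacked("theta").mean(axis=0)
    if np.any((mu_hat == 0) & (o > 0)):
        raise DiagnosticError("zero fitted value against a positive count")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(o > 0, o * np.log(np.where(o > 0, o, 1.0) / np.where(mu_hat > 0, mu_hat, 1.0)), 0.0)
        dev2 = 2.0 * (term - (o - mu_hat))
        r = np.sign(o - mu_hat) * np.sqrt(np.maximum(dev2, 0.0))
        r = np.where(mu_hat > 0, r, 0.0)
    return r.mean(axis=1)


def morans_i(
    x: np.ndarray,
    graph: AdjacencyGraph,
    weighting: str = "binary",
    n_perm: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Moran's I with a two-sided permutation test.

    ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with ``z = x -
    mean(x)``.  The permutation p-value counts relabellings whose |I -
    E[I]| is at least the observed one, the observed configuration included
    in the null set (add-one rule), so ``p >= 1/(n_perm + 1)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise InputError("Moran's I needs at least 3 regions")
    if n != graph.n_regions:
        raise InputError("x length does not match the graph")
    if weighting not in ("binary", "row-standardised"):
        raise InputError(f"unknown weighting {weighting!r}")
    w = graph.adjacency_matrix(row_standardised=(weighting == "row-standardised"))
    s0 = w.sum()
    if s0 == 0:
        raise InputError("graph has no edges")
    z = x - x.mean()
    denom = float(np.sum(z**2))
    if denom == 0:
        raise InputError("zero variance: Moran's I is undefined")

    def stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ w @ zv) / np.sum(zv**2))

    i_obs = stat(z)
    e_i = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    ref = abs(i_obs - e_i)
    hits = 0
    for _ in range(int(n_perm)):
        zp = rng.permutation(z)
        if abs(stat(zp) - e_i) >= ref - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MoranResult(I=i_obs, expected_I=e_i, p_value=p, n_perm=int(n_perm))


def compute_dic(draws: PosteriorDraws, O, E_adj, X=None) -> DICResult:
    """Deviance information criterion with plug-in posterior means."""
    if draws.n_chains * draws.n_kept < 2:
        raise InputError("DIC needs at least 2 retained draws")
    x = draws.design if X is None else X
    alpha = draws.stacked("alpha")
    beta = draws.stacked("beta")
    u = draws.stacked("u")
    v = draws.stacked("v")
    dev = np.empty(alpha.size)
    for s in range(alpha.size):
        state = BYMState(alpha[s], beta[s], u[s], v[s], 1.0, 1.0)
        dev[s] = -2.0 * poisson_loglik(state, O, E_adj, x)
        if not np.isfinite(dev[s]):
            raise DiagnosticError(f"non-finite deviance at draw {s}")
    dbar = float(dev.mean())
    d_hat = -2.0 * poisson_loglik(draws.posterior_mean_state(), O, E_adj, x)
    p_d = dbar - d_hat
    return DICResult(dbar=dbar, d_hat=float(d_hat), p_d=float(p_d), dic=dbar + p_d)


def convergence_summary(draws: PosteriorDraws, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split-R-hat and effective sample size per monitored scalar.

    Uses rank-normalised split-R-hat and bulk ESS (via ``arviz``); rows
    with R-hat above ``rhat_threshold`` are flagged.
    """
    if draws.n_chains < 2 and draws.n_kept < 100:
        raise InputError("need at least 2 chains or 100 draws per chain")
    import arviz as az

    data = {
        "alpha": draws.alpha,
        "tau_u": draws.tau_u,
        "tau_v": draws.tau_v,
    }
    for k, name in enumerate(draws.covariate_names):
        data[f"beta_{name}"] = draws.beta[:, :, k]
    for i, r in enumerate(draws.region_ids):
        data[f"u_{r}"] = draws.u[:, :, i]
        data[f"v_{r}"] = draws.v[:, :, i]
    idata = az.from_dict(posterior=data)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in data:
        rh = float(rhat[name].values)
        rows.append(
            {
                "parameter": name,
                "rhat": rh,
                "ess": float(ess[name].values),
                "flagged": bool(rh > rhat_threshold),
            }
        )
    return pd.DataFrame(rows)
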