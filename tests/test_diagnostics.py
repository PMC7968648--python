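"""Pearson residuals, Moran's I, DIC and convergence summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from itertools import permutations

from bymap import build_lattice, compute_dic, convergence_summary, morans_i, pearson_residuals
from bymap.diagnostics import deviance_residuals
from bymap.exceptions import InputError
from bymap.model import BYMState, poisson_loglik

from conftest import make_draws


# -- residuals -------------------------------------------------------------


def _draws_with_theta(theta_rp, region_ids, periods):
    """Point-mass draws whose posterior-mean theta equals ``theta_rp``."""
    r, p = np.asarray(theta_rp).shape
    d = make_draws(np.zeros((1, 2)), region_ids=region_ids, periods=periods)
    d.theta = np.broadcast_to(
        np.asarray(theta_rp, float)[None, None], (1, 2, r, p)
    ).copy()
    return d


def test_perfect_fit_gives_zero_residuals():
    o = np.array([[4.0], [9.0]])
    e = np.array([[4.0], [9.0]])
    d = _draws_with_theta(np.ones((2, 1)), ("A", "B"), ("p",))
    assert np.allclose(pearson_residuals(o, d, e), 0.0)


def test_hand_residual():
    # O = 4, mu_hat = 1 -> (4 - 1)/sqrt(1) = 3
    o = np.array([[4.0]])
    e = np.array([[1.0]])
    d = _draws_with_theta(np.ones((1, 1)), ("A",), ("p",))
    assert pearson_residuals(o, d, e)[0] == pytest.approx(3.0)


def test_residual_scales_with_sqrt_of_doubling():
    o = np.array([[7.0]])
    e = np.array([[4.0]])
    d = _draws_with_theta(np.ones((1, 1)), ("A",), ("p",))
    r1 = pearson_residuals(o, d, e)[0]
    r2 = pearson_residuals(2 * o, d, 2 * e)[0]
    assert r2 == pytest.approx(np.sqrt(2) * r1)


def test_deviance_residuals_match_poisson_deviance_formula():
    o = np.array([[4.0], [0.0]])
    e = np.array([[1.0], [2.0]])
    d = _draws_with_theta(np.ones((2, 1)), ("A", "B"), ("p",))
    r = deviance_residuals(o, d, e)
    assert r[0] == pytest.approx(np.sqrt(2 * (4 * np.log(4.0) - 3.0)))
    assert r[1] == pytest.approx(-np.sqrt(4.0))  # O = 0 limit: -sqrt(2 mu)
    # perfect fit -> zero
    assert np.allclose(
        deviance_residuals(np.array([[5.0]]), _draws_with_theta(np.ones((1, 1)), ("A",), ("p",)),
                           np.array([[5.0]])), 0.0)


# -- Moran's I -------------------------------------------------------------


def test_checkerboard_moran_is_minus_one(grid4):
    res = morans_i(np.array([1.0, -1.0, -1.0, 1.0]), grid4, n_perm=99, seed=0)
    assert res.I == pytest.approx(-1.0)
    assert res.expected_I == pytest.approx(-1 / 3)
    assert res.p_value >= 1 / 100


def test_constant_vector_is_degenerate(grid4):
    with pytest.raises(InputError):
        morans_i(np.full(4, 2.0), grid4)


def test_too_few_regions():
    g = build_lattice(2, "ring")
    with pytest.raises(InputError):
        morans_i(np.array([1.0, -1.0]), g)


def _brute_force_moran_p(x, graph):
    """Exhaustive two-sided permutation p over all relabelings (oracle)."""
    n = x.size
    w = graph.adjacency_matrix()
    s0 = w.sum()

    def stat(v):
        z = v - v.mean()
        return n / s0 * (z @ w @ z) / np.sum(z**2)

    e_i = -1 / (n - 1)
    obs = abs(stat(x) - e_i)
    vals = [abs(stat(np.asarray(p)) - e_i) for p in permutations(x)]
    return np.mean([v >= obs - 1e-12 for v in vals])


def test_permutation_p_matches_exhaustive_enumeration(grid4):
    x = np.array([0.5, -1.2, 0.3, 1.0])
    exact = _brute_force_moran_p(x, grid4)
    res = morans_i(x, grid4, n_perm=9999, seed=3)
    assert abs(res.p_value - exact) < 0.02


@given(
    shift=st.floats(min_value=-50, max_value=50),
    scale=st.floats(min_value=0.1, max_value=20),
)
def test_moran_is_affine_invariant(grid4, shift, scale):
    x = np.array([0.7, -0.4, 1.3, -0.9])
    a = morans_i(x, grid4, n_perm=49, seed=7)
    b = morans_i(scale * x + shift, grid4, n_perm=49, seed=7)
    assert b.I == pytest.approx(a.I)
    assert b.p_value == a.p_value


def test_permutation_p_is_super_uniform_under_the_null():
    g = build_lattice(16, "grid")
    rng = np.random.default_rng(0)
    rejections = 0
    n_reps = 1500
    for k in range(n_reps):
        x = rng.normal(size=16)
        res = morans_i(x, g, n_perm=199, seed=k)
        rejections += res.p_value <= 0.05
    assert rejections / n_reps <= 0.07


# -- DIC -------------------------------------------------------------------


def test_point_mass_posterior_has_zero_pd():
    o = np.array([[3.0]])
    e = np.array([[2.0]])
    d = make_draws(np.full((1, 4), 0.3))
    res = compute_dic(d, o, e)
    assert res.p_d == pytest.approx(0.0, abs=1e-9)
    assert res.dic == pytest.approx(res.dbar)


def test_two_draw_hand_computation():
    # 1-cell data O=2, E=1; draws alpha = 0 and log 2
    o = np.array([[2.0]])
    e = np.array([[1.0]])
    d = make_draws(np.array([[0.0, np.log(2.0)]]))
    res = compute_dic(d, o, e)
    dev1 = -2 * (2 * 0.0 - 1.0)
    dev2 = -2 * (2 * np.log(2) - 2.0)
    dbar = (dev1 + dev2) / 2
    a_bar = np.log(2) / 2
    d_hat = -2 * (2 * a_bar - np.exp(a_bar))
    assert res.dbar == pytest.approx(dbar)
    assert res.d_hat == pytest.approx(d_hat)
    assert res.p_d == pytest.approx(dbar - d_hat)
    assert res.dic == pytest.approx(2 * dbar - d_hat)


def test_dic_identity_on_a_real_fit():
    from bymap import simulate_scenario
    from bymap.demography import adjust_for_completeness
    from bymap.model import MCMCConfig, run_mcmc

    scen = simulate_scenario(seed=3, n_regions=9)
    e_adj = adjust_for_completeness(scen.expected, scen.covariates)
    cfg = MCMCConfig(n_iter=800, n_burnin=400, thin=2, n_chains=1, seed=3)
    draws = run_mcmc(scen.counts_observed, e_adj, scen.covariates, scen.graph, cfg)
    res = compute_dic(draws, scen.counts_observed.totals(), e_adj.values)
    assert res.dic == pytest.approx(2 * res.dbar - res.d_hat, rel=1e-12)
    assert res.p_d > 0


def test_irrelevant_covariate_does_not_shrink_pd():
    """An extra noise column can only add effective parameters (MC slack)."""
    from bymap.model import MCMCConfig, run_mcmc

    g = build_lattice(16, "grid")
    e = np.full((16, 1), 40.0)
    diffs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        o = rng.poisson(e).astype(float)
        cfg = MCMCConfig(n_iter=2000, n_burnin=1000, thin=1, n_chains=1, seed=seed)
        d0 = run_mcmc(o, e, None, g, cfg)
        x = rng.normal(size=(16, 1, 1))
        x = (x - x.mean()) / x.std()
        d1 = run_mcmc(o, e, x, g, cfg)
        p0 = compute_dic(d0, o, e).p_d
        p1 = compute_dic(d1, o, e).p_d
        diffs.append(p1 - p0)
    diffs = np.array(diffs)
    assert diffs.mean() > -0.1
    assert np.all(diffs > -1.0)


# -- convergence -----------------------------------------------------------


def test_identical_chains_have_unit_rhat():
    rng = np.random.default_rng(5)
    chain = rng.normal(size=500)
    d = make_draws(np.stack([chain, chain]))
    conv = convergence_summary(d)
    rhat = conv.set_index("parameter").loc["alpha", "rhat"]
    assert rhat == pytest.approx(1.0, abs=0.01)


def test_disjoint_chains_are_flagged():
    rng = np.random.default_rng(6)
    d = make_draws(np.stack([rng.normal(0, 1, 500), rng.normal(50, 1, 500)]))
    conv = convergence_summary(d).set_index("parameter")
    assert conv.loc["alpha", "rhat"] > 1.5
    assert bool(conv.loc["alpha", "flagged"])


def test_white_noise_ess_near_nominal():
    rng = np.random.default_rng(7)
    d = make_draws(rng.normal(size=(1, 1000)))
    conv = convergence_summary(d).set_index("parameter")
    assert 800 <= conv.loc["alpha", "ess"] <= 1200


def test_too_few_draws_rejected():
    d = make_draws(np.zeros((1, 10)))
    with pytest.raises(InputError):
        convergence_summary(d)
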