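import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bymap import build_lattice
from bymap.model import PosteriorDraws

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid4():
    """2x2 rook lattice."""
    return build_lattice(4, "grid")


@pytest.fixture(scope="session")
def ring4():
    return build_lattice(4, "ring")


def make_draws(
    alpha,
    beta=None,
    u=None,
    v=None,
    design=None,
    region_ids=("R00",),
    periods=("p0",),
    covariate_names=(),
):
    """Hand-build a PosteriorDraws object with consistent shapes.

    ``alpha`` is (chains, kept); missing effect/coefficient arrays default
    to zeros; theta is derived from the supplied parameters and design.
    """
    alpha = np.asarray(alpha, dtype=float)
    c, s = alpha.shape
    r, p = len(region_ids), len(periods)
    k = len(covariate_names)
    beta = np.zeros((c, s, k)) if beta is None else np.asarray(beta, dtype=float)
    u = np.zeros((c, s, r)) if u is None else np.asarray(u, dtype=float)
    v = np.zeros((c, s, r)) if v is None else np.asarray(v, dtype=float)
    design = np.zeros((r, p, k)) if design is None else np.asarray(design, dtype=float)
    eta = (
        alpha[:, :, None, None]
        + np.einsum("rpk,csk->csrp", design, beta)
        + (u + v)[:, :, :, None]
    )
    return PosteriorDraws(
        region_ids=tuple(region_ids),
        periods=tuple(periods),
        covariate_names=tuple(covariate_names),
        alpha=alpha,
        beta=beta,
        u=u,
        v=v,
        tau_u=np.ones((c, s)),
        tau_v=np.ones((c, s)),
        theta=np.exp(eta),
        design=design,
    )
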