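import numpy as np
import pytest

from wordage import DiffusionNetwork, validate_network
from wordage.networks import build_unidirectional_chain


def random_valid_network(rng: np.random.Generator, n: int) -> DiffusionNetwork:
    """Random row-stochastic network, guaranteed reachable from the centre.

    Each row blends a Dirichlet draw over (centre, P1..Pn) with the
    unidirectional-chain backbone, so rows sum to one exactly and every
    population has a positive-rate path from the centre.
    """
    raw = rng.dirichlet(np.ones(n + 1), size=n)
    backbone = build_unidirectional_chain(n, 0.5)
    chain = np.column_stack([backbone.source_rates, backbone.A.toarray()])
    rows = 0.5 * raw + 0.5 * chain
    net = DiffusionNetwork(source_rates=rows[:, 0], A=rows[:, 1:])
    return validate_network(net)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def fixed_point_mean(net: DiffusionNetwork, tol: float = 1e-12,
                     max_iter: int = 10**6) -> np.ndarray:
    """Independent oracle for the equilibrium mean: iterate r <- A r + 1."""
    r = np.zeros(net.n)
    for _ in range(max_iter):
        nxt = net.A @ r + 1.0
        if np.abs(nxt - r).max() < tol:
            return nxt
        r = nxt
    raise RuntimeError("fixed-point iteration did not converge")
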