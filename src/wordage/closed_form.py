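"""Analytic equilibrium moments for the two chain topologies.

These closed forms are exact consequences of the linear age recursion on
chains and double as independent oracles for the numerical solver.  Writing
``k`` for the distance from the centre (``1..n``) and ``a`` for the
neighbour transmission rate:

unidirectional chain
    ``r_k = k / a`` and ``sigma_k^2 = (k / a)(1/a - 1)`` — the age at ``Pk``
    is a sum of ``k`` independent geometric waiting times with success
    probability ``a``.

bidirectional chain
    ``r_k = k (2n - k + 1) / (2a)`` and
    ``sigma_k^2 = k (2n - k + 1)(2n^2 - 2nk + k^2 + 2n - k + 1) / (6 a^2)
    - r_k``.  The variance form is validated against the moment solve of
    :func:`wordage.core.equilibrium_sd` in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import RateRangeError

__all__ = ["uni_chain_moments", "bi_chain_moments"]


def uni_chain_moments(n: int, a: float) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium mean and SD of word age on the unidirectional chain.

    Returns ``(means, sds)``, each of length ``n`` indexed by distance ``k``
    from the centre.
    """
    if not 0 < a <= 1:
        raise RateRangeError(f"need 0 < a <= 1, got a={a}")
    if n < 1:
        raise RateRangeError(f"need n >= 1, got n={n}")
    k = np.arange(1, n + 1, dtype=float)
    means = k / a
    sds = np.sqrt((k / a) * (1.0 / a - 1.0))
    return means, sds


def bi_chain_moments(n: int, a: float) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium mean and SD of word age on the bidirectional chain.

    Returns ``(means, sds)`` of length ``n``.  Both moments grow with the
    distance ``k`` *and* with the chain length ``n``: remote populations feed
    old variants back toward the centre.
    """
    if not 0 < a <= 0.5:
        raise RateRangeError(f"need 0 < a <= 1/2, got a={a}")
    if n < 1:
        raise RateRangeError(f"need n >= 1, got n={n}")
    k = np.arange(1, n + 1, dtype=float)
    means = k * (2 * n - k + 1) / (2 * a)
    second = (
        k * (2 * n - k + 1) * (2 * n**2 - 2 * n * k + k**2 + 2 * n - k + 1)
        / (6 * a**2)
    )
    var = second - means
    sds = np.sqrt(np.clip(var, 0.0, None))
    return means, sds
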