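"""Parametric builders for the idealized topologies: chains, lattices, barriers.

All builders share the convention that transmission between connected
populations happens at a single rate ``a`` (reduced to ``b < a`` across a
barrier), with each population's self-rate absorbing the remainder so that
every row of choice probabilities sums to one.  Every builder output passes
:func:`wordage.core.validate_network`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .core import DiffusionNetwork, validate_network
from .errors import BarrierIsCenterError, RateRangeError

__all__ = [
    "LatticeSpec",
    "build_unidirectional_chain",
    "build_bidirectional_chain",
    "build_chain_with_barrier",
    "build_lattice",
    "build_lattice_with_barrier",
]


def build_unidirectional_chain(n: int, a: float) -> DiffusionNetwork:
    """Chain ``P0 -> P1 -> ... -> Pn`` with outward-only transmission.

    Each ``P(j+1)`` copies from ``P(j)`` at rate ``a`` and from itself
    otherwise; words can only move away from the centre.  This is the
    hierarchical limit in which learners always prefer the more central
    neighbour, and the equilibrium mean age grows linearly, ``r_k = k / a``.
    """
    if not 0 < a <= 1:
        raise RateRangeError(f"need 0 < a <= 1, got a={a}")
    if n < 1:
        raise RateRangeError(f"need n >= 1, got n={n}")
    source = np.zeros(n)
    source[0] = a
    A = sparse.lil_array((n, n))
    for k in range(n):
        A[k, k] = 1.0 - a
        if k > 0:
            A[k, k - 1] = a
    net = DiffusionNetwork(
        source_rates=source,
        A=sparse.csr_array(A),
        meta={"builder": "unidirectional_chain", "n": n, "a": a},
    )
    return validate_network(net)


def build_bidirectional_chain(n: int, a: float) -> DiffusionNetwork:
    """Chain with symmetric transmission between adjacent populations.

    Interior populations copy from both neighbours at rate ``a`` (self-rate
    ``1 - 2a``); the terminal population has one neighbour only (self-rate
    ``1 - a``).  Old words flow back inward, so mean ages exceed the
    unidirectional chain's and depend on the chain length ``n``.
    """
    if not 0 < a <= 0.5:
        raise RateRangeError(f"need 0 < a <= 1/2, got a={a}")
    if n < 1:
        raise RateRangeError(f"need n >= 1, got n={n}")
    source = np.zeros(n)
    source[0] = a
    A = sparse.lil_array((n, n))
    for k in range(n):
        if k > 0:
            A[k, k - 1] = a
        if k < n - 1:
            A[k, k + 1] = a
        neighbours = (1 if k < n - 1 else 0) + 1  # predecessor is P0 for k=0
        A[k, k] = 1.0 - a * neighbours
    net = DiffusionNetwork(
        source_rates=source,
        A=sparse.csr_array(A),
        meta={"builder": "bidirectional_chain", "n": n, "a": a},
    )
    return validate_network(net)


def build_chain_with_barrier(n: int, a: float, b: float, h: int) -> DiffusionNetwork:
    """Bidirectional chain with a weakened link between ``Ph`` and ``Ph+1``.

    The barrier (a river, mountain range, or cultural boundary) reduces the
    two rates across the ``Ph``–``Ph+1`` edge to ``b`` in both directions;
    the freed probability ``a - b`` returns to the two self-rates so rows
    still sum to one.  ``h`` counts from the centre: ``h = 1`` puts the
    barrier between ``P1`` and ``P2``.
    """
    if not 0 < b <= a:
        raise RateRangeError(f"need 0 < b <= a, got a={a}, b={b}")
    if not 1 <= h <= n - 1:
        raise RateRangeError(f"need 1 <= h <= n-1, got h={h}, n={n}")
    net = build_bidirectional_chain(n, a)
    A = sparse.lil_array(net.A)
    i, j = h - 1, h  # 0-based indices of Ph and Ph+1
    A[i, j] = b
    A[j, i] = b
    A[i, i] += a - b
    A[j, j] += a - b
    net = DiffusionNetwork(
        source_rates=net.source_rates,
        A=sparse.csr_array(A),
        meta={"builder": "chain_with_barrier", "n": n, "a": a, "b": b, "h": h},
    )
    return validate_network(net)


@dataclass
class LatticeSpec:
    """Geometry of a rectangular lattice of populations.

    Coordinates are 1-based ``(x, y)`` with ``x`` the column (``1..m``) and
    ``y`` the row (``1..l``).  ``center`` locates the central population;
    ``barrier``/``b`` optionally mark one node whose incident edges are
    weakened to rate ``b``.
    """

    m: int
    l: int
    center: tuple[int, int]
    a: float
    barrier: tuple[int, int] | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        for name, (x, y) in (("center", self.center),) + (
            (("barrier", self.barrier),) if self.barrier is not None else ()
        ):
            if not (1 <= x <= self.m and 1 <= y <= self.l):
                raise RateRangeError(
                    f"{name} {(x, y)} outside the {self.m} x {self.l} lattice"
                )
        if self.barrier is not None:
            if self.barrier == self.center:
                raise BarrierIsCenterError("barrier node coincides with the centre")
            if self.b is None or not 0 < self.b <= self.a:
                raise RateRangeError(f"need 0 < b <= a, got a={self.a}, b={self.b}")

    def node_index(self, x: int, y: int) -> int:
        """Row-major flat index of grid node ``(x, y)`` (centre included)."""
        return (y - 1) * self.m + (x - 1)


def _lattice_network(spec: LatticeSpec) -> DiffusionNetwork:
    m, l, a = spec.m, spec.l, spec.a
    total = m * l
    c = spec.node_index(*spec.center)
    barrier_idx = spec.node_index(*spec.barrier) if spec.barrier is not None else None

    def neighbours(idx: int):
        x, y = idx % m + 1, idx // m + 1
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx, ny = x + dx, y + dy
            if 1 <= nx <= m and 1 <= ny <= l:
                yield spec.node_index(nx, ny)

    # rates on the full grid, then drop the centre's row / move its column
    W = sparse.lil_array((total, total))
    for i in range(total):
        if i == c:
            continue
        for j in neighbours(i):
            rate = a
            if barrier_idx is not None and barrier_idx in (i, j):
                rate = spec.b
            W[i, j] = rate
    diag = 1.0 - np.asarray(W.sum(axis=1)).ravel()
    if (diag[np.arange(total) != c] < -1e-12).any():
        raise RateRangeError(
            f"a={a} too large: some self-rate would be negative "
            "(interior nodes need a <= 1/4)"
        )
    for i in range(total):
        if i != c:
            W[i, i] = diag[i]

    keep = [i for i in range(total) if i != c]
    Wc = sparse.csr_array(W)
    source = Wc[:, [c]].toarray().ravel()[keep]
    A = Wc[keep][:, keep]
    labels = [f"({i % m + 1},{i // m + 1})" for i in keep]
    meta = {
        "builder": "lattice" if barrier_idx is None else "lattice_with_barrier",
        "m": m,
        "l": l,
        "center": spec.center,
        "a": a,
    }
    if barrier_idx is not None:
        meta.update({"barrier": spec.barrier, "b": spec.b})
    net = DiffusionNetwork(
        source_rates=source, A=sparse.csr_array(A), labels=labels, meta=meta
    )
    return validate_network(net)


def build_lattice(spec: LatticeSpec) -> DiffusionNetwork:
    """Rectangular lattice with bidirectional nearest-neighbour diffusion.

    Every population copies from each of its 2-4 von Neumann neighbours at
    rate ``a``; edges pointing at the central node become source rates.  Node
    labels record the ``(x,y)`` grid coordinate of each peripheral population.
    """
    if spec.barrier is not None:
        raise RateRangeError("spec has a barrier; use build_lattice_with_barrier")
    return _lattice_network(spec)


def build_lattice_with_barrier(spec: LatticeSpec) -> DiffusionNetwork:
    """Lattice in which one node is a weakly connected barrier.

    Transmission to and from the barrier node happens at rate ``b < a`` on
    every incident edge; the freed probability raises the affected self-rates.
    With small ``b`` the barrier node becomes a local peak of mean word age —
    words reach it late, from already-old neighbourhoods.
    """
    if spec.barrier is None:
        raise RateRangeError("spec.barrier must be set")
    return _lattice_network(spec)
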