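"""Deterministic (large-population) word-age computations on diffusion networks.

The model: a central population ``P0`` invents one new linguistic variant per
time step and always carries only the newest one.  Each learner in a peripheral
population ``Pk`` copies a role model drawn from population ``Pj`` with
probability ``a_kj`` (``j = 0`` meaning the centre).  Because every variant is
born in the centre, a variant is identified by its *age* — the number of steps
since its invention — and the state of the system is the per-population
frequency distribution of ages ``f_k(rho, t)``.

With populations large enough for sampling noise to vanish, the dynamics are a
linear recursion on the age distribution, and the equilibrium mean age solves
``(E - A) r = 1`` where ``A`` is the periphery-to-periphery transmission
matrix.  This module holds the state containers and every exact computation:
the one-step recursion, transient and equilibrium distributions, mean and
standard deviation of word age, and heterozygosity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import spsolve

from .errors import (
    CutoffError,
    MissingInitError,
    NegativeRateError,
    NegativeVarianceError,
    RowSumError,
    SingularityError,
    UnreachableError,
)

__all__ = [
    "DiffusionNetwork",
    "AgeDistribution",
    "AgeSummary",
    "TransientConfig",
    "validate_network",
    "step_distribution",
    "transient_age_distribution",
    "equilibrium_age_distribution",
    "equilibrium_mean",
    "mean_trajectory",
    "equilibrium_sd",
    "heterozygosity",
    "summarize",
]

#: Row sums must match 1 to this absolute tolerance.
ROW_SUM_TOL = 1e-12

#: Hard ceiling on the age cut-off search.
MAX_CUTOFF = 10**7

EQUILIBRIUM = "equilibrium"


@dataclass
class DiffusionNetwork:
    """Transmission structure of a centre-periphery population network.

    Parameters
    ----------
    source_rates
        Length-``n`` vector; entry ``k`` is the probability that a learner in
        peripheral population ``P(k+1)`` copies from the central population.
    A
        ``n x n`` matrix of peripheral transmission rates; ``A[i, j]`` is the
        probability that a learner in ``P(i+1)`` copies from ``P(j+1)``.
        Accepted dense or sparse; stored as CSR.
    labels
        Optional user-facing names for the peripheral populations.  Defaults
        to ``P1 .. Pn`` (the centre is ``P0`` and is not stored as a row).
    meta
        Free-form provenance notes (builder name, parameters, ...).
    """

    source_rates: np.ndarray
    A: sparse.csr_array
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.source_rates = np.asarray(self.source_rates, dtype=float).ravel()
        if not sparse.issparse(self.A):
            self.A = sparse.csr_array(np.atleast_2d(np.asarray(self.A, dtype=float)))
        else:
            self.A = sparse.csr_array(self.A).astype(float)
        if self.A.shape != (self.n, self.n):
            raise ValueError(
                f"A has shape {self.A.shape}, expected ({self.n}, {self.n})"
            )
        if self.labels is None:
            self.labels = [f"P{k + 1}" for k in range(self.n)]

    @property
    def n(self) -> int:
        """Number of peripheral populations."""
        return self.source_rates.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.source_rates + np.asarray(self.A.sum(axis=1)).ravel()


def validate_network(net: DiffusionNetwork) -> DiffusionNetwork:
    """Check rate ranges, row sums and reachability from the centre.

    Every learner's choice probabilities must form a distribution over the
    centre plus the periphery (rows sum to one), and every peripheral
    population must be reachable from the centre along positive-rate edges —
    otherwise no word ever arrives there and no equilibrium exists.

    Returns the network unchanged if all invariants hold.
    """
    A = net.A.toarray()
    if (net.source_rates < 0).any() or (A < 0).any():
        raise NegativeRateError("transmission rates must be non-negative")
    if (net.source_rates > 1 + ROW_SUM_TOL).any() or (A > 1 + ROW_SUM_TOL).any():
        raise NegativeRateError("transmission rates must not exceed one")
    sums = net.row_sums()
    bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
    if bad.size:
        names = ", ".join(f"{net.labels[k]} (sum={sums[k]:.15g})" for k in bad[:5])
        raise RowSumError(f"rows must sum to 1: {names}")

    # Directed reachability on the (n+1)-node graph with a virtual centre 0
    # and an edge j->i whenever a_ij > 0.  Equivalent to spectral radius of
    # A being < 1, but exact and cheap.
    n = net.n
    adj = sparse.lil_array((n + 1, n + 1))
    src = np.flatnonzero(net.source_rates > 0)
    adj[0, src + 1] = 1.0
    rows, cols = net.A.nonzero()
    adj[cols + 1, rows + 1] = 1.0  # edge transmitter -> receiver
    order = csgraph.breadth_first_order(
        sparse.csr_array(adj), i_start=0, directed=True, return_predecessors=False
    )
    reached = set(order.tolist())
    missing = [net.labels[k] for k in range(n) if (k + 1) not in reached]
    if missing:
        raise UnreachableError(
            "no transmission path from the centre to: " + ", ".join(missing)
        )
    return net


@dataclass
class AgeDistribution:
    """Per-population word-age frequencies up to a cut-off age.

    ``freqs[k, rho]`` is the frequency of the age-``rho`` variant in the
    peripheral population ``P(k+1)``; ages beyond ``rho_max`` are aggregated
    into ``tail_mass`` so that each population's total mass is exactly one.
    ``t`` is the time step the distribution refers to, or ``"equilibrium"``.
    """

    freqs: np.ndarray
    t: int | str
    tail_mass: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.atleast_2d(np.asarray(self.freqs, dtype=float))
        self.tail_mass = np.asarray(self.tail_mass, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.freqs.shape[0]

    @property
    def rho_max(self) -> int:
        """Largest stored age (inclusive)."""
        return self.freqs.shape[1] - 1

    def check(self, tol: float = 1e-12) -> None:
        if (self.freqs < -tol).any():
            raise ValueError("negative frequency")
        if (self.tail_mass < -tol).any():
            raise ValueError("negative tail mass")
        total = self.freqs.sum(axis=1) + self.tail_mass
        if np.abs(total - 1.0).max() > 1e-9:
            raise ValueError(f"mass not conserved: totals {total}")


@dataclass
class AgeSummary:
    """Equilibrium mean, SD and heterozygosity of word age per population."""

    mean: np.ndarray
    sd: np.ndarray
    heterozygosity: np.ndarray
    rho_max_used: int
    labels: list[str] | None = None
    tail_mass: np.ndarray | None = None


@dataclass
class TransientConfig:
    """Initial conditions and horizon for transient dynamics.

    ``r0`` is the vector of initial mean ages (used by the mean recursion);
    ``f0`` optionally gives the full initial age distribution of pre-existing
    variants, with column ``j`` holding the frequencies of age ``j + 1`` (the
    model defines initial mass only for ages >= 1 — the age-0 variant of step
    0 lives in the centre).  ``horizon`` is the number of steps to simulate.
    """

    r0: np.ndarray | None = None
    f0: np.ndarray | None = None
    horizon: int = 0

    def initial_means(self, n: int) -> np.ndarray:
        if self.r0 is None:
            return np.zeros(n)
        r0 = np.asarray(self.r0, dtype=float).ravel()
        if (r0 < 0).any():
            raise ValueError("initial mean ages must be non-negative")
        return r0


def step_distribution(net: DiffusionNetwork, dist: AgeDistribution) -> AgeDistribution:
    """Advance an age distribution by one transmission step.

    Each age-``rho`` frequency at ``t+1`` mixes the age-``rho-1`` frequencies
    of the source populations; the centre contributes a point mass at age 1
    (its variant is always brand new).  Mass ageing past the cut-off moves to
    the tail, and tail mass keeps circulating through ``A`` so that totals are
    conserved exactly.
    """
    f = dist.freqs
    new = np.zeros_like(f)
    new[:, 1:] = net.A @ f[:, :-1]
    new[:, 1] += net.source_rates
    tail = net.A @ (dist.tail_mass + f[:, -1])
    t = dist.t + 1 if isinstance(dist.t, int) else dist.t
    return AgeDistribution(freqs=new, t=t, tail_mass=tail)


def transient_age_distribution(
    net: DiffusionNetwork,
    cfg: TransientConfig,
    t: int,
    rho_max: int | None = None,
) -> AgeDistribution:
    """Age distribution at a finite time ``t`` after the centre emerges.

    Ages ``1..t`` carry the variants invented since emergence: the age-``rho``
    column is ``A^(rho-1) @ source_rates``, accumulated by repeated sparse
    application (never by eigendecomposition).  Ages above ``t`` are
    pre-existing variants propagated as ``A^t @ f0``; without ``cfg.f0`` that
    mass is unspecified and is reported as tail mass.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    f0 = None if cfg.f0 is None else np.atleast_2d(np.asarray(cfg.f0, dtype=float))
    if rho_max is None:
        rho_max = t if f0 is None else t + f0.shape[1]
    if rho_max > t and f0 is None:
        raise MissingInitError(
            f"ages above t={t} require an initial distribution (cfg.f0)"
        )

    n = net.n
    freqs = np.zeros((n, rho_max + 1))
    v = net.source_rates.copy()
    for rho in range(1, min(t, rho_max) + 1):
        freqs[:, rho] = v
        v = net.A @ v

    if f0 is not None:
        prop = f0.copy()
        for _ in range(t):
            prop = net.A @ prop
        stored = min(rho_max - t, prop.shape[1])
        if stored > 0:
            freqs[:, t + 1 : t + 1 + stored] = prop[:, :stored]
    tail = 1.0 - freqs.sum(axis=1)
    tail[np.abs(tail) < 1e-15] = 0.0
    return AgeDistribution(freqs=freqs, t=t, tail_mass=tail)


def _eye_minus_a(net: DiffusionNetwork) -> sparse.csc_array:
    return sparse.csc_array(sparse.eye_array(net.n) - net.A)


def spsolve_eye_minus_a(net: DiffusionNetwork, rhs: np.ndarray) -> np.ndarray:
    """Solve ``(E - A) x = rhs`` by sparse LU, raising on singularity."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", sparse.linalg.MatrixRankWarning)
        try:
            x = spsolve(_eye_minus_a(net), rhs)
        except (RuntimeError, sparse.linalg.MatrixRankWarning) as exc:
            raise SingularityError(f"(E - A) is singular: {exc}") from exc
    x = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise SingularityError("(E - A) solve returned non-finite values")
    return x


def equilibrium_age_distribution(
    net: DiffusionNetwork,
    rho_max: int | None = None,
    tail_tol: float | None = None,
) -> AgeDistribution:
    """Equilibrium age distribution up to a cut-off.

    The age-``rho`` column is ``A^(rho-1) @ source_rates``; summed over all
    ages this telescopes to ``(E - A)^{-1} @ source_rates``, which equals the
    all-ones vector for a valid network, so per-population mass is conserved.
    Either give ``rho_max`` explicitly, or give ``tail_tol`` to grow the
    cut-off until every population's unaccounted tail falls below it
    (default ``tail_tol = 1e-9``).
    """
    if rho_max is None and tail_tol is None:
        tail_tol = 1e-9
    n = net.n
    cols: list[np.ndarray] = [np.zeros(n)]
    v = net.source_rates.copy()
    remaining = np.ones(n)
    rho = 0
    while True:
        rho += 1
        cols.append(v.copy())
        remaining = remaining - v
        if rho_max is not None and rho >= rho_max:
            break
        if tail_tol is not None and rho_max is None and remaining.max() < tail_tol:
            break
        if rho >= MAX_CUTOFF:
            raise CutoffError(
                f"cut-off reached {MAX_CUTOFF} with max tail {remaining.max():.3g}"
            )
        v = net.A @ v
    tail = np.clip(remaining, 0.0, None)
    return AgeDistribution(freqs=np.column_stack(cols), t=EQUILIBRIUM, tail_mass=tail)


def equilibrium_mean(net: DiffusionNetwork) -> np.ndarray:
    """Equilibrium mean word age ``r``: the solution of ``(E - A) r = 1``.

    This is the expected number of steps since invention for a variant drawn
    at random from each population; it grows with network distance from the
    centre and is the model's main prediction.
    """
    return spsolve_eye_minus_a(net, np.ones(net.n))


def mean_trajectory(net: DiffusionNetwork, cfg: TransientConfig) -> np.ndarray:
    """Mean word age over time, ``r(t) = A r(t-1) + 1`` from ``r(0) = r0``.

    Returns an ``(horizon + 1, n)`` array whose row ``t`` is ``r(t)``.  The
    recursion is algebraically identical to the closed form
    ``A^t (r0 - r_inf) + r_inf`` and converges to :func:`equilibrium_mean`.
    """
    r = cfg.initial_means(net.n)
    out = np.empty((cfg.horizon + 1, net.n))
    out[0] = r
    for t in range(1, cfg.horizon + 1):
        r = net.A @ r + 1.0
        out[t] = r
    return out


def equilibrium_sd(net: DiffusionNetwork) -> np.ndarray:
    """Equilibrium standard deviation of word age per population.

    A learner's new variant is one step older than its role model's, so the
    equilibrium second moment ``m`` satisfies ``(E - A) m = 2 A r + 1`` with
    ``r`` the equilibrium mean; the SD is ``sqrt(m - r^2)`` elementwise.
    """
    r = equilibrium_mean(net)
    m = spsolve_eye_minus_a(net, 2.0 * (net.A @ r) + 1.0)
    var = m - r**2
    if (var < -1e-9).any():
        raise NegativeVarianceError(
            f"negative variance {var.min():.3g}: numerical failure in moment solve"
        )
    return np.sqrt(np.clip(var, 0.0, None))


def heterozygosity(dist: AgeDistribution) -> np.ndarray:
    """Probability that two randomly sampled variants differ, ``1 - sum f^2``.

    The analogue of genetic heterozygosity at one locus; variant identity is
    the age.  Summed to the distribution's stored cut-off, so a non-negligible
    tail biases the value upward (a warning is issued above 1e-6).
    """
    if dist.tail_mass.max() > 1e-6:
        warnings.warn(
            f"tail mass up to {dist.tail_mass.max():.3g} ignored by the "
            "heterozygosity sum; increase the cut-off",
            stacklevel=2,
        )
    return 1.0 - (dist.freqs**2).sum(axis=1)


def summarize(
    net: DiffusionNetwork,
    rho_max: int | None = None,
    tail_tol: float | None = None,
) -> AgeSummary:
    """Equilibrium mean, SD and heterozygosity in one pass.

    Mean and SD come from exact linear solves; heterozygosity needs the full
    distribution and uses the cut-off policy of
    :func:`equilibrium_age_distribution`.
    """
    dist = equilibrium_age_distribution(net, rho_max=rho_max, tail_tol=tail_tol)
    return AgeSummary(
        mean=equilibrium_mean(net),
        sd=equilibrium_sd(net),
        heterozygosity=heterozygosity(dist),
        rho_max_used=dist.rho_max,
        labels=list(net.labels) if net.labels else None,
        tail_mass=dist.tail_mass,
    )
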