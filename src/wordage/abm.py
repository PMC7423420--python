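"""Finite-population agent-based simulator of centre-periphery word diffusion.

The deterministic model assumes infinitely large populations; this module
drops that assumption.  Each peripheral population ``Pk`` holds ``N_k``
agents.  Every step, each agent independently picks a source population
according to its row of transmission rates (the centre included), then copies
a uniformly chosen role model from that population's previous-step state; all
updates are synchronous.  The central population always consists of the
variant invented that very step, so the copied variant is one step older by
the time it is expressed.

Variant identity is the invention step (no mutation), so two agents share a
variant exactly when their current ages coincide with the same birth step.
Finite ``N`` adds cultural drift: per-step population means fluctuate around
the deterministic trajectory, and heterozygosity is depressed by sampling.
Expected mean ages remain exactly those of the deterministic recursion, which
makes the simulator a direct stochastic check of the equilibrium solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DiffusionNetwork

__all__ = ["AbmConfig", "AbmRun", "run_abm", "abm_summaries"]


@dataclass
class AbmConfig:
    """Simulation settings.

    ``sizes`` gives the agent count of each peripheral population (length
    must match the network); ``horizon`` the number of steps; ``replicates``
    the number of independent runs; ``seed`` the master RNG seed, from which
    each replicate draws a deterministic substream.  ``record`` selects the
    per-step summaries to keep.
    """

    sizes: Sequence[int]
    horizon: int
    replicates: int = 1
    seed: int = 0
    record: tuple[str, ...] = ("mean_age", "sd_age", "heterozygosity", "n_variants")

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if (self.sizes < 1).any():
            raise ValueError("population sizes must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.record) - {
            "mean_age",
            "sd_age",
            "heterozygosity",
            "n_variants",
        }
        if unknown:
            raise ValueError(f"unknown record fields: {sorted(unknown)}")


@dataclass
class AbmRun:
    """Result container: per-step summary table and final agent states.

    ``table`` is long-format with columns ``replicate, step, node`` plus the
    recorded summaries; ``final_ages`` holds, per replicate, the final
    variant-age array of each population.  Per-agent history is never stored.
    """

    config: AbmConfig
    labels: list[str]
    table: pd.DataFrame
    final_ages: list[list[np.ndarray]] = field(repr=False, default_factory=list)


def _replicate_seeds(seed: int, replicates: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(replicates)


def run_abm(net: DiffusionNetwork, cfg: AbmConfig) -> AbmRun:
    """Run the agent-based simulation; fully reproducible given ``cfg.seed``.

    Agents start holding the variant invented at step 0.  Each step is
    vectorized: source populations are drawn by inverse-CDF lookup on the
    learner's rate row, and role models by uniform index into the previous
    state (the centre contributing a single age-0 "agent").
    """
    n = net.n
    sizes = np.asarray(cfg.sizes, dtype=np.int64)
    if sizes.shape[0] != n:
        raise ValueError(f"sizes has length {sizes.shape[0]}, network has n={n}")

    # cumulative choice distribution over (centre, P1..Pn) per learner row
    rows = np.column_stack([net.source_rates, net.A.toarray()])
    cum = np.cumsum(rows, axis=1)
    cum[:, -1] = 1.0  # guard against rounding at the top end

    # previous-step states are read through one concatenated array whose
    # first entry is the centre's (always age 0); offsets locate each pop
    pool_sizes = np.concatenate([[1], sizes])
    offsets = np.concatenate([[0], np.cumsum(pool_sizes)])[:-1]

    want = set(cfg.record)
    records: list[tuple] = []
    final_ages: list[list[np.ndarray]] = []

    for rep, seq in enumerate(_replicate_seeds(cfg.seed, cfg.replicates)):
        rng = np.random.default_rng(seq)
        ages = [np.zeros(sizes[k], dtype=np.int64) for k in range(n)]
        for step in range(1, cfg.horizon + 1):
            pool = np.concatenate([np.zeros(1, dtype=np.int64), *ages])
            new_ages = []
            for k in range(n):
                src = np.searchsorted(cum[k], rng.random(sizes[k]), side="right")
                pick = (rng.random(sizes[k]) * pool_sizes[src]).astype(np.int64)
                new_ages.append(pool[offsets[src] + pick] + 1)
            ages = new_ages
            for k in range(n):
                rec: list = [rep, step, net.labels[k]]
                a = ages[k]
                if "mean_age" in want:
                    rec.append(a.mean())
                if "sd_age" in want:
                    rec.append(a.std())
                if "heterozygosity" in want or "n_variants" in want:
                    counts = np.bincount(a)
                    if "heterozygosity" in want:
                        p = counts / sizes[k]
                        rec.append(1.0 - (p**2).sum())
                    if "n_variants" in want:
                        rec.append(int((counts > 0).sum()))
                records.append(tuple(rec))
        final_ages.append(ages)

    columns = ["replicate", "step", "node"] + [
        c
        for c in ("mean_age", "sd_age", "heterozygosity", "n_variants")
        if c in want
    ]
    table = pd.DataFrame.from_records(records, columns=columns)
    return AbmRun(config=cfg, labels=list(net.labels), table=table, final_ages=final_ages)


def abm_summaries(run: AbmRun, burn_in: int = 0) -> pd.DataFrame:
    """Time-averaged per-population statistics with across-replicate SEs.

    Steps ``<= burn_in`` are discarded as equilibration.  Each recorded
    summary is averaged over the remaining steps within each replicate; the
    returned table reports the across-replicate mean and standard error
    (sample SD over replicates divided by ``sqrt(R)``; zero for ``R = 1``).
    """
    if burn_in >= run.config.horizon:
        raise ValueError("burn_in must leave at least one recorded step")
    df = run.table[run.table["step"] > burn_in]
    value_cols = [c for c in df.columns if c not in ("replicate", "step", "node")]
    per_rep = df.groupby(["node", "replicate"], sort=False)[value_cols].mean()
    grouped = per_rep.groupby("node", sort=False)
    mean = grouped.mean()
    R = run.config.replicates
    se = grouped.std(ddof=1).fillna(0.0) / np.sqrt(R) if R > 1 else mean * 0.0
    out = mean.join(se, rsuffix="_se").reset_index()
    # preserve network node order
    order = {lab: i for i, lab in enumerate(run.labels)}
    return out.sort_values("node", key=lambda s: s.map(order)).reset_index(drop=True)
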