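"""Tabular I/O: edge-list network files, summary and distribution CSVs.

The edge-list format has columns ``from,to,rate``, one row per directed
transmission channel: ``rate`` is the probability that a learner in the
``to`` population copies a role model in the ``from`` population.  The label
``P0`` is reserved for the central population.  Self-rates must be explicit
(a row with ``from == to``) unless loading with ``complete_diagonal=True``,
which fills each missing self-rate with one minus the row's off-diagonal sum.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import AgeDistribution, AgeSummary, DiffusionNetwork, validate_network

__all__ = [
    "write_edgelist",
    "load_edgelist",
    "write_summary",
    "write_distribution",
]

CENTER_LABEL = "P0"


def write_edgelist(net: DiffusionNetwork, path: str | Path) -> None:
    """Serialize a network to ``from,to,rate`` CSV (self-rates explicit)."""
    rows = []
    for k in range(net.n):
        if net.source_rates[k] > 0:
            rows.append((CENTER_LABEL, net.labels[k], net.source_rates[k]))
    A = net.A.tocoo()
    for i, j, rate in zip(A.row, A.col, A.data):
        if rate != 0.0:
            rows.append((net.labels[j], net.labels[i], rate))
    pd.DataFrame(rows, columns=["from", "to", "rate"]).to_csv(path, index=False)


def load_edgelist(
    path: str | Path, complete_diagonal: bool = False
) -> DiffusionNetwork:
    """Read a ``from,to,rate`` CSV into a validated network.

    Peripheral populations are ordered by first appearance in the file
    (scanning the ``to`` column, then ``from``); ``P0`` is the centre and
    never appears as a receiver.
    """
    df = pd.read_csv(path)
    missing = {"from", "to", "rate"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    if (df["to"] == CENTER_LABEL).any():
        raise ValueError(f"{CENTER_LABEL} is the centre and cannot receive words")

    labels: list[str] = []
    for col in ("to", "from"):
        for lab in df[col]:
            if lab != CENTER_LABEL and lab not in labels:
                labels.append(lab)
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)

    source = np.zeros(n)
    A = np.zeros((n, n))
    for src, dst, rate in zip(df["from"], df["to"], df["rate"]):
        i = index[dst]
        if src == CENTER_LABEL:
            source[i] += rate
        else:
            A[i, index[src]] += rate

    if complete_diagonal:
        for k in range(n):
            if A[k, k] == 0.0:
                A[k, k] = 1.0 - source[k] - (A[k].sum() - A[k, k])
    net = DiffusionNetwork(
        source_rates=source, A=A, labels=labels, meta={"builder": "edgelist", "path": str(path)}
    )
    return validate_network(net)


def write_summary(summary: AgeSummary, path: str | Path) -> None:
    """Write ``node,mean_age,sd_age,heterozygosity,tail_mass`` CSV."""
    n = summary.mean.shape[0]
    labels = summary.labels or [f"P{k + 1}" for k in range(n)]
    tail = summary.tail_mass if summary.tail_mass is not None else np.zeros(n)
    pd.DataFrame(
        {
            "node": labels,
            "mean_age": summary.mean,
            "sd_age": summary.sd,
            "heterozygosity": summary.heterozygosity,
            "tail_mass": tail,
        }
    ).to_csv(path, index=False)


def write_distribution(
    dist: AgeDistribution, labels: list[str], path: str | Path
) -> None:
    """Write the full age distribution as long-format ``node,age,frequency``."""
    n, width = dist.freqs.shape
    pd.DataFrame(
        {
            "node": np.repeat(labels, width),
            "age": np.tile(np.arange(width), n),
            "frequency": dist.freqs.ravel(),
        }
    ).to_csv(path, index=False)
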