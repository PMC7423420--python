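"""Geographic network builder: interaction-density (modified gravity) model.

Given a table of labelled nodes with coordinates and population sizes, the
interaction density between two nodes is a gravity-style weight

    phi_ij = pi_i * pi_j / (1 + d_ij^2 / gamma^2)     (population-dependent)
    phi_ij = 1 / (1 + d_ij^2 / gamma^2)               (population-independent)

where ``d_ij`` is the great-circle distance between the nodes and ``gamma``
is the half-decay distance — the distance at which interaction falls to half
its same-place value.  Row-normalizing phi turns it into transmission rates:
a learner in ``Pi`` copies from ``Pj`` with probability proportional to the
time spent interacting with ``Pj``'s speakers, including ``Pi`` itself
(``phi_ii`` with ``d = 0``).  In the population-dependent mode this
self-interaction makes populous nodes self-absorbing, so they act as
conservative barriers to incoming novelty.

A 46-row table of Japanese prefectures (prefectural-office coordinates, 2018
population estimates, Okinawa excluded, Kyoto central) ships with the package
for the concentric-dialect use case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DiffusionNetwork, validate_network
from .errors import CoordinateRangeError, ZeroRowError

__all__ = [
    "GeoNodeTable",
    "GravityConfig",
    "great_circle_distance",
    "interaction_density",
    "to_transmission_rates",
    "build_geo_network",
    "load_node_table",
    "japan_prefectures",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class GeoNodeTable:
    """Labelled geographic nodes with population sizes and a designated centre.

    ``nodes`` must have columns ``label``, ``lat``, ``lon``, ``population``;
    labels are unique and ``center_label`` names one of them.
    """

    nodes: pd.DataFrame
    center_label: str

    def __post_init__(self) -> None:
        required = {"label", "lat", "lon", "population"}
        missing = required - set(self.nodes.columns)
        if missing:
            raise ValueError(f"node table missing columns: {sorted(missing)}")
        self.nodes = self.nodes.reset_index(drop=True)
        if self.nodes["label"].duplicated().any():
            dup = self.nodes.loc[self.nodes["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate labels: {dup}")
        if self.center_label not in set(self.nodes["label"]):
            raise ValueError(f"center label {self.center_label!r} not in table")
        lat = self.nodes["lat"].to_numpy(float)
        lon = self.nodes["lon"].to_numpy(float)
        if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
            raise CoordinateRangeError("lat must be in [-90, 90], lon in [-180, 180]")
        if (self.nodes["population"].to_numpy(float) <= 0).any():
            raise ValueError("population sizes must be positive")

    @property
    def center_index(self) -> int:
        return int(self.nodes.index[self.nodes["label"] == self.center_label][0])

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class GravityConfig:
    """Parameters of the interaction-density model.

    ``gamma`` is the half-decay distance in km; ``mode`` selects whether the
    density carries the population-size product; ``earth_radius_km`` feeds
    the great-circle computation.
    """

    gamma: float
    mode: str = "population_dependent"
    earth_radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.mode not in ("population_dependent", "population_independent"):
            raise ValueError(f"unknown mode {self.mode!r}")


def great_circle_distance(
    p: tuple[float, float],
    q: tuple[float, float],
    earth_radius_km: float = EARTH_RADIUS_KM,
) -> float:
    """Shortest surface distance in km between two (lat, lon) points.

    Haversine formula on a sphere; symmetric, non-negative, zero only for
    identical points, and ``pi * R`` for antipodal ones.
    """
    for lat, lon in (p, q):
        if abs(lat) > 90 or abs(lon) > 180:
            raise CoordinateRangeError(f"invalid coordinate ({lat}, {lon})")
    la1, lo1 = np.radians(p)
    la2, lo2 = np.radians(q)
    h = (
        np.sin((la2 - la1) / 2.0) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2.0) ** 2
    )
    return float(2.0 * earth_radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def _distance_matrix(table: GeoNodeTable, earth_radius_km: float) -> np.ndarray:
    lat = np.radians(table.nodes["lat"].to_numpy(float))
    lon = np.radians(table.nodes["lon"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(
        dlon / 2
    ) ** 2
    return 2.0 * earth_radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def interaction_density(table: GeoNodeTable, cfg: GravityConfig) -> np.ndarray:
    """Symmetric matrix of pairwise interaction densities over all nodes.

    Diagonal entries use ``d = 0`` (``pi_i^2`` or 1), which is what lets a
    large population absorb most of its own learners after normalization.
    """
    d = _distance_matrix(table, cfg.earth_radius_km)
    phi = 1.0 / (1.0 + d**2 / cfg.gamma**2)
    if cfg.mode == "population_dependent":
        pop = table.nodes["population"].to_numpy(float)
        phi = np.outer(pop, pop) * phi
    return phi


def to_transmission_rates(
    phi: np.ndarray,
    center_index: int,
    labels: list[str] | None = None,
    meta: dict | None = None,
) -> DiffusionNetwork:
    """Row-normalize an interaction-density matrix into a diffusion network.

    ``a_ij = phi_ij / sum_l phi_il`` over every node including the centre and
    the learner's own population.  The centre's row is dropped (it learns
    from nobody); its column becomes the source-rate vector.
    """
    phi = np.asarray(phi, dtype=float)
    if (phi < 0).any():
        raise ValueError("interaction densities must be non-negative")
    totals = phi.sum(axis=1)
    if (totals <= 0).any():
        bad = np.flatnonzero(totals <= 0).tolist()
        raise ZeroRowError(f"rows with zero total interaction: {bad}")
    rates = phi / totals[:, None]
    keep = [i for i in range(phi.shape[0]) if i != center_index]
    source = rates[keep, center_index]
    A = rates[np.ix_(keep, keep)]
    out_labels = [labels[i] for i in keep] if labels is not None else None
    net = DiffusionNetwork(
        source_rates=source, A=A, labels=out_labels, meta=dict(meta or {})
    )
    return validate_network(net)


def build_geo_network(table: GeoNodeTable, cfg: GravityConfig) -> DiffusionNetwork:
    """Interaction densities + normalization in one call; records cfg in meta."""
    phi = interaction_density(table, cfg)
    return to_transmission_rates(
        phi,
        table.center_index,
        labels=table.nodes["label"].tolist(),
        meta={
            "builder": "gravity",
            "gamma": cfg.gamma,
            "mode": cfg.mode,
            "earth_radius_km": cfg.earth_radius_km,
            "center": table.center_label,
        },
    )


def load_node_table(path: str | Path, center_label: str) -> GeoNodeTable:
    """Read a ``label,lat,lon,population`` CSV into a :class:`GeoNodeTable`."""
    return GeoNodeTable(nodes=pd.read_csv(path), center_label=center_label)


def japan_prefectures() -> GeoNodeTable:
    """The bundled 46-prefecture table (Okinawa excluded), Kyoto central.

    Coordinates are prefectural-office locations in decimal degrees;
    populations are 2018 estimates in thousands (only ratios matter for the
    transmission rates).
    """
    with resources.files("wordage.data").joinpath("japan_prefectures.csv").open() as fh:
        nodes = pd.read_csv(fh)
    return GeoNodeTable(nodes=nodes, center_label="Kyoto")
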