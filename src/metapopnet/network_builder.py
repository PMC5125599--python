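"""Aggregation of dispersal events into directed population networks and covariate matrices.

Populations are nodes; the directed weight ``W[i, j]`` counts dispersal events
from population i to population j within a temporal window (an event is
attributed to the calendar year of its arrival observation). Within-population
events never enter ``W``: they are kept in per-population ``self_counts`` so the
type invariant ``W.sum() + self_counts.sum() == number of events`` holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geo import haversine_km
from .records_io import Population, check_unique_names
from .dispersal_extraction import TemporalClassScheme, DEFAULT_SCHEME

__all__ = [
    "DispersalNetwork",
    "CovariateMatrices",
    "build_network",
    "node_strength",
    "build_covariates",
]


@dataclass(frozen=True)
class DispersalNetwork:
    """Directed event-count network over populations for one temporal window."""

    populations: tuple[str, ...]
    W: np.ndarray
    self_counts: np.ndarray
    temporal_class: str = "total"

    def __post_init__(self) -> None:
        n = len(self.populations)
        W = np.asarray(self.W)
        if W.shape != (n, n):
            raise ValueError("W shape does not match populations")
        if np.any(W < 0) or np.any(np.diag(W) != 0):
            raise ValueError("W must be non-negative with zero diagonal")
        if np.asarray(self.self_counts).shape != (n,):
            raise ValueError("self_counts shape does not match populations")

    @property
    def n_events(self) -> int:
        return int(self.W.sum() + np.sum(self.self_counts))

    def index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise ValueError(f"unknown population {population!r}") from None


@dataclass(frozen=True)
class CovariateMatrices:
    """Symmetric pairwise covariates: centroid distance (km), absolute breeding
    density difference (pairs per 100 km^2) and symmetrized exchange counts."""

    populations: tuple[str, ...]
    distance: np.ndarray
    density_diff: np.ndarray
    exchange: np.ndarray


def build_network(
    events: pd.DataFrame,
    populations: Sequence[Population],
    temporal_class: str = "total",
) -> DispersalNetwork:
    """Count dispersal events into a directed network for one temporal class or ``"total"``."""
    check_unique_names(populations)
    names = tuple(p.name for p in populations)
    idx = {name: i for i, name in enumerate(names)}
    n = len(names)
    W = np.zeros((n, n), dtype=int)
    self_counts = np.zeros(n, dtype=int)
    if len(events):
        sel = events if temporal_class == "total" else events[events["temporal_class"] == temporal_class]
        for frm, to in zip(sel["from_population"], sel["to_population"]):
            if frm not in idx or to not in idx:
                raise ValueError(f"event names unknown population: {frm!r} -> {to!r}")
            if frm == to:
                self_counts[idx[frm]] += 1
            else:
                W[idx[frm], idx[to]] += 1
    return DispersalNetwork(names, W, self_counts, temporal_class)


def node_strength(network: DispersalNetwork, population: str) -> int:
    """Total between-population events touching ``population`` (in + out; self events excluded)."""
    i = network.index(population)
    return int(network.W[i, :].sum() + network.W[:, i].sum())


def build_covariates(
    populations: Sequence[Population],
    network: DispersalNetwork,
    scheme: TemporalClassScheme = DEFAULT_SCHEME,
) -> CovariateMatrices:
    """Pairwise covariate matrices for the window the network was built on.

    Density is the window mean of yearly breeding pairs per 100 km^2; a
    missing pair count for any window year is an error naming the years.
    """
    check_unique_names(populations)
    names = tuple(p.name for p in populations)
    if names != network.populations:
        raise ValueError("population list does not match network ordering")
    years = scheme.years if network.temporal_class == "total" else scheme.years_of(network.temporal_class)
    dens = np.array([p.density(years) for p in populations])
    n = len(names)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(populations[i].lat, populations[i].lon, populations[j].lat, populations[j].lon)
            dist[i, j] = dist[j, i] = d
    density_diff = np.abs(dens[:, None] - dens[None, :])
    exchange = network.W + network.W.T
    return CovariateMatrices(names, dist, density_diff, exchange.astype(float))
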