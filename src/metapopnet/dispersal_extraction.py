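"""Turning per-individual observation histories into dispersal events.

A dispersal event is a movement of a breeding adult of more than a threshold
distance (default 5 km, strict inequality) between its current breeding-season
location and a reference location: the natal nest for the first qualifying
resighting (natal dispersal), or the location of the previous breeding-season
resighting afterwards (breeding dispersal). Only resightings falling inside
the breeding window (default April 15 - July 15 inclusive) and at calendar-year
age >= 4 (observation year minus ringing year; storks are ringed as nestlings,
so hatch year equals ring year) qualify - younger birds move erratically and
are not breeders.

The reference chain advances with every qualifying resighting, including moves
at or below the threshold: the bird's current nest is always the reference for
the next season, whether or not the last move counted as dispersal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geo import haversine_km
from .records_io import Population, check_unique_names, dedupe_seasonal_resights, assign_population

__all__ = [
    "DataError",
    "TemporalClassScheme",
    "DEFAULT_SCHEME",
    "DEFAULT_WINDOW",
    "compute_distance_km",
    "in_breeding_window",
    "assign_temporal_class",
    "extract_dispersal_events",
    "EVENT_COLUMNS",
]

DEFAULT_WINDOW = ((4, 15), (7, 15))

EVENT_COLUMNS = [
    "individual_id",
    "from_population",
    "to_population",
    "from_lat",
    "from_lon",
    "to_lat",
    "to_lon",
    "distance_km",
    "kind",
    "year",
    "temporal_class",
    "scope",
]


class DataError(ValueError):
    """Observation history violates a structural precondition."""


@dataclass(frozen=True)
class TemporalClassScheme:
    """Ordered, non-overlapping inclusive year ranges partitioning the study period."""

    classes: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("temporal class scheme must be non-empty")
        prev_last = None
        for label, first, last in self.classes:
            if first > last:
                raise ValueError(f"class {label}: first year after last year")
            if prev_last is not None and first <= prev_last:
                raise ValueError(f"class {label}: overlaps or is out of order")
            prev_last = last

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.classes)

    @property
    def years(self) -> range:
        return range(self.classes[0][1], self.classes[-1][2] + 1)

    def years_of(self, label: str) -> range:
        for lab, first, last in self.classes:
            if lab == label:
                return range(first, last + 1)
        raise ValueError(f"unknown temporal class {label!r}")

    def class_of(self, year: int) -> str:
        for label, first, last in self.classes:
            if first <= year <= last:
                return label
        raise ValueError(f"year {year} outside temporal class scheme")


#: The study design: one long early window (few marked birds) then four
#: three-year windows.
DEFAULT_SCHEME = TemporalClassScheme(
    (
        ("1988-1996", 1988, 1996),
        ("1997-1999", 1997, 1999),
        ("2000-2002", 2000, 2002),
        ("2003-2005", 2003, 2005),
        ("2006-2008", 2006, 2008),
    )
)


def compute_distance_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points."""
    return haversine_km(a[0], a[1], b[0], b[1])


def assign_temporal_class(year: int, scheme: TemporalClassScheme = DEFAULT_SCHEME) -> str:
    """Label of the temporal class containing ``year``; error outside coverage."""
    return scheme.class_of(int(year))


def in_breeding_window(dates: pd.Series, window=DEFAULT_WINDOW) -> pd.Series:
    """Boolean mask of dates whose (month, day) falls inside the inclusive window."""
    (m0, d0), (m1, d1) = window
    md = dates.dt.month * 100 + dates.dt.day
    return (md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)


def extract_dispersal_events(
    records: pd.DataFrame,
    populations: Sequence[Population],
    threshold_km: float = 5.0,
    breeding_window=DEFAULT_WINDOW,
    min_age_years: int = 4,
    scheme: TemporalClassScheme = DEFAULT_SCHEME,
    dedupe: bool = True,
) -> pd.DataFrame:
    """Extract dispersal events from an observation table.

    ``records`` must contain one ring record per individual; population labels
    are filled by nearest centroid where absent. Returns a DataFrame with
    :data:`EVENT_COLUMNS`, one row per movement strictly greater than
    ``threshold_km`` between a qualifying adult breeding-season resighting and
    its reference location. ``scope`` is ``within`` when source and destination
    population coincide, else ``between``.
    """
    check_unique_names(populations)
    if records.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    if records["population"].isna().any():
        records = assign_population(records, populations, rule="nearest_centroid")
    known = {p.name for p in populations}
    bad = sorted(set(records["population"]) - known)
    if bad:
        raise DataError(f"records assigned to unknown populations: {bad}")
    if dedupe:
        records = dedupe_seasonal_resights(records, breeding_window)

    records = records.sort_values(["individual_id", "date"], kind="mergesort").reset_index(drop=True)
    dates = pd.to_datetime(records["date"])
    year = dates.dt.year
    is_ring = (records["event_type"] == "ring").to_numpy()

    ring_counts = records.loc[is_ring].groupby("individual_id").size()
    all_ids = records["individual_id"].unique()
    bad_counts = ring_counts.reindex(all_ids, fill_value=0)
    offenders = bad_counts[bad_counts != 1]
    if len(offenders):
        ind, cnt = offenders.index[0], int(offenders.iloc[0])
        raise DataError(f"individual {ind}: expected exactly one ring record, found {cnt}")

    rings = records.loc[is_ring].set_index("individual_id")
    ring_date = rings["date"].reindex(records["individual_id"]).to_numpy()
    if (dates.to_numpy() < ring_date).any():
        first_bad = records.loc[dates.to_numpy() < ring_date, "individual_id"].iloc[0]
        raise DataError(f"individual {first_bad}: resighting before ringing")

    ring_year = rings["date"].dt.year.reindex(records["individual_id"]).to_numpy()
    qualifies = (
        (~is_ring)
        & in_breeding_window(dates, breeding_window).to_numpy()
        & (year.to_numpy() - ring_year >= min_age_years)
    )
    adult = records.loc[qualifies].copy()
    if adult.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    adult["_year"] = year[qualifies]

    # the reference chain is: natal nest, then every qualifying resighting in
    # turn (whether or not the move exceeded the threshold), so each event
    # candidate is simply a consecutive pair along that chain
    grp = adult.groupby("individual_id", sort=False)
    prev_lat = grp["lat"].shift(1)
    prev_lon = grp["lon"].shift(1)
    prev_pop = grp["population"].shift(1)
    first = prev_lat.isna()
    ids = adult["individual_id"]
    prev_lat = prev_lat.where(~first, rings["lat"].reindex(ids).to_numpy())
    prev_lon = prev_lon.where(~first, rings["lon"].reindex(ids).to_numpy())
    prev_pop = prev_pop.where(~first, rings["population"].reindex(ids).to_numpy())

    dist = haversine_km(
        prev_lat.to_numpy(dtype=float),
        prev_lon.to_numpy(dtype=float),
        adult["lat"].to_numpy(dtype=float),
        adult["lon"].to_numpy(dtype=float),
    )
    keep = dist > threshold_km
    events = pd.DataFrame(
        {
            "individual_id": ids[keep].to_numpy(),
            "from_population": prev_pop[keep].to_numpy(),
            "to_population": adult.loc[keep, "population"].to_numpy(),
            "from_lat": prev_lat[keep].to_numpy(dtype=float),
            "from_lon": prev_lon[keep].to_numpy(dtype=float),
            "to_lat": adult.loc[keep, "lat"].to_numpy(dtype=float),
            "to_lon": adult.loc[keep, "lon"].to_numpy(dtype=float),
            "distance_km": dist[keep],
            "kind": np.where(first[keep], "natal", "breeding"),
            "year": adult.loc[keep, "_year"].to_numpy(dtype=int),
        }
    )
    events["temporal_class"] = [scheme.class_of(y) for y in events["year"]]
    events["scope"] = np.where(events["from_population"] == events["to_population"], "within", "between")
    return events[EVENT_COLUMNS].reset_index(drop=True)
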