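"""Reading, validating and writing mark-resight observation tables and analysis outputs.

The canonical observation table is a CSV with columns
``individual_id, event_type, date, lat, lon, population`` where
``event_type`` is ``ring`` (nestling marking) or ``resight`` (later
re-observation), ``date`` is ISO-8601, coordinates are decimal degrees and
``population`` is optional. In memory it is a pandas DataFrame sorted by
(individual_id, date).

Malformed rows are never dropped silently: :func:`read_observations` returns
the parsed table together with a rejects table carrying one reason per bad
row, and parsed + rejected always equals the number of input rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .geo import haversine_km

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["individual_id", "event_type", "date", "lat", "lon", "population"]
EVENT_TYPES = ("ring", "resight")

__all__ = [
    "OBS_COLUMNS",
    "FormatError",
    "Population",
    "ReadResult",
    "read_observations",
    "write_observations",
    "assign_population",
    "dedupe_seasonal_resights",
    "write_outputs",
    "read_results_json",
    "import_study_xlsx",
]


class FormatError(ValueError):
    """Input file does not have the expected structure (e.g. missing headers)."""


@dataclass(frozen=True)
class Population:
    """A geographical population: a named centroid with an area and yearly breeding-pair counts.

    ``pair_counts`` maps calendar year to the number of breeding pairs counted
    that year; densities are expressed as pairs per 100 km^2.
    """

    name: str
    lat: float
    lon: float
    area_km2: float
    pair_counts: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("population name must be non-empty")
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"population {self.name}: centroid out of range")
        if not (self.area_km2 > 0):
            raise ValueError(f"population {self.name}: area_km2 must be > 0")

    def density(self, years: Iterable[int]) -> float:
        """Mean breeding-pair density over ``years``, in pairs per 100 km^2."""
        years = list(years)
        missing = [y for y in years if y not in self.pair_counts]
        if missing:
            raise ValueError(f"population {self.name}: missing pair counts for years {missing}")
        mean_pairs = float(np.mean([self.pair_counts[y] for y in years]))
        return mean_pairs / (self.area_km2 / 100.0)


def check_unique_names(populations: Sequence[Population]) -> None:
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValueError(f"population names not unique: {names}")


class ReadResult(NamedTuple):
    records: pd.DataFrame
    rejects: pd.DataFrame


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": pd.Series(dtype=str),
            "event_type": pd.Series(dtype=str),
            "date": pd.Series(dtype="datetime64[ns]"),
            "lat": pd.Series(dtype=float),
            "lon": pd.Series(dtype=float),
            "population": pd.Series(dtype=object),
        }
    )


def read_observations(path: str | Path, dayfirst: bool = False) -> ReadResult:
    """Read an observation CSV into a validated, sorted record table.

    Returns ``(records, rejects)``; rejects carry the original row payload
    plus a human-readable ``reason``. Raises :class:`FormatError` when
    required headers are absent. ``dayfirst=True`` enables a d/m/Y import
    shim for legacy exports; the canonical format is ISO-8601.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in OBS_COLUMNS if c != "population"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if "population" not in raw.columns:
        raw["population"] = ""

    reasons = np.full(len(raw), "", dtype=object)

    etype = raw["event_type"].str.strip().str.lower()
    bad = ~etype.isin(EVENT_TYPES)
    reasons[bad.to_numpy() & (reasons == "")] = "unknown event_type"

    date = pd.to_datetime(raw["date"], errors="coerce", dayfirst=dayfirst, format="mixed")
    reasons[(date.isna()).to_numpy() & (reasons == "")] = "unparsable date"

    lat = pd.to_numeric(raw["lat"], errors="coerce")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    reasons[lat.isna().to_numpy() & (reasons == "")] = "unparsable latitude"
    reasons[lon.isna().to_numpy() & (reasons == "")] = "unparsable longitude"
    reasons[(lat.abs() > 90).to_numpy() & (reasons == "")] = "latitude out of range"
    reasons[(lon.abs() > 180).to_numpy() & (reasons == "")] = "longitude out of range"
    reasons[(raw["individual_id"].str.strip() == "").to_numpy() & (reasons == "")] = "empty individual_id"

    ok = reasons == ""
    rejects = raw.loc[~ok].copy()
    rejects["reason"] = reasons[~ok]

    records = pd.DataFrame(
        {
            "individual_id": raw.loc[ok, "individual_id"].str.strip(),
            "event_type": etype[ok],
            "date": date[ok],
            "lat": lat[ok].astype(float),
            "lon": lon[ok].astype(float),
            "population": raw.loc[ok, "population"].str.strip().replace("", None),
        }
    )
    records = records.sort_values(["individual_id", "date"], kind="mergesort").reset_index(drop=True)
    if len(records) + len(rejects) != len(raw):
        raise AssertionError("record count not conserved")  # pragma: no cover
    if len(records) == 0:
        records = _empty_records()
    return ReadResult(records, rejects.reset_index(drop=True))


def write_observations(records: pd.DataFrame, path: str | Path) -> None:
    """Write a record table back to canonical CSV (ISO dates, 6-decimal coords)."""
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out["lat"] = out["lat"].map(lambda v: f"{v:.6f}")
    out["lon"] = out["lon"].map(lambda v: f"{v:.6f}")
    out["population"] = out["population"].fillna("")
    out[OBS_COLUMNS].to_csv(path, index=False)


def assign_population(
    records: pd.DataFrame,
    populations: Sequence[Population],
    rule: str = "nearest_centroid",
) -> pd.DataFrame:
    """Fill the ``population`` column of a record table.

    ``rule="label"`` keeps the labels already present and raises if any record
    lacks one; ``rule="nearest_centroid"`` assigns every record to the
    population with the nearest centroid by great-circle distance, breaking
    exact ties by the order populations are listed.
    """
    if not populations:
        raise ValueError("populations must be non-empty")
    check_unique_names(populations)
    out = records.copy()
    if rule == "label":
        missing = out.loc[out["population"].isna(), "individual_id"].unique().tolist()
        if missing:
            raise ValueError(f"rule='label' but records without population label for individuals: {missing}")
        known = {p.name for p in populations}
        bad = sorted(set(out["population"]) - known)
        if bad:
            raise ValueError(f"unknown population labels: {bad}")
        return out
    if rule != "nearest_centroid":
        raise ValueError(f"unknown assignment rule: {rule!r}")
    lats = out["lat"].to_numpy(dtype=float)
    lons = out["lon"].to_numpy(dtype=float)
    # distance matrix records x populations; argmin returns the first (listed
    # earliest) population on exact ties
    d = np.column_stack([haversine_km(lats, lons, p.lat, p.lon) for p in populations])
    if d.size:
        idx = np.argmin(d, axis=1)
        out["population"] = [populations[i].name for i in idx]
    return out


def dedupe_seasonal_resights(records: pd.DataFrame, window=((4, 15), (7, 15))) -> pd.DataFrame:
    """Collapse multiple breeding-season resightings of one individual in one year.

    Within the breeding window (month/day bounds, inclusive) only the earliest
    dated resighting per individual per calendar year is kept; this makes
    multiplicity of volunteer reports irrelevant downstream. Records outside
    the window and ring records pass through untouched.
    """
    from .dispersal_extraction import in_breeding_window  # local import avoids a cycle

    dates = pd.to_datetime(records["date"])
    inwin = in_breeding_window(dates, window)
    is_resight = records["event_type"] == "resight"
    target = inwin & is_resight
    keyed = records.loc[target].copy()
    keyed["_year"] = dates[target].dt.year
    keyed = keyed.sort_values(["individual_id", "_year", "date"], kind="mergesort")
    keep = keyed.drop_duplicates(["individual_id", "_year"], keep="first").drop(columns="_year")
    out = pd.concat([records.loc[~target], keep])
    return out.sort_values(["individual_id", "date"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def _jsonable(obj):
    """Recursively convert results objects to JSON-safe structures (NaN -> null)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {}
        for f in dataclasses.fields(obj):
            if f.name == "dendrogram":
                continue
            d[f.name] = _jsonable(getattr(obj, f.name))
        return d
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def results_to_json_dict(results) -> dict:
    return _jsonable(results)


def write_results_json(results, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True) + "\n")


def read_results_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def network_to_graph(network, populations: Sequence[Population] | None = None) -> nx.DiGraph:
    """Directed weighted graph for a :class:`~metapopnet.network_builder.DispersalNetwork`.

    Nodes carry ``strength`` (between-population events touching the node),
    ``self_events`` and, when pair counts are supplied, ``mean_pairs``.
    """
    from .network_builder import node_strength

    g = nx.DiGraph(temporal_class=network.temporal_class)
    by_name = {p.name: p for p in populations or []}
    for i, name in enumerate(network.populations):
        attrs = {
            "strength": int(node_strength(network, name)),
            "self_events": int(network.self_counts[i]),
        }
        pop = by_name.get(name)
        if pop is not None:
            attrs["lat"] = pop.lat
            attrs["lon"] = pop.lon
            if pop.pair_counts:
                attrs["mean_pairs"] = float(np.mean(list(pop.pair_counts.values())))
        g.add_node(name, **attrs)
    for i, a in enumerate(network.populations):
        for j, b in enumerate(network.populations):
            w = int(network.W[i, j])
            if w > 0:
                g.add_edge(a, b, weight=w)
    return g


def write_outputs(
    networks,
    cluster_results,
    test_results,
    out_dir: str | Path,
    populations: Sequence[Population] | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the standard output bundle for a set of per-window analyses.

    ``networks`` and ``cluster_results`` map temporal-class label (or
    ``"total"``) to a DispersalNetwork / ClusterResult (cluster entries may be
    absent for degenerate windows). Produces an edge-list CSV, one GraphML per
    window, Newick dendrograms, a results JSON (statistics, p-values,
    permutation counts, seed) and a run log. Returns the paths written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    paths: dict[str, Path] = {}

    rows = []
    for label, net in networks.items():
        for i, a in enumerate(net.populations):
            for j, b in enumerate(net.populations):
                if net.W[i, j] > 0:
                    rows.append({"source": a, "target": b, "weight": int(net.W[i, j]), "temporal_class": label})
    edges = pd.DataFrame(rows, columns=["source", "target", "weight", "temporal_class"])
    paths["edges"] = out_dir / "edges.csv"
    edges.to_csv(paths["edges"], index=False)

    for label, net in networks.items():
        g = network_to_graph(net, populations)
        p = out_dir / f"network_{_slug(label)}.graphml"
        nx.write_graphml(g, p)
        paths[f"graphml_{label}"] = p

    cluster_rows = []
    for label, cres in cluster_results.items():
        if cres is None:
            continue
        p = out_dir / f"dendrogram_{_slug(label)}.nwk"
        p.write_text(cres.dendrogram.to_newick() + "\n")
        paths[f"newick_{label}"] = p
        for pop, cid in cres.partition.items():
            cluster_rows.append(
                {
                    "temporal_class": label,
                    "population": pop,
                    "cluster": cid,
                    "in_events": cres.in_counts.get(pop),
                    "out_events": cres.out_counts.get(pop),
                    "out_in": cres.out_in.get(pop),
                }
            )
    if cluster_rows:
        paths["clusters"] = out_dir / "clusters.csv"
        pd.DataFrame(cluster_rows).to_csv(paths["clusters"], index=False)

    payload = {
        "seed": seed,
        "tests": _jsonable(test_results),
        "clusters": {
            label: _jsonable(cres) for label, cres in cluster_results.items() if cres is not None
        },
    }
    paths["results"] = out_dir / "results.json"
    Path(paths["results"]).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    paths["log"] = out_dir / "run.log"
    with open(paths["log"], "a") as fh:
        fh.write(f"wrote {len(paths)} outputs to {out_dir} (seed={seed})\n")
    return paths


def _slug(label: str) -> str:
    return str(label).replace("/", "-").replace(" ", "_")


def import_study_xlsx(path: str | Path, sheet=0, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Best-effort importer for a deposited XLSX mark-resight workbook.

    Tries to map the sheet's columns onto the canonical observation schema,
    either via an explicit ``column_map`` (canonical name -> sheet column) or
    by fuzzy header matching. Intended for exploratory use with archived
    supplementary datasets; the canonical CSV path is the supported input.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if column_map is None:
        column_map = {}
        lowered = {str(c).strip().lower(): c for c in df.columns}
        hints = {
            "individual_id": ("individual_id", "ring", "ring_number", "id", "individual", "bird"),
            "event_type": ("event_type", "event", "type"),
            "date": ("date", "observation date", "obs_date"),
            "lat": ("lat", "latitude", "y"),
            "lon": ("lon", "long", "longitude", "x"),
            "population": ("population", "pop", "region"),
        }
        for canon, keys in hints.items():
            for k in keys:
                if k in lowered:
                    column_map[canon] = lowered[k]
                    break
    missing = [c for c in ("individual_id", "date", "lat", "lon") if c not in column_map]
    if missing:
        raise FormatError(f"could not locate columns for: {missing}")
    out = pd.DataFrame({canon: df[col] for canon, col in column_map.items()})
    if "event_type" not in out.columns:
        # if no explicit event column, call the first dated record per bird the
        # ringing and the rest resightings
        out = out.sort_values(["individual_id", "date"], kind="mergesort")
        first = ~out.duplicated("individual_id", keep="first")
        out["event_type"] = np.where(first, "ring", "resight")
    if "population" not in out.columns:
        out["population"] = None
    out["date"] = pd.to_datetime(out["date"])
    return out[OBS_COLUMNS].reset_index(drop=True)
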