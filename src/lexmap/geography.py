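"""Stations, station pairs, great-circle distances, within-group z-scores.

A :class:`Station` is a named landmark with a city membership and geographic
coordinates in decimal degrees. Every downstream analysis row is either an
unordered station pair (distance analyses) or a single station (coordinate
analyses), so this module owns pair enumeration and the km-scale distance
computation, plus the per-city standardisation used by the coordinate models.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Station",
    "EARTH_RADIUS_KM",
    "haversine_km",
    "all_pairs",
    "zscore_within",
    "read_stations_csv",
    "write_stations_csv",
    "dedupe_stations",
]

#: IUGG mean Earth radius. The km scale of all geographic distances.
EARTH_RADIUS_KM = 6371.0088

STATION_COLUMNS = ["id", "name", "city", "lat", "lon"]


@dataclass(frozen=True)
class Station:
    """A named landmark: subway station with city membership and coordinates."""

    id: str
    name: str
    city: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"station {self.id!r}: latitude {self.lat} out of [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"station {self.id!r}: longitude {self.lon} out of [-180, 180]")


def haversine_km(
    a: tuple[float, float] | np.ndarray,
    b: tuple[float, float] | np.ndarray,
    radius_km: float = EARTH_RADIUS_KM,
) -> float | np.ndarray:
    """Great-circle distance between (lat, lon) points, in km.

    Spherical haversine on a sphere of ``radius_km``; accepts scalar pairs or
    broadcastable arrays of shape ``(..., 2)``. Symmetric, zero iff the points
    coincide, bounded by ``pi * radius_km``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lat1, lon1 = a[..., 0], a[..., 1]
    lat2, lon2 = b[..., 0], b[..., 1]
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude out of [-90, 90]")
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude out of [-180, 180]")
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def all_pairs(stations: Sequence[Station]) -> list[tuple[Station, Station]]:
    """Enumerate every unordered station pair exactly once.

    Stations are sorted by id; output is the n(n-1)/2 combinations in
    lexicographic (id_i, id_j) order with id_i < id_j, so regeneration from
    the same station set is byte-identical.
    """
    if len(stations) < 2:
        raise ValueError(f"need at least 2 stations, got {len(stations)}")
    ids = [s.id for s in stations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate station ids: {dupes}")
    ordered = sorted(stations, key=lambda s: s.id)
    return list(itertools.combinations(ordered, 2))


def zscore_within(
    values: Sequence[float], groups: Sequence[str] | None = None
) -> np.ndarray:
    """Z-transform ``values`` independently within each group.

    Uses the sample (n-1) standard deviation, so each group block of the
    output has mean 0 and sd 1. Groups of fewer than two members or with zero
    variance are an error (a silent NaN would poison downstream model fits).
    """
    values = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    groups = np.asarray(groups)
    if len(groups) != len(values):
        raise ValueError("values and groups must be parallel sequences")
    out = np.empty_like(values)
    for g in pd.unique(groups):
        mask = groups == g
        block = values[mask]
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        sd = block.std(ddof=1)
        if sd == 0.0:
            raise ValueError(f"group {g!r} is constant; z-score undefined")
        out[mask] = (block - block.mean()) / sd
    return out


def dedupe_stations(stations: Iterable[Station]) -> list[Station]:
    """Drop repeated (name, city) records, keeping the first occurrence.

    Stations served by several lines appear once per line in raw open-data
    exports; the analyses need one record per station.
    """
    seen: set[tuple[str, str]] = set()
    out: list[Station] = []
    for s in stations:
        key = (s.name, s.city)
        if key in seen:
            logger.info("dropping duplicate station %r in %r", s.name, s.city)
            continue
        seen.add(key)
        out.append(s)
    return out


def read_stations_csv(path: str | Path) -> list[Station]:
    """Read stations from CSV with header ``id,name,city,lat,lon`` (UTF-8)."""
    df = pd.read_csv(path, comment="#", dtype={"id": str, "name": str, "city": str})
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    stations = [
        Station(id=row.id, name=row.name, city=row.city, lat=float(row.lat), lon=float(row.lon))
        for row in df[STATION_COLUMNS].itertuples(index=False)
    ]
    return dedupe_stations(stations)


def write_stations_csv(stations: Sequence[Station], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.id, s.name, s.city, s.lat, s.lon) for s in stations],
        columns=STATION_COLUMNS,
    )
    df.to_csv(path, index=False)
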