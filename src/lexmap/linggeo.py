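"""Linguistic distances, anchor-word coordinates, and analysis tables.

The two language-derived spatial quantities live here:

* **linguistic distance** between two labels: ``1 - cos(v_a, v_b)``, turning
  embedding proximity into a distance in [0, 2];
* **linguistic latitude / longitude** of a label: the difference of its
  cosines to a pair of opposed cardinal anchor words,
  ``cos(v, north) - cos(v, south)`` and ``cos(v, east) - cos(v, west)``,
  projecting the label onto language-defined cardinal axes (positive =
  linguistically northern / eastern).

The table builders join these with the geographic side into tidy DataFrames
ready for the models in :mod:`lexmap.stats`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingStore, SubwordTable, cosine, resolve_label
from .geography import EARTH_RADIUS_KM, Station, all_pairs, haversine_km, zscore_within

logger = logging.getLogger(__name__)

__all__ = [
    "CardinalAnchors",
    "load_anchor_words",
    "linguistic_distance",
    "linguistic_latitude",
    "linguistic_longitude",
    "build_pair_table",
    "build_coordinate_table",
]

DIRECTIONS = ("north", "south", "east", "west")

PAIR_COLUMNS = [
    "station_i",
    "station_j",
    "city",
    "geo_km",
    "map_dist",
    "ling_dist",
    "provenance_i",
    "provenance_j",
]

COORD_COLUMNS = [
    "id",
    "city",
    "geo_lat",
    "geo_lon",
    "ling_lat",
    "ling_lon",
    "z_geo_lat",
    "z_geo_lon",
]


def load_anchor_words(
    language: str, path: str | Path | None = None
) -> dict[str, str]:
    """Anchor words (north/south/east/west) for ``language``.

    Reads the JSON table at ``path`` when given, otherwise the table shipped
    with the package. The shipped translations are editorial defaults and are
    meant to be overridden when replicating a specific embedding space.
    """
    if path is None:
        text = resources.files("lexmap").joinpath("data/anchors.json").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    table = json.loads(text)
    key = language.lower()
    if key not in table:
        raise KeyError(
            f"no anchor words for language {language!r}; available: {sorted(table)}"
        )
    words = table[key]
    missing = [d for d in DIRECTIONS if d not in words]
    if missing:
        raise ValueError(f"anchor table for {language!r} missing {missing}")
    return {d: words[d] for d in DIRECTIONS}


@dataclass
class CardinalAnchors:
    """The four cardinal anchor words of a language and their vectors."""

    language: str
    words: Mapping[str, str]
    vectors: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for d in DIRECTIONS:
            if d not in self.vectors:
                raise ValueError(f"missing anchor vector for {d!r}")
        dims = {np.asarray(self.vectors[d]).shape for d in DIRECTIONS}
        if len(dims) != 1:
            raise ValueError(f"anchor vectors have inconsistent shapes: {dims}")
        for d in DIRECTIONS:
            v = np.asarray(self.vectors[d], dtype=float)
            if np.linalg.norm(v) == 0.0:
                raise ValueError(f"anchor vector for {d!r} has zero norm")

    @property
    def dim(self) -> int:
        return int(np.asarray(self.vectors["north"]).shape[0])

    @classmethod
    def from_store(
        cls,
        language: str,
        store: EmbeddingStore,
        words: Mapping[str, str] | None = None,
        table: SubwordTable | None = None,
        lowercase: bool = True,
    ) -> "CardinalAnchors":
        """Resolve a language's anchor words against an embedding store.

        Anchor labels resolve exactly like station labels: exact lookup first,
        subword fallback second. Queries default to lowercase (direction words
        are common nouns); pass ``lowercase=False`` to query as written.
        """
        if words is None:
            words = load_anchor_words(language)
        words = {d: (w.lower() if lowercase else w) for d, w in words.items()}
        vectors = {}
        for d in DIRECTIONS:
            vec, prov = resolve_label(store, words[d], table)
            logger.info("anchor %s=%r resolved via %s", d, words[d], prov)
            vectors[d] = vec
        return cls(language=language, words=words, vectors=vectors)


def linguistic_distance(
    store: EmbeddingStore,
    a: str,
    b: str,
    table: SubwordTable | None = None,
) -> float:
    """``1 - cosine`` distance between two labels' vectors, in [0, 2].

    Zero iff the vectors are positively collinear; 2 for antipodal vectors.
    """
    va, _ = resolve_label(store, a, table)
    vb, _ = resolve_label(store, b, table)
    try:
        return 1.0 - cosine(va, vb)
    except ValueError as err:
        raise ValueError(f"linguistic distance between {a!r} and {b!r}: {err}") from None


def linguistic_latitude(v: np.ndarray, anchors: CardinalAnchors) -> float:
    """``cos(v, north) - cos(v, south)``: positive = linguistically northern."""
    return cosine(v, anchors.vectors["north"]) - cosine(v, anchors.vectors["south"])


def linguistic_longitude(v: np.ndarray, anchors: CardinalAnchors) -> float:
    """``cos(v, east) - cos(v, west)``: positive = linguistically eastern."""
    return cosine(v, anchors.vectors["east"]) - cosine(v, anchors.vectors["west"])


def _station_vectors(
    stations: Sequence[Station],
    store: EmbeddingStore,
    table: SubwordTable | None,
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Resolve every station name once; fail before any table is built."""
    vectors: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    counts = {"exact": 0, "subword": 0}
    for s in stations:
        vec, prov = resolve_label(store, s.name, table)
        if np.linalg.norm(vec) == 0.0:
            raise ValueError(f"station {s.name!r} resolved to a zero-norm vector")
        vectors[s.id] = vec
        provenance[s.id] = prov
        counts[prov] += 1
    logger.info(
        "resolved %d station labels: %d exact, %d subword",
        len(stations),
        counts["exact"],
        counts["subword"],
    )
    return vectors, provenance


def build_pair_table(
    stations: Sequence[Station],
    store: EmbeddingStore,
    table: SubwordTable | None = None,
    radius_km: float = EARTH_RADIUS_KM,
) -> pd.DataFrame:
    """All-pairs analysis table: one row per unordered within-city pair.

    Columns: ``station_i, station_j, city, geo_km, map_dist, ling_dist,
    provenance_i, provenance_j``. Pairing is within city (stations of
    different cities are never paired); for a single-city input the row count
    is n(n-1)/2. ``map_dist`` is NaN until a schematic-map calibration fills
    it. Raises before emitting anything if any label fails to resolve.
    """
    stations = list(stations)
    vectors, provenance = _station_vectors(stations, store, table)
    unit = {sid: v / np.linalg.norm(v) for sid, v in vectors.items()}
    rows = []
    for city in sorted({s.city for s in stations}):
        members = [s for s in stations if s.city == city]
        if len(members) < 2:
            raise ValueError(f"city {city!r} has fewer than 2 stations")
        for si, sj in all_pairs(members):
            geo = haversine_km((si.lat, si.lon), (sj.lat, sj.lon), radius_km)
            ling = 1.0 - float(unit[si.id] @ unit[sj.id])
            rows.append(
                (si.id, sj.id, city, geo, np.nan, ling, provenance[si.id], provenance[sj.id])
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def build_coordinate_table(
    stations: Sequence[Station],
    store: EmbeddingStore,
    anchors: CardinalAnchors | Mapping[str, CardinalAnchors],
    table: SubwordTable | None = None,
) -> pd.DataFrame:
    """Per-station coordinate table joining geographic and linguistic axes.

    ``anchors`` is either a single :class:`CardinalAnchors` (applied to every
    city) or a mapping city -> anchors for multilingual datasets. Geographic
    coordinates are additionally z-scored within city (``z_geo_lat``,
    ``z_geo_lon``), the scale on which the coordinate models are fitted.
    """
    stations = list(stations)
    ids = [s.id for s in stations]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate station ids")
    vectors, _ = _station_vectors(stations, store, table)
    rows = []
    for s in sorted(stations, key=lambda s: s.id):
        anc = anchors[s.city] if isinstance(anchors, Mapping) else anchors
        v = vectors[s.id]
        rows.append(
            (s.id, s.city, s.lat, s.lon, linguistic_latitude(v, anc), linguistic_longitude(v, anc))
        )
    df = pd.DataFrame(rows, columns=COORD_COLUMNS[:6])
    df["z_geo_lat"] = zscore_within(df["geo_lat"].to_numpy(), df["city"].to_numpy())
    df["z_geo_lon"] = zscore_within(df["geo_lon"].to_numpy(), df["city"].to_numpy())
    return df
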