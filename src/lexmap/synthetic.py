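"""Synthetic cities and embedding spaces with tunable spatial signal.

The real pipeline consumes open-data station lists and multi-gigabyte
pretrained embedding spaces. This module generates stand-ins with the
statistical structure the analyses presuppose, so every stage — file I/O,
distance tables, anchor projections, model fits — and the recovery
properties of the whole pipeline are testable offline.

Generative model
----------------
Station coordinates are uniform over a square of half-width ``extent``
degrees about ``center``. Embedding vectors are built from three mutually
orthonormal latent directions in ``dim`` dimensions: a shared base direction
``u0`` and two spatial axes ``uN`` (latitude) and ``uE`` (longitude). With
planar coordinates rescaled to lambda, phi in [-1, 1], station k gets

    v_k = normalize( c*u0 + a_k*(lambda_k*uN + phi_k*uE) + sigma*eps_k )

with iid Gaussian noise ``eps_k`` scaled by ``1/sqrt(dim)``. The shared base
weight ``c`` is what makes *cosine distance* track planar proximity: all
stations point broadly the same way, and spatial position perturbs that
common direction, so the angle between two stations grows with their planar
separation. Without it, normalisation would erase radial information and
distances would be unrecoverable by construction.

``a_k`` equals the signal weight ``alpha`` except for a ``polysemy_prob``
fraction of stations, where it drops to ``alpha/10``: a station name
dominated by its non-geographic meanings (the "Angel" problem) is only
weakly informative about where the station is, but not mute.

Anchor vectors are noisy antipodal copies of the axes:
``north = normalize(uN + tau*z)``, ``south = normalize(-uN + tau*z')`` and
likewise east/west, with the same ``1/sqrt(dim)`` noise scaling.

All randomness streams from one root seed through named substreams (city,
embedding, anchors), so e.g. the station layout is unchanged when only the
anchor noise is varied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .embeddings import EmbeddingStore
from .geography import Station
from .linggeo import (
    CardinalAnchors,
    build_coordinate_table,
    build_pair_table,
)
from .stats import CrossedLMM, GroupInteractionOLS

__all__ = [
    "SynthConfig",
    "SynthCity",
    "generate_city",
    "generate_embedding_space",
    "generate",
    "simulate_experiment",
]

_SUBSTREAMS = {"city": 0, "embedding": 1, "anchors": 2}

_CONSONANTS = list("bdfgklmnprstvz")
_VOWELS = list("aeiou")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic city + embedding-space generator.

    Defaults describe a moderately informative medium-scale space: a city of
    120 stations spanning roughly 33 km, embeddings where spatial position
    carries a clear but noisy share of the vector (alpha=0.6 against base
    weight 3), mildly noisy anchors, and 10% polysemy-contaminated labels.
    """

    n_stations: int = 120
    dim: int = 50
    alpha: float = 0.6          # spatial-signal weight, in [0, 1]
    base_weight: float = 3.0    # shared-direction weight c
    sigma: float = 0.1          # station vector noise sd
    tau: float = 0.05           # anchor vector noise sd
    polysemy_prob: float = 0.1
    extent: float = 0.15        # half-width of the coordinate square, degrees
    center: tuple[float, float] = (52.52, 13.40)
    seed: int = 0
    multiword_frac: float = 0.25
    city: str = "Synthville"
    language: str = "english"

    def __post_init__(self) -> None:
        if self.n_stations < 2:
            raise ValueError("n_stations must be >= 2")
        if self.dim < 3:
            raise ValueError("dim must be >= 3")
        for name in ("alpha", "polysemy_prob", "multiword_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.base_weight <= 0:
            raise ValueError("base_weight must be positive")
        for name in ("sigma", "tau", "extent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream of the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))[_SUBSTREAMS[stream]]
        )


@dataclass
class SynthCity:
    """A generated city bundle, with the latent truth kept for recovery tests."""

    stations: list[Station]
    store: EmbeddingStore
    anchors: CardinalAnchors
    truth: dict
    config: SynthConfig


def _make_name(rng: np.random.Generator, two_words: bool) -> str:
    def word() -> str:
        n_syll = int(rng.integers(2, 4))
        s = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syll)
        )
        return s.capitalize()

    return word() + (" " + word() if two_words else "")


def generate_city(config: SynthConfig) -> list[Station]:
    """Generate stations uniformly over the extent square, with unique names.

    A ``multiword_frac`` fraction of stations get two-word names with an
    internal space (exercising the subword-label path downstream). Output is
    bit-identical for identical config.
    """
    rng = config.rng("city")
    lat0, lon0 = config.center
    lats = lat0 + rng.uniform(-config.extent, config.extent, config.n_stations)
    lons = lon0 + rng.uniform(-config.extent, config.extent, config.n_stations)
    two_word = rng.random(config.n_stations) < config.multiword_frac
    names: list[str] = []
    seen: set[str] = set()
    for k in range(config.n_stations):
        name = _make_name(rng, bool(two_word[k]))
        while name in seen:
            name = _make_name(rng, bool(two_word[k]))
        seen.add(name)
        names.append(name)
    width = len(str(config.n_stations - 1))
    return [
        Station(
            id=f"{config.city}-{k:0{width}d}",
            name=names[k],
            city=config.city,
            lat=float(lats[k]),
            lon=float(lons[k]),
        )
        for k in range(config.n_stations)
    ]


def generate_embedding_space(
    stations: Sequence[Station], config: SynthConfig
) -> tuple[EmbeddingStore, CardinalAnchors, dict]:
    """Generate station vectors, cardinal anchors, and the latent truth.

    See the module docstring for the generative model. The returned store
    contains one vector per station *name* and the four anchor words, so the
    bundle is consumable by the exact same code path as real data. ``truth``
    records the latent axes, rescaled coordinates, per-station signal weights
    and polysemy flags.
    """
    rng = config.rng("embedding")
    dim = config.dim
    basis, _ = np.linalg.qr(rng.standard_normal((dim, 3)))
    u0, uN, uE = basis[:, 0], basis[:, 1], basis[:, 2]

    lat0, lon0 = config.center
    if config.extent > 0:
        lam = np.array([(s.lat - lat0) / config.extent for s in stations])
        phi = np.array([(s.lon - lon0) / config.extent for s in stations])
    else:
        lam = np.zeros(len(stations))
        phi = np.zeros(len(stations))

    poly = rng.random(len(stations)) < config.polysemy_prob
    a_k = np.where(poly, config.alpha / 10.0, config.alpha)

    store = EmbeddingStore(dim=dim)
    for k, s in enumerate(stations):
        noise = config.sigma * rng.standard_normal(dim) / np.sqrt(dim)
        v = config.base_weight * u0 + a_k[k] * (lam[k] * uN + phi[k] * uE) + noise
        store.add(s.name, v / np.linalg.norm(v))

    arng = config.rng("anchors")
    words = {"north": "north", "south": "south", "east": "east", "west": "west"}
    axes = {"north": uN, "south": -uN, "east": uE, "west": -uE}
    vectors = {}
    for d in ("north", "south", "east", "west"):
        noise = config.tau * arng.standard_normal(dim) / np.sqrt(dim)
        v = axes[d] + noise
        v = v / np.linalg.norm(v)
        vectors[d] = v
        store.add(words[d], v)
    anchors = CardinalAnchors(language=config.language, words=words, vectors=vectors)

    truth = {
        "u0": u0,
        "uN": uN,
        "uE": uE,
        "lambda": lam,
        "phi": phi,
        "a_k": a_k,
        "polysemous": poly,
        "alpha": config.alpha,
        "base_weight": config.base_weight,
        "sigma": config.sigma,
        "tau": config.tau,
    }
    return store, anchors, truth


def generate(config: SynthConfig) -> SynthCity:
    """Generate a full city bundle (stations + embedding space + anchors)."""
    stations = generate_city(config)
    store, anchors, truth = generate_embedding_space(stations, config)
    return SynthCity(
        stations=stations, store=store, anchors=anchors, truth=truth, config=config
    )


def truth_to_json(truth: dict) -> str:
    """Serialise a truth record (numpy arrays become lists)."""
    def conv(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.bool_, np.floating, np.integer)):
            return v.item()
        return v

    return json.dumps({k: conv(v) for k, v in truth.items()}, indent=1)


def _multi_city(config: SynthConfig, n_cities: int,
                station_counts: Sequence[int] | None) -> list[SynthCity]:
    counts = list(station_counts) if station_counts else [config.n_stations] * n_cities
    if len(counts) == 1 and counts[0] == config.n_stations:
        return [generate(config)]
    seeds = np.random.SeedSequence(config.seed).generate_state(len(counts) + 1)[1:]
    bundles = []
    for c, (count, seed) in enumerate(zip(counts, seeds)):
        sub = replace(
            config,
            n_stations=int(count),
            seed=int(seed % (2**31)),
            city=f"{config.city}{c}" if len(counts) > 1 else config.city,
            # separate the cities on the globe; pairing stays within city
            center=(config.center[0], config.center[1] + 2.0 * c),
        )
        bundles.append(generate(sub))
    return bundles


def simulate_experiment(
    config: SynthConfig,
    which: str = "exp1",
    n_cities: int = 1,
    station_counts: Sequence[int] | None = None,
    n_restarts: int = 10,
):
    """Run a full pipeline experiment on synthetic data and report recovery.

    ``which="exp1"``: pair-distance analysis — build the all-pairs table and
    fit the crossed random-intercepts mixed model
    ``geo_km ~ ling_dist [* city] + (1|station_i) + (1|station_j)``.

    ``which="exp2"``: coordinate analysis — build the per-station coordinate
    table and fit the two interaction OLS models
    ``z_geo_lat ~ ling_lat [* city]`` and ``z_geo_lon ~ ling_lon [* city]``.

    Returns a dict with the fitted results, the analysis table, per-city
    simple slopes (where applicable) and the generating truth. Deterministic
    under ``config.seed``.
    """
    if which not in ("exp1", "exp2"):
        raise ValueError(f"which must be 'exp1' or 'exp2', got {which!r}")
    bundles = _multi_city(config, n_cities, station_counts)
    stations = [s for b in bundles for s in b.stations]
    report: dict = {
        "which": which,
        "seed": config.seed,
        "truth_alpha": config.alpha,
        "n_cities": len(bundles),
        "n_stations": len(stations),
    }
    if which == "exp1":
        tables = [
            build_pair_table(b.stations, b.store) for b in bundles
        ]
        pairs = pd.concat(tables, ignore_index=True)
        group = "city" if len(bundles) > 1 else None
        model = CrossedLMM.from_pairs(
            pairs, y="geo_km", x="ling_dist", group=group
        )
        res = model.fit(n_restarts=n_restarts)
        report.update(
            table=pairs,
            result=res,
            slope=float(res.params["ling_dist"]),
            slope_z=float(res.zvalues["ling_dist"]),
            simple_slopes=res.simple_slopes(),
        )
    else:
        frames = [
            build_coordinate_table(b.stations, b.store, b.anchors) for b in bundles
        ]
        coords = pd.concat(frames, ignore_index=True)
        group = coords["city"].to_numpy() if len(bundles) > 1 else None
        results = {}
        for axis, (yc, xc) in {
            "lat": ("z_geo_lat", "ling_lat"),
            "lon": ("z_geo_lon", "ling_lon"),
        }.items():
            res = GroupInteractionOLS(
                coords[yc].to_numpy(), coords[xc].to_numpy(), group,
                x_name=xc, group_name="city",
            ).fit()
            results[axis] = res
            report[f"{axis}_slope"] = float(res.params[xc])
            report[f"{axis}_r2"] = float(res.rsquared)
            report[f"{axis}_df_resid"] = res.df_resid
        report.update(table=coords, result=results)
    return report
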