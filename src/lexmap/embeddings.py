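"""Word-embedding I/O, subword composition, and cosine geometry.

This module handles the distributional-semantic side of the pipeline: reading
pretrained embedding files in the fastText ``.vec`` text dialect, composing
vectors for out-of-vocabulary labels from hashed character n-grams (the same
construction fastText uses for unseen words, which matters for multi-word
station labels such as "Elephant & Castle"), and the cosine similarity that
all downstream linguistic distances are built on.

Label matching is byte-exact: no case folding, no unicode normalisation.
Pretrained spaces distinguish "Angel" from "angel", and station labels keep
their internal spaces, so silent normalisation would change the science.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingStore",
    "SubwordTable",
    "EmbeddingError",
    "VecParseError",
    "MissingLabelError",
    "read_vec_file",
    "write_vec_file",
    "char_ngrams",
    "fnv1a32",
    "oov_vector",
    "cosine",
    "resolve_label",
    "get_label_vector",
]

FNV_OFFSET_BASIS = 2166136261
FNV_PRIME = 16777619


class EmbeddingError(Exception):
    """Base class for embedding-related failures."""


class VecParseError(EmbeddingError):
    """A ``.vec`` file violated the format; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class MissingLabelError(EmbeddingError, KeyError):
    """A label could not be resolved to a vector."""

    def __init__(self, label: str):
        super().__init__(f"label not found in embedding store: {label!r}")
        self.label = label


@dataclass
class EmbeddingStore:
    """A label -> vector map with fixed dimensionality.

    Labels are unicode strings matched exactly (case- and space-sensitive).
    """

    dim: int
    _vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError(f"dim must be positive, got {self.dim}")

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, label: str) -> bool:
        return label in self._vectors

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self._vectors[label]
        except KeyError:
            raise MissingLabelError(label) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._vectors)

    @property
    def labels(self) -> list[str]:
        return list(self._vectors)

    def add(self, label: str, vector: np.ndarray) -> None:
        vec = np.asarray(vector, dtype=float)
        if vec.shape != (self.dim,):
            raise ValueError(
                f"vector for {label!r} has shape {vec.shape}, expected ({self.dim},)"
            )
        if label in self._vectors:
            logger.warning("duplicate label %r: last occurrence wins", label)
        self._vectors[label] = vec

    def get(self, label: str, default=None):
        return self._vectors.get(label, default)


@dataclass
class SubwordTable:
    """Hashed character n-gram bucket vectors for OOV composition.

    ``buckets`` is a ``(bucket_count, dim)`` array; an n-gram maps to row
    ``fnv1a32(ngram) % bucket_count``. ``minn``/``maxn`` bound n-gram lengths
    (default 5/5, the length used by the pretrained CBOW spaces this package
    mirrors).
    """

    buckets: np.ndarray
    minn: int = 5
    maxn: int = 5

    def __post_init__(self) -> None:
        self.buckets = np.asarray(self.buckets, dtype=float)
        if self.buckets.ndim != 2 or self.buckets.shape[0] < 1:
            raise ValueError("buckets must be a non-empty 2-D array")
        if not (1 <= self.minn <= self.maxn):
            raise ValueError(f"need 1 <= minn <= maxn, got {self.minn}, {self.maxn}")

    @property
    def bucket_count(self) -> int:
        return self.buckets.shape[0]

    @property
    def dim(self) -> int:
        return self.buckets.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Serialise as ``bucket_index,v1,...,vdim`` plus a JSON sidecar."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            for i, row in enumerate(self.buckets):
                fh.write(str(i) + "," + ",".join(repr(float(v)) for v in row) + "\n")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"bucket_count": self.bucket_count, "minn": self.minn, "maxn": self.maxn}
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SubwordTable":
        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".json").read_text(encoding="utf-8")
        )
        raw = np.loadtxt(path, delimiter=",", ndmin=2)
        order = np.argsort(raw[:, 0])
        buckets = raw[order, 1:]
        if buckets.shape[0] != meta["bucket_count"]:
            raise ValueError(
                f"{path}: {buckets.shape[0]} rows but sidecar says "
                f"{meta['bucket_count']} buckets"
            )
        return cls(buckets=buckets, minn=meta["minn"], maxn=meta["maxn"])


def read_vec_file(path: str | Path) -> EmbeddingStore:
    """Read a fastText ``.vec`` text file.

    Format: a header line ``<count> <dim>`` followed by one
    ``<token> v1 ... vdim`` line per token, space-separated, UTF-8. Duplicate
    tokens collapse (last wins) with a logged warning.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        parts = header.split()
        if len(parts) != 2:
            raise VecParseError(f"malformed header {header!r}", line=1)
        try:
            count, dim = int(parts[0]), int(parts[1])
        except ValueError:
            raise VecParseError(f"non-integer header {header!r}", line=1) from None
        if dim <= 0:
            raise VecParseError(f"non-positive dimension {dim}", line=1)
        store = EmbeddingStore(dim=dim)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(" ")
            # tokens may contain spaces (multi-word labels): the vector is the
            # trailing `dim` fields, the token is everything before them.
            if len(fields) < dim + 1:
                raise VecParseError(
                    f"expected {dim} vector components, got {len(fields) - 1}",
                    line=lineno,
                )
            token = " ".join(fields[: len(fields) - dim])
            try:
                vec = np.array([float(v) for v in fields[len(fields) - dim:]])
            except ValueError:
                raise VecParseError("non-numeric vector component", line=lineno) from None
            store.add(token, vec)
    if len(store) != count:
        logger.warning(
            "%s: header announced %d tokens, parsed %d (duplicates collapse)",
            path,
            count,
            len(store),
        )
    return store


def write_vec_file(store: EmbeddingStore, path: str | Path, precision: int = 6) -> None:
    """Write a store back out in the same ``.vec`` dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(store)} {store.dim}\n")
        for label in store:
            vec = store[label]
            fh.write(label + " " + " ".join(f"{v:.{precision}g}" for v in vec) + "\n")


def char_ngrams(word: str, minn: int = 5, maxn: int = 5) -> list[str]:
    """Enumerate boundary-wrapped character n-grams of ``word``.

    The word is wrapped as ``"<" + word + ">"`` and every contiguous substring
    with length in ``[minn, maxn]`` is returned, sweeping start positions left
    to right and, within a start, shorter n-grams first. Empty when the
    wrapped word is shorter than ``minn``.
    """
    if not word:
        raise ValueError("word must be non-empty")
    wrapped = f"<{word}>"
    out: list[str] = []
    for start in range(len(wrapped)):
        for n in range(minn, maxn + 1):
            if start + n <= len(wrapped):
                out.append(wrapped[start : start + n])
    return out


def fnv1a32(data: bytes | str) -> int:
    """32-bit FNV-1a hash (fastText's n-gram bucket hash).

    Offset basis 2166136261, prime 16777619; per byte: XOR then multiply,
    all arithmetic mod 2**32. Strings are hashed as their UTF-8 bytes.
    """
    if isinstance(data, str):
        data = data.encode("utf-8")
    h = FNV_OFFSET_BASIS
    for byte in data:
        h ^= byte
        h = (h * FNV_PRIME) & 0xFFFFFFFF
    return h


def oov_vector(word: str, table: SubwordTable, agg: str = "sum") -> np.ndarray:
    """Compose a vector for an out-of-vocabulary word from its n-gram buckets.

    Each n-gram (per :func:`char_ngrams` with the table's ``minn``/``maxn``)
    selects bucket ``fnv1a32(ngram) % bucket_count``; the composed vector is
    the sum of the selected bucket vectors (``agg="mean"`` averages instead —
    irrelevant for any cosine-based quantity, exposed for replication of the
    query-tool convention). A word with no n-grams yields the zero vector with
    a warning; downstream cosines reject zero-norm input explicitly.
    """
    if agg not in ("sum", "mean"):
        raise ValueError(f"agg must be 'sum' or 'mean', got {agg!r}")
    grams = char_ngrams(word, table.minn, table.maxn)
    if not grams:
        logger.warning("word %r yields no n-grams; returning zero vector", word)
        return np.zeros(table.dim)
    idx = [fnv1a32(g) % table.bucket_count for g in grams]
    vec = table.buckets[idx].sum(axis=0)
    if agg == "mean":
        vec = vec / len(grams)
    return vec


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    Raises on zero-norm input rather than returning NaN.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def resolve_label(
    store: EmbeddingStore,
    label: str,
    table: SubwordTable | None = None,
    agg: str = "sum",
) -> tuple[np.ndarray, str]:
    """Resolve a label to a vector with provenance ``"exact"`` or ``"subword"``.

    Exact byte-level lookup first; on a miss, subword composition when a
    :class:`SubwordTable` is available, otherwise :class:`MissingLabelError`.
    """
    if not label:
        raise ValueError("label must be non-empty")
    if label in store:
        return store[label], "exact"
    if table is not None:
        if table.dim != store.dim:
            raise ValueError(
                f"subword table dim {table.dim} != store dim {store.dim}"
            )
        logger.info("label %r missing from store; composing from subwords", label)
        return oov_vector(label, table, agg=agg), "subword"
    raise MissingLabelError(label)


def get_label_vector(
    store: EmbeddingStore,
    label: str,
    table: SubwordTable | None = None,
    agg: str = "sum",
) -> np.ndarray:
    """Vector for ``label``: exact lookup with optional subword fallback."""
    vec, _ = resolve_label(store, label, table, agg=agg)
    return vec
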