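"""Triplet pseudoatom fingerprints.

Every unordered triple of pseudoatoms is encoded as a *triplet key*: the
three pseudoatom type codes together with the three pairwise distances,
each distance discretised into one of six bins (0-4, 4-6, 6-9, 9-13,
13-17, 17+ Angstrom, half-open on the right).  Bins are attached to the
side *opposite* each vertex, and the key is canonicalised as the minimum
over all six vertex orderings, so the same triangle always produces the
same key regardless of input order.

A :class:`FeatureDictionary` maps the most frequent keys of a corpus to a
fixed 211-slot index; vectorising a complex then counts (or flags) its
triplet keys through that dictionary.  Extra per-molecule descriptors (for
instance a docking score) can be appended after the 211 base positions.

The sklearn-style :class:`TifpVectorizer` wraps dictionary building
(``fit``) and vectorisation (``transform``).
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .interactions import PSEUDOATOM_TYPES, Pseudoatom

__all__ = [
    "DEFAULT_EDGES",
    "DICTIONARY_SIZE",
    "BinScheme",
    "TripletKey",
    "FeatureDictionary",
    "Fingerprint",
    "bin_distance",
    "canonical_triplet_key",
    "enumerate_triplets",
    "build_dictionary",
    "vectorize",
    "append_descriptors",
    "TifpVectorizer",
]

DEFAULT_EDGES = (4.0, 6.0, 9.0, 13.0, 17.0)
DICTIONARY_SIZE = 211
_TYPE_INDEX = {t: i for i, t in enumerate(PSEUDOATOM_TYPES)}


@dataclass(frozen=True)
class BinScheme:
    """Six half-open distance bins: [0,4), [4,6), [6,9), [9,13), [13,17), [17,inf)."""

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        e = tuple(float(v) for v in self.edges)
        if list(e) != sorted(e) or len(set(e)) != len(e):
            raise ValueError("bin edges must be strictly increasing")
        if len(e) != 5:
            raise ValueError("scheme must define exactly 6 bins (5 inner edges)")
        object.__setattr__(self, "edges", e)

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1


def bin_distance(d: float, scheme: BinScheme = BinScheme()) -> int:
    """Bin index in 0..5 for a distance in Angstrom; [lo, hi) convention."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return int(np.searchsorted(scheme.edges, d, side="right"))


@dataclass(frozen=True, order=True)
class TripletKey:
    """Canonical key of one pseudoatom triangle.

    ``sides`` is a tuple of three (type code, opposite-side bin) pairs in
    canonical order; the bin paired with a vertex is the bin of the edge
    between the other two vertices.
    """

    sides: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.sides) != 3:
            raise ValueError("a triplet key has exactly three sides")
        for t, b in self.sides:
            if t not in _TYPE_INDEX:
                raise ValueError(f"unknown pseudoatom type {t!r}")
            if not (0 <= b):
                raise ValueError("bin index must be non-negative")

    def encode(self) -> str:
        return "|".join(f"{t}:{b}" for t, b in self.sides)

    @classmethod
    def decode(cls, s: str) -> "TripletKey":
        sides = []
        for part in s.split("|"):
            t, b = part.rsplit(":", 1)
            sides.append((t, int(b)))
        return cls(sides=tuple(sides))


def canonical_triplet_key(
    p1: Pseudoatom, p2: Pseudoatom, p3: Pseudoatom, scheme: BinScheme = BinScheme()
) -> TripletKey:
    """Key of the triangle (p1, p2, p3), identical for all six input orders.

    Each vertex carries the bin of its opposite side; the canonical form is
    the minimum over all vertex permutations of the ((type rank, bin), ...)
    sequence.  Coincident pseudoatoms are allowed (distance 0 -> bin 0).
    """
    pts = (p1, p2, p3)
    xyz = [p.xyz for p in pts]
    # bins[i] = bin of the side opposite vertex i
    bins = [
        bin_distance(float(np.linalg.norm(xyz[(i + 1) % 3] - xyz[(i + 2) % 3])), scheme)
        for i in range(3)
    ]
    items = [(pts[i].ptype, bins[i]) for i in range(3)]
    best = min(
        tuple(items[i] for i in perm)
        for perm in itertools.permutations(range(3))
    )
    return TripletKey(sides=best)


def enumerate_triplets(
    pseudoatoms: Sequence[Pseudoatom], scheme: BinScheme = BinScheme()
) -> Counter[TripletKey]:
    """Multiset of keys over all C(n, 3) unordered pseudoatom triples."""
    keys: Counter[TripletKey] = Counter()
    for a, b, c in itertools.combinations(pseudoatoms, 3):
        keys[canonical_triplet_key(a, b, c, scheme)] += 1
    return keys


@dataclass
class FeatureDictionary:
    """Ordered map from the ``size`` most frequent triplet keys to indices.

    Keys are ranked by descending corpus count with lexicographic-encoding
    tie break; when the corpus holds fewer distinct keys than ``size``, the
    trailing slots are inert (``None``) so vectors keep a fixed length.
    """

    keys: list[Optional[TripletKey]]
    counts: list[int]
    provenance: str = ""

    def __post_init__(self) -> None:
        active = [k for k in self.keys if k is not None]
        if len(active) != len({k.encode() for k in active}):
            raise ValueError("duplicate keys in dictionary")
        self._index = {k.encode(): i for i, k in enumerate(self.keys) if k is not None}

    @property
    def size(self) -> int:
        return len(self.keys)

    @property
    def n_active(self) -> int:
        return len(self._index)

    def index_of(self, key: TripletKey) -> Optional[int]:
        return self._index.get(key.encode())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "size": self.size,
            "provenance": self.provenance,
            "entries": [
                {"key": (k.encode() if k is not None else None), "count": c}
                for k, c in zip(self.keys, self.counts)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureDictionary":
        payload = json.loads(Path(path).read_text())
        keys = [
            TripletKey.decode(e["key"]) if e["key"] is not None else None
            for e in payload["entries"]
        ]
        counts = [int(e["count"]) for e in payload["entries"]]
        return cls(keys=keys, counts=counts, provenance=payload.get("provenance", ""))


def build_dictionary(
    corpus: Iterable[Counter[TripletKey]],
    size: int = DICTIONARY_SIZE,
    provenance: str = "",
) -> FeatureDictionary:
    """Rank all keys of a corpus by total count and keep the top ``size``.

    Count ties break by lexicographic key encoding, which makes the
    dictionary deterministic for a given corpus.
    """
    if size < 1:
        raise ValueError("dictionary size must be >= 1")
    total: Counter[TripletKey] = Counter()
    n_docs = 0
    for doc in corpus:
        total.update(doc)
        n_docs += 1
    if n_docs == 0:
        raise ValueError("corpus is empty")
    ranked = sorted(total.items(), key=lambda kv: (-kv[1], kv[0].encode()))[:size]
    keys: list[Optional[TripletKey]] = [k for k, _c in ranked]
    counts = [c for _k, c in ranked]
    while len(keys) < size:
        keys.append(None)
        counts.append(0)
    return FeatureDictionary(keys=keys, counts=counts, provenance=provenance)


@dataclass
class Fingerprint:
    """A fixed-length feature vector: 211 base positions plus k appended
    descriptors.  ``mode`` is ``count`` (triplet multiplicities) or
    ``binary`` (presence bits)."""

    values: np.ndarray
    mode: str = "count"
    molecule_id: str = ""
    target_id: str = ""
    n_base: int = DICTIONARY_SIZE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < self.n_base:
            raise ValueError(f"fingerprint must have >= {self.n_base} positions")
        if self.mode not in ("count", "binary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        base = self.values[: self.n_base]
        if np.any(base < 0) or np.any(base != np.round(base)):
            raise ValueError("base positions must be non-negative integers")
        if self.mode == "binary" and np.any(base > 1):
            raise ValueError("binary mode allows only 0/1 in base positions")

    @property
    def n_extra(self) -> int:
        return len(self.values) - self.n_base


def vectorize(
    triplets: Counter[TripletKey],
    dictionary: FeatureDictionary,
    mode: str = "count",
    molecule_id: str = "",
    target_id: str = "",
) -> Fingerprint:
    """Map a triplet-key multiset through the dictionary to a fixed vector.

    Keys absent from the dictionary are dropped; position i holds the
    multiplicity (count mode) or presence (binary mode) of dictionary
    key i.
    """
    vec = np.zeros(dictionary.size, dtype=float)
    for key, n in triplets.items():
        i = dictionary.index_of(key)
        if i is not None:
            vec[i] += n
    if mode == "binary":
        vec = (vec > 0).astype(float)
    return Fingerprint(values=vec, mode=mode, molecule_id=molecule_id,
                       target_id=target_id, n_base=dictionary.size)


def append_descriptors(fp: Fingerprint, extra: Sequence[float]) -> Fingerprint:
    """Append extra descriptors (e.g. a docking score) after the base vector."""
    extra = np.asarray(list(extra), dtype=float)
    if extra.size and not np.all(np.isfinite(extra)):
        raise ValueError("appended descriptors must be finite")
    return Fingerprint(
        values=np.concatenate([fp.values, extra]),
        mode=fp.mode,
        molecule_id=fp.molecule_id,
        target_id=fp.target_id,
        n_base=fp.n_base,
    )


class TifpVectorizer(TransformerMixin, BaseEstimator):
    """Corpus-fitted triplet-fingerprint vectoriser.

    ``fit`` consumes an iterable of pseudoatom lists (one complex each),
    enumerates their triplet keys and retains the ``size`` most frequent as
    the feature dictionary; ``transform`` maps complexes to a dense
    ``(n, size)`` array of counts or presence bits.

    Parameters
    ----------
    size : dictionary length (default 211).
    mode : ``count`` or ``binary``.
    edges : inner distance-bin edges in Angstrom.
    """

    def __init__(self, size: int = DICTIONARY_SIZE, mode: str = "count",
                 edges: tuple[float, ...] = DEFAULT_EDGES):
        self.size = size
        self.mode = mode
        self.edges = edges

    def _keys(self, pseudoatoms: Sequence[Pseudoatom]) -> Counter[TripletKey]:
        return enumerate_triplets(pseudoatoms, BinScheme(edges=self.edges))

    def fit(self, X: Iterable[Sequence[Pseudoatom]], y=None) -> "TifpVectorizer":
        corpus = [self._keys(pas) for pas in X]
        self.dictionary_ = build_dictionary(corpus, size=self.size)
        self.n_features_out_ = self.dictionary_.size
        return self

    def transform(self, X: Iterable[Sequence[Pseudoatom]]) -> np.ndarray:
        if not hasattr(self, "dictionary_"):
            raise ValueError("TifpVectorizer is not fitted yet; call fit first")
        rows = [
            vectorize(self._keys(pas), self.dictionary_, mode=self.mode).values
            for pas in X
        ]
        return np.stack(rows) if rows else np.zeros((0, self.dictionary_.size))
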