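"""LSH-forest style index over histosketches.

Each sketch's first K*L slot values are split into L consecutive chunks of K
values; each chunk is serialized to a little-endian binary key and stored in
its chunk's hash table.  A query collides with a stored sketch when any chunk
key matches; under the standard banding model the collision probability at
slot-Jaccard similarity ``s`` is ``p(s) = 1 - (1 - s**K)**L``.  Self-tuning
evaluates every integer (K, L) pair with K*L <= Z against that model at the
requested similarity threshold and picks the pair minimizing the predicted
false-positive + false-negative rate.

Candidates returned by the tables are post-filtered by their exact slot-match
Jaccard against the query, so reported neighbours always satisfy the
threshold (no false positives); only the candidate-generation stage can miss
true neighbours, at the tuned false-negative rate.
"""

from __future__ import annotations

import json
from typing import NamedTuple

import numpy as np

from .exceptions import IncompatibleSketchError, LSHTuningError, MicrosketchError, SketchFormatError
from .histosketch import EMPTY_SLOT, HistoSketch, SketchConfig, _require_comparable

__all__ = [
    "tune_parameters",
    "collision_probability",
    "estimate_error_rates",
    "LSHForestIndex",
    "TunedParameters",
]

_FORMAT = "microsketch-lsh-index"
_VERSION = 1


class TunedParameters(NamedTuple):
    K: int
    L: int


def collision_probability(s: float, K: int, L: int) -> float:
    """P(>= 1 chunk collision) at slot-Jaccard similarity ``s``."""
    return 1.0 - (1.0 - s**K) ** L


def estimate_error_rates(
    K: int, L: int, threshold: float, fp_margin: float = 0.05
) -> tuple[float, float]:
    """(false-positive, false-negative) rates predicted by the banding model.

    FN is the miss probability for a pair exactly at the threshold; FP is the
    collision probability for a pair ``fp_margin`` below it.
    """
    fn = 1.0 - collision_probability(threshold, K, L)
    fp = collision_probability(max(threshold - fp_margin, 0.0), K, L)
    return fp, fn


def tune_parameters(
    sketch_size: int,
    threshold: float,
    max_fp: float = 1.0,
    max_fn: float = 1.0,
    fp_margin: float = 0.05,
) -> TunedParameters:
    """Choose (K, L) with K*L <= sketch_size minimizing predicted FP + FN.

    Ties prefer larger K (sharper chunks).  Raises :class:`LSHTuningError`
    when no pair satisfies both caps.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    best = None
    best_key = None
    for K in range(1, sketch_size + 1):
        for L in range(1, sketch_size // K + 1):
            fp, fn = estimate_error_rates(K, L, threshold, fp_margin)
            if fp > max_fp or fn > max_fn:
                continue
            key = (fp + fn, -K, L)
            if best_key is None or key < best_key:
                best_key = key
                best = TunedParameters(K, L)
    if best is None:
        raise LSHTuningError(
            "no (K, L) pair meets the requested error bounds; "
            "try a larger sketch size (Z) or looser bounds"
        )
    return best


def _chunk_keys(S: np.ndarray, K: int, L: int) -> list[bytes]:
    """Split the first K*L slot values into L little-endian binary chunk keys."""
    vals = np.asarray(S[: K * L], dtype="<u4")
    return [vals[l * K : (l + 1) * K].tobytes() for l in range(L)]


class LSHForestIndex:
    """Searchable store of histosketches at a Jaccard similarity threshold."""

    def __init__(
        self,
        K: int,
        L: int,
        threshold: float,
        config: SketchConfig,
        fp_margin: float = 0.05,
    ):
        if K * L > config.sketch_size:
            raise ValueError("K * L must not exceed the sketch size")
        self.K = K
        self.L = L
        self.threshold = threshold
        self.fp_margin = fp_margin
        self.config = config
        self.tables: list[dict[bytes, set[str]]] = [dict() for _ in range(L)]
        self.entries: dict[str, np.ndarray] = {}

    # -- construction ----------------------------------------------------

    @classmethod
    def create(
        cls,
        sketches,
        labels,
        threshold: float = 0.9,
        max_fp: float = 1.0,
        max_fn: float = 1.0,
        fp_margin: float = 0.05,
    ) -> "LSHForestIndex":
        """Tune (K, L) for the sketches' Z and index them all."""
        if len(sketches) == 0:
            raise MicrosketchError("cannot create an index from zero sketches")
        if len(sketches) != len(labels):
            raise ValueError("labels must match sketches in length")
        cfg = sketches[0].config
        K, L = tune_parameters(cfg.sketch_size, threshold, max_fp, max_fn, fp_margin)
        index = cls(K, L, threshold, cfg, fp_margin)
        for sk, label in zip(sketches, labels):
            index.add(sk, label)
        return index

    def add(self, sketch: HistoSketch, label: str) -> "LSHForestIndex":
        """Insert one sketch under ``label`` using the stored parameters."""
        _require_comparable(self.config, sketch.config)
        if label in self.entries:
            raise MicrosketchError(f"duplicate label {label!r} in index")
        if np.any(sketch.S == EMPTY_SLOT):
            raise MicrosketchError("cannot index a sketch with unfilled slots")
        self.entries[label] = sketch.S.copy()
        for table, key in zip(self.tables, _chunk_keys(sketch.S, self.K, self.L)):
            table.setdefault(key, set()).add(label)
        return self

    # -- search ----------------------------------------------------------

    def search(self, query: HistoSketch, filtered: bool = True) -> set[str]:
        """Labels colliding with the query in >= 1 chunk; by default
        post-filtered to those with slot-Jaccard >= threshold."""
        _require_comparable(self.config, query.config)
        candidates: set[str] = set()
        for table, key in zip(self.tables, _chunk_keys(query.S, self.K, self.L)):
            candidates |= table.get(key, set())
        if not filtered:
            return candidates
        hits = set()
        for label in candidates:
            sim = float(np.mean(self.entries[label] == query.S))
            if sim >= self.threshold:
                hits.add(label)
        return hits

    # -- serialization ---------------------------------------------------

    def save(self, path: str) -> None:
        cfg = self.config
        doc = {
            "format": _FORMAT,
            "version": _VERSION,
            "K": self.K,
            "L": self.L,
            "threshold": self.threshold,
            "fp_margin": self.fp_margin,
            "header": {
                "k": cfg.k,
                "sketch_size": cfg.sketch_size,
                "num_bins": cfg.num_bins,
                "master_seed": cfg.master_seed,
            },
            "entries": {label: s.tolist() for label, s in self.entries.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path: str) -> "LSHForestIndex":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != _FORMAT or doc.get("version") != _VERSION:
            raise SketchFormatError("not a recognised LSH index file")
        h = doc["header"]
        cfg = SketchConfig(
            k=h["k"],
            sketch_size=h["sketch_size"],
            num_bins=h["num_bins"],
            master_seed=h["master_seed"],
        )
        index = cls(doc["K"], doc["L"], doc["threshold"], cfg, doc["fp_margin"])
        for label, s in doc["entries"].items():
            sk = HistoSketch(
                cfg,
                np.asarray(s, dtype=np.int64),
                np.ones(cfg.sketch_size, dtype=np.float64),
            )
            index.add(sk, label)
        return index
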