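"""Histosketching: similarity-preserving sketches of streaming k-mer spectra.

The k-mer spectrum of a sample is viewed as a histogram: every canonical
k-mer is hashed uniformly into one of ``X`` bins and the bin's weight is the
accumulated k-mer frequency.  A histosketch summarizes this weighted set with
``Z`` slots.  For slot ``j``, every nonzero bin ``i`` receives a hash value
through consistent weighted sampling (CWS),

    y_ij = exp(log W_i - r_ij * beta_ij)
    a_ij = c_ij / (y_ij * exp(r_ij))

with r_ij, c_ij ~ Gamma(shape=2, scale=1) and beta_ij ~ Uniform(0, 1) drawn
as pure functions of (bin, slot, master seed).  The slot stores the bin with
the minimal hash, ``S_j``, together with that hash value, ``A_j``.  Because
``a_ij`` is an Exp(1) variate shared across samples and divided by the bin
weight, a bin wins a slot with probability proportional to its weight, and
the fraction of slots two sketches share estimates the similarity of the
underlying spectra.

Keeping ``A`` makes the sketch incrementally updatable: when new counts for a
bin arrive, its cumulative frequency is re-estimated from a persistent
count-min sketch, re-hashed, and swapped into any slot where it now achieves
a new minimum.  An optional decay step scales the counters and inflates the
stored minima before each update round so that old mass is gradually
forgotten (concept drift).
"""

from __future__ import annotations

import io
import json
import math
import struct
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from ._hash import GOLDEN, SALT_BIN, SALT_CWS, U64, mix64, seed_u64, to_unit
from .countmin import CountMinSketch, derive_cms_dimensions
from .exceptions import (
    EmptySpectrumError,
    IncompatibleSketchError,
    NothingToSketchError,
    SketchFormatError,
)
from .sequence_stream import SequenceRecord, encode_canonical_kmers, trim_quality

__all__ = [
    "SketchConfig",
    "KmerSpectrum",
    "CWSDraw",
    "HistoSketch",
    "assign_bin",
    "cws_draw",
    "cws_hash",
    "create_histosketch",
    "update_histosketch",
    "apply_decay",
    "sketch_stream",
    "save_sketch",
    "load_sketch",
]

#: Slot marker for "no bin credited yet".
EMPTY_SLOT = -1

_MAGIC = b"HSKT"
_VERSION = 1
_HEADER = struct.Struct("<4sBBIIqdQ")  # magic, version, k, Z, X, seed, decay, reads

# Cap on elements per temporary (bins x slots) matrix during vectorized
# hashing; bounds peak memory to a few hundred MB regardless of X and Z.
_CHUNK_ELEMENTS = 4_000_000


@dataclass(frozen=True)
class SketchConfig:
    """Parameters fixing a sketching run.

    Two sketches are comparable iff (k, sketch_size, num_bins, master_seed)
    match; the remaining fields steer counting and streaming only.

    Attributes
    ----------
    k : k-mer length (default 21).
    sketch_size : Z, number of sketch slots (default 512).
    num_bins : X, number of histogram bins; the default mirrors the
        count-min counter budget at the default epsilon/delta (4 x 20,000).
    epsilon, delta : count-min accuracy/confidence.
    decay_ratio : concept-drift forgetting parameter in [0, 1); 0 disables.
    interval : reads per counter between flushes to the sketcher; 0 means
        the whole input is one flush.
    master_seed : seeds all hashing; must match for sketches to be compared.
    num_counters : parallel counting processes fed round-robin.
    min_quality : 3'-trim threshold (0 = off).
    """

    k: int = 21
    sketch_size: int = 512
    num_bins: int = 80_000
    epsilon: float = 1e-4
    delta: float = 0.9
    decay_ratio: float = 0.0
    interval: int = 0
    master_seed: int = 42
    num_counters: int = 1
    min_quality: int = 0

    def __post_init__(self):
        if not 1 <= self.k <= 31:
            raise ValueError("k must be in [1, 31]")
        if self.sketch_size < 1:
            raise ValueError("sketch_size must be >= 1")
        if self.num_bins < 1:
            raise ValueError("num_bins must be >= 1")
        if not 0 <= self.decay_ratio < 1:
            raise ValueError("decay_ratio must be in [0, 1)")
        if self.interval < 0:
            raise ValueError("interval must be >= 0")
        if self.num_counters < 1:
            raise ValueError("num_counters must be >= 1")

    @property
    def comparability(self) -> tuple:
        return (self.k, self.sketch_size, self.num_bins, self.master_seed)


@dataclass
class KmerSpectrum:
    """Histogram of canonical k-mer mass across ``num_bins`` bins."""

    num_bins: int
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (self.num_bins,):
            raise ValueError("weights must have length num_bins")
        if self.weights.min(initial=0.0) < 0:
            raise ValueError("weights must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())

    @classmethod
    def from_kmers(
        cls, kmers: np.ndarray, num_bins: int, master_seed: int
    ) -> "KmerSpectrum":
        """Exact spectrum from an array of encoded k-mers (dictionary count)."""
        bins = assign_bin(kmers, num_bins, master_seed)
        weights = np.bincount(np.asarray(bins, dtype=np.intp), minlength=num_bins)
        return cls(num_bins, weights.astype(np.float64))


class CWSDraw(NamedTuple):
    """The three CWS variates for one (bin, slot) pair."""

    r: float
    c: float
    beta: float


def assign_bin(kmer, num_bins: int, master_seed: int):
    """Uniform deterministic bin assignment for encoded k-mers.

    Accepts a scalar or array; returns the same shape.  A seeded 64-bit mix
    hash of the value modulo ``num_bins``.
    """
    if num_bins < 1:
        raise ValueError("num_bins must be >= 1")
    with np.errstate(over="ignore"):
        salt = mix64(seed_u64(master_seed) + SALT_BIN)
    h = mix64(np.asarray(kmer, dtype=np.uint64) ^ salt) % U64(num_bins)
    if np.isscalar(kmer) or np.ndim(kmer) == 0:
        return int(h)
    return h.astype(np.int64)


def _cws_randoms(bins, slots, master_seed: int):
    """Vectorized CWS variates for broadcastable (bins, slots) index arrays.

    Returns (r, c, beta) float64 arrays of the broadcast shape.  r and c are
    Gamma(shape=2, scale=1) built as sums of two Exp(1) variates; beta is
    Uniform(0, 1).  Everything derives from counter-based splitmix64 streams
    keyed by (bin, slot, master_seed), so draws are identical across calls,
    processes and samples.
    """
    bins = np.asarray(bins, dtype=np.uint64)
    slots = np.asarray(slots, dtype=np.uint64)
    with np.errstate(over="ignore"):
        base = mix64(mix64(seed_u64(master_seed) + SALT_CWS) + (bins + U64(1)) * GOLDEN)
        h = mix64(base ^ ((slots + U64(1)) * GOLDEN))
        u = [to_unit(mix64(h + U64(t) * GOLDEN)) for t in range(5)]
    r = -np.log(u[0]) - np.log(u[1])
    c = -np.log(u[2]) - np.log(u[3])
    beta = u[4]
    return r, c, beta


def cws_draw(i: int, j: int, master_seed: int) -> CWSDraw:
    """CWS variates for bin ``i`` and slot ``j`` (pure function of inputs)."""
    r, c, beta = _cws_randoms(np.uint64(i), np.uint64(j), master_seed)
    return CWSDraw(float(r), float(c), float(beta))


def cws_hash(weight: float, draw: CWSDraw) -> tuple[float, float]:
    """Hash a positive bin weight under a CWS draw.

    Returns ``(y, a)`` with ``y = exp(log(weight) - r*beta)`` and
    ``a = c / (y * exp(r))``; ``a`` is the slot-competition hash value
    (smaller wins, stochastically smaller for heavier bins).
    """
    if weight <= 0:
        raise ValueError("weight must be positive (log undefined otherwise)")
    y = math.exp(math.log(weight) - draw.r * draw.beta)
    a = draw.c / (y * math.exp(draw.r))
    return y, a


def _min_hash_over_bins(bins, weights, slots, master_seed: int):
    """For each slot, the (winning bin, minimal hash) over candidate bins.

    ``bins``/``weights`` are 1-D candidate arrays; ``slots`` a 1-D slot-index
    array.  Ties go to the earliest candidate (argmin), so callers pass bins
    in ascending order for the lowest-bin-index tie-break.
    """
    bins = np.asarray(bins, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    slots = np.asarray(slots, dtype=np.int64)
    r, c, beta = _cws_randoms(bins[:, None].astype(np.uint64), slots[None, :].astype(np.uint64), master_seed)
    y = np.exp(np.log(weights)[:, None] - r * beta)
    a = c / (y * np.exp(r))
    winner = np.argmin(a, axis=0)
    cols = np.arange(slots.size)
    return bins[winner], a[winner, cols]


@dataclass
class HistoSketch:
    """The pair (S, A): Z winning bin identifiers and their minimal hashes."""

    config: SketchConfig
    S: np.ndarray = field(default=None)  # int64, EMPTY_SLOT where unfilled
    A: np.ndarray = field(default=None)  # float64, +inf where unfilled
    reads_consumed: int = 0

    def __post_init__(self):
        z = self.config.sketch_size
        if self.S is None:
            self.S = np.full(z, EMPTY_SLOT, dtype=np.int64)
        if self.A is None:
            self.A = np.full(z, np.inf, dtype=np.float64)
        self.S = np.asarray(self.S, dtype=np.int64)
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.S.shape != (z,) or self.A.shape != (z,):
            raise ValueError("S and A must both have length sketch_size")

    # -- comparability ---------------------------------------------------

    def require_comparable(self, other: "HistoSketch") -> None:
        _require_comparable(self.config, other.config)

    @property
    def filled(self) -> bool:
        return bool(np.all(self.S != EMPTY_SLOT))

    def copy(self) -> "HistoSketch":
        return HistoSketch(self.config, self.S.copy(), self.A.copy(), self.reads_consumed)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HistoSketch)
            and self.config.comparability == other.config.comparability
            and self.reads_consumed == other.reads_consumed
            and np.array_equal(self.S, other.S)
            and np.array_equal(self.A, other.A)
        )


def _require_comparable(a: SketchConfig, b: SketchConfig) -> None:
    names = ("k", "sketch_size (Z)", "num_bins (X)", "master_seed")
    for name, va, vb in zip(names, a.comparability, b.comparability):
        if va != vb:
            raise IncompatibleSketchError(
                f"sketches are not comparable: {name} differs ({va} != {vb})"
            )


def create_histosketch(spectrum: KmerSpectrum, config: SketchConfig) -> HistoSketch:
    """One-shot sketch of a spectrum: per slot, the bin minimizing the CWS hash.

    Ties are broken toward the lower bin index.  Raises
    :class:`EmptySpectrumError` when the spectrum has no nonzero bin.
    """
    if spectrum.num_bins != config.num_bins:
        raise IncompatibleSketchError(
            f"spectrum has {spectrum.num_bins} bins but config expects {config.num_bins}"
        )
    nz = np.flatnonzero(spectrum.weights > 0)
    if nz.size == 0:
        raise EmptySpectrumError("empty spectrum: no nonzero bins")
    hs = HistoSketch(config)
    _update_with_frequencies(hs, nz, spectrum.weights[nz])
    return hs


def _update_with_frequencies(hs: HistoSketch, bins: np.ndarray, freqs: np.ndarray) -> None:
    """Evaluate candidate bins (ascending order) against every slot in place."""
    z = hs.config.sketch_size
    bins = np.asarray(bins, dtype=np.int64)
    freqs = np.asarray(freqs, dtype=np.float64)
    step = max(1, _CHUNK_ELEMENTS // max(1, bins.size))
    for start in range(0, z, step):
        slots = np.arange(start, min(start + step, z), dtype=np.int64)
        cand_bins, cand_a = _min_hash_over_bins(bins, freqs, slots, hs.config.master_seed)
        better = cand_a < hs.A[slots]
        idx = slots[better]
        hs.S[idx] = cand_bins[better]
        hs.A[idx] = cand_a[better]


def update_histosketch(hs: HistoSketch, bin: int, cms: CountMinSketch) -> HistoSketch:
    """Incremental update: re-hash one bin at its cumulative frequency.

    The count-min sketch must already hold the bin's accumulated counts; its
    estimate is used as the bin weight, and any slot where the new hash is a
    strict improvement is taken over.  Updates mutate and return ``hs``.
    """
    f = cms.estimate(bin)
    if f <= 0:
        raise EmptySpectrumError(f"bin {bin} has no counted mass")
    _update_with_frequencies(hs, np.array([bin]), np.array([f]))
    return hs


def apply_decay(
    hs: HistoSketch, cms: CountMinSketch, decay_ratio: float
) -> tuple[HistoSketch, CountMinSketch]:
    """Gradual forgetting: scale counters by ``w = 1 - decay_ratio`` and divide
    the stored minima by ``w`` so old winners become easier to displace."""
    if not 0 <= decay_ratio < 1:
        raise ValueError("decay_ratio must be in [0, 1)")
    if decay_ratio > 0:
        w = 1.0 - decay_ratio
        cms.scale(w)
        hs.A /= w
    return hs, cms


class _Counter:
    """One counting process: a local count-min store plus its touched bins."""

    def __init__(self, config: SketchConfig):
        self.cms = CountMinSketch(config.epsilon, config.delta, config.master_seed)
        self.touched: set[int] = set()
        self.reads = 0

    def consume(self, bins: np.ndarray) -> None:
        self.reads += 1
        if bins.size:
            uniq, counts = np.unique(bins, return_counts=True)
            self.cms.add_many(uniq, counts.astype(np.float64))
            self.touched.update(int(b) for b in uniq)

    def wipe(self) -> None:
        self.cms.reset()
        self.touched.clear()
        self.reads = 0


def sketch_stream(
    records: Iterable[SequenceRecord], config: SketchConfig
) -> Iterator[HistoSketch]:
    """Sketch a read stream, yielding a snapshot after every flush.

    Reads are dealt round-robin to ``num_counters`` counting processes, each
    keeping a local count-min store of bin counts.  Every ``interval`` reads a
    counter flushes: decay is applied once (if enabled), the counter's touched
    bins are credited to the persistent count-min sketch, re-hashed at their
    cumulative estimates in ascending bin order, and the local store is wiped.
    A final snapshot is always yielded at end of stream.  With decay off, the
    final sketch is independent of interval, counter count and read order,
    because hashes depend only on cumulative counts.
    """
    persistent = CountMinSketch(config.epsilon, config.delta, config.master_seed)
    hs = HistoSketch(config)
    counters = [_Counter(config) for _ in range(config.num_counters)]
    any_kmers = False
    n_reads = 0

    def flush(counter: _Counter) -> None:
        nonlocal hs
        if not counter.touched:
            counter.wipe()
            return
        apply_decay(hs, persistent, config.decay_ratio)
        bins = np.array(sorted(counter.touched), dtype=np.int64)
        amounts = counter.cms.estimate_many(bins)
        persistent.add_many(bins, amounts)
        freqs = persistent.estimate_many(bins)
        _update_with_frequencies(hs, bins, freqs)
        counter.wipe()

    for idx, record in enumerate(records):
        if config.min_quality > 0:
            record = trim_quality(record, config.min_quality)
        kmers = encode_canonical_kmers(record.bases, config.k)
        bins = assign_bin(kmers, config.num_bins, config.master_seed)
        if kmers.size:
            any_kmers = True
        counter = counters[idx % config.num_counters]
        counter.consume(np.asarray(bins))
        n_reads += 1
        if config.interval > 0 and counter.reads == config.interval:
            flush(counter)
            hs.reads_consumed = n_reads
            yield hs.copy()

    if not any_kmers:
        raise NothingToSketchError("nothing to sketch: stream produced no valid k-mers")
    for counter in counters:
        flush(counter)
    hs.reads_consumed = n_reads
    yield hs.copy()


# -- serialization -------------------------------------------------------

_S_SENTINEL = 0xFFFFFFFF  # on-disk stand-in for an unfilled slot


def save_sketch(hs: HistoSketch) -> bytes:
    """Serialize a sketch to bytes (little-endian, versioned header)."""
    cfg = hs.config
    header = _HEADER.pack(
        _MAGIC,
        _VERSION,
        cfg.k,
        cfg.sketch_size,
        cfg.num_bins,
        cfg.master_seed,
        cfg.decay_ratio,
        hs.reads_consumed,
    )
    s = hs.S.copy()
    s[s == EMPTY_SLOT] = _S_SENTINEL
    return header + s.astype("<u4").tobytes() + hs.A.astype("<f8").tobytes()


def load_sketch(data: bytes) -> HistoSketch:
    """Inverse of :func:`save_sketch`; raises :class:`SketchFormatError` on a
    bad magic string, unknown version or truncated payload."""
    if len(data) < _HEADER.size:
        raise SketchFormatError("truncated sketch: header incomplete")
    magic, version, k, z, x, seed, decay, reads = _HEADER.unpack_from(data)
    if magic != _MAGIC:
        raise SketchFormatError(f"bad magic {magic!r}, expected {_MAGIC!r}")
    if version != _VERSION:
        raise SketchFormatError(f"unsupported sketch version {version}")
    expected = _HEADER.size + z * 4 + z * 8
    if len(data) != expected:
        raise SketchFormatError(
            f"truncated sketch: expected {expected} bytes, got {len(data)}"
        )
    s = np.frombuffer(data, dtype="<u4", count=z, offset=_HEADER.size).astype(np.int64)
    s[s == _S_SENTINEL] = EMPTY_SLOT
    a = np.frombuffer(data, dtype="<f8", count=z, offset=_HEADER.size + z * 4).copy()
    cfg = SketchConfig(
        k=k, sketch_size=z, num_bins=x, master_seed=seed, decay_ratio=decay
    )
    return HistoSketch(cfg, s, a, reads_consumed=reads)


def save_sketch_file(hs: HistoSketch, path: str) -> None:
    with open(path, "wb") as fh:
        fh.write(save_sketch(hs))


def load_sketch_file(path: str) -> HistoSketch:
    with open(path, "rb") as fh:
        return load_sketch(fh.read())


def sketch_to_json(hs: HistoSketch) -> str:
    """JSON export mirroring the binary fields (interoperability aid)."""
    cfg = hs.config
    return json.dumps(
        {
            "magic": _MAGIC.decode(),
            "version": _VERSION,
            "k": cfg.k,
            "sketch_size": cfg.sketch_size,
            "num_bins": cfg.num_bins,
            "master_seed": cfg.master_seed,
            "decay_ratio": cfg.decay_ratio,
            "reads_consumed": hs.reads_consumed,
            "S": hs.S.tolist(),
            "A": hs.A.tolist(),
        }
    )


def sketch_from_json(text: str) -> HistoSketch:
    d = json.loads(text)
    if d.get("magic") != _MAGIC.decode() or d.get("version") != _VERSION:
        raise SketchFormatError("bad JSON sketch header")
    cfg = SketchConfig(
        k=d["k"],
        sketch_size=d["sketch_size"],
        num_bins=d["num_bins"],
        master_seed=d["master_seed"],
        decay_ratio=d["decay_ratio"],
    )
    return HistoSketch(
        cfg,
        np.asarray(d["S"], dtype=np.int64),
        np.asarray(d["A"], dtype=np.float64),
        reads_consumed=d["reads_consumed"],
    )
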