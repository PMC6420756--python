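"""FASTQ stream parsing, quality trimming and canonical k-mer encoding.

Reads are consumed record-by-record from a (possibly gzip-compressed) FASTQ
byte stream — a file or standard input — without ever materializing the whole
file.  Each read is optionally 3'-trimmed and then decomposed into canonical
k-mers packed into 64-bit integers: base codes A=0, C=1, G=2, T=3 are packed
two bits each, first base in the most-significant position, and the canonical
form is the numeric minimum of the forward and reverse-complement encodings.
Windows containing any non-ACGT symbol are skipped (substituting would
fabricate k-mers that were never sequenced).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import BinaryIO, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .exceptions import FastqParseError

__all__ = [
    "SequenceRecord",
    "read_fastq",
    "open_fastq",
    "trim_quality",
    "encode_canonical_kmers",
    "reverse_complement",
]

_PHRED_OFFSET = 33

# Base → 2-bit code lookup; 255 marks ambiguous/invalid symbols.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class SequenceRecord:
    """One FASTQ read: identifier, bases and per-base Phred quality scores."""

    identifier: str
    bases: str
    qualities: np.ndarray  # integer Phred scores, same length as bases

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int32)
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"record {self.identifier!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SequenceRecord)
            and self.identifier == other.identifier
            and self.bases == other.bases
            and np.array_equal(self.qualities, other.qualities)
        )


def read_fastq(stream: BinaryIO, gzipped: bool = False) -> Iterator[SequenceRecord]:
    """Yield :class:`SequenceRecord` objects from a FASTQ byte stream.

    Parameters
    ----------
    stream
        Binary file-like object (a file handle or ``sys.stdin.buffer``).
    gzipped
        Transparently decompress the stream when True.

    Raises
    ------
    FastqParseError
        Naming the 1-based record index, on a truncated record, a missing
        ``+`` line, or a sequence/quality length mismatch.
    """
    if gzipped:
        stream = gzip.GzipFile(fileobj=stream, mode="rb")
    text = io.TextIOWrapper(stream, encoding="ascii")
    parser = FastqGeneralIterator(text)
    index = 0
    while True:
        try:
            title, seq, qual = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(index + 1, str(exc)) from exc
        index += 1
        qualities = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32)
        qualities -= _PHRED_OFFSET
        if qualities.size and qualities.min() < 0:
            raise FastqParseError(index, "quality character below Phred+33 '!'")
        yield SequenceRecord(title.split()[0] if title else "", seq, qualities)


def open_fastq(path: str) -> Iterator[SequenceRecord]:
    """Open a FASTQ file by path (``-`` = stdin); ``.gz`` suffix → gzip."""
    if path == "-":
        import sys

        return read_fastq(sys.stdin.buffer, gzipped=False)
    gzipped = path.endswith(".gz")
    handle = open(path, "rb")
    return read_fastq(handle, gzipped=gzipped)


def trim_quality(record: SequenceRecord, min_quality: int) -> SequenceRecord:
    """3'-trim a read by the BWA-style running-sum rule.

    Scanning from the 3' end, the cut point maximizing
    ``sum(min_quality - q_i)`` over the trimmed suffix is chosen; the read is
    truncated there.  ``min_quality == 0`` disables trimming (identity).
    """
    if min_quality < 0:
        raise ValueError("min_quality must be >= 0")
    if min_quality == 0 or len(record) == 0:
        return record
    q = record.qualities
    running = 0
    best = 0
    cut = len(q)
    for i in range(len(q) - 1, -1, -1):
        running += min_quality - int(q[i])
        if running > best:
            best = running
            cut = i
    if cut == len(q):
        return record
    return SequenceRecord(record.identifier, record.bases[:cut], q[:cut])


def reverse_complement(bases: str) -> str:
    """Reverse complement of a nucleotide string (case preserved per base)."""
    return bases.translate(_COMPLEMENT)[::-1]


def encode_canonical_kmers(bases: str, k: int) -> np.ndarray:
    """Decompose ``bases`` into canonical k-mers encoded as uint64.

    One value is emitted per length-k window whose bases are all in
    {A, C, G, T}; other windows are skipped.  Each value is
    ``min(forward, reverse_complement)`` of the 2-bit packed encodings and is
    therefore ``< 4**k``.  Returns an empty array when ``k > len(bases)``.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    n = len(bases)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    valid = codes != 255
    # A window is valid iff all k of its positions are valid.
    cs = np.concatenate(([0], np.cumsum(valid)))
    window_ok = (cs[k:] - cs[:-k]) == k

    codes64 = codes.astype(np.uint64)
    codes64[~valid] = 0  # placeholder; these windows are dropped anyway
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    three = np.uint64(3)
    for t in range(k):
        col = codes64[t : t + m]
        fwd = (fwd << np.uint64(2)) | col
        rc |= (three - col) << np.uint64(2 * t)
    canonical = np.minimum(fwd, rc)
    return canonical[window_ok]
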