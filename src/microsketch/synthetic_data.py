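"""Synthetic microbial communities with known spectra and overlaps.

A community is a set of random i.i.d. ACGT "genomes" plus a relative
abundance vector.  At k = 21 the chance of two independent random genomes
sharing a k-mer is negligible, so the k-mer overlap between two communities
is controlled purely by which taxa they share and at what abundance — making
planted similarities analytically predictable and exactly computable by the
dictionary-count oracle in :func:`exact_spectrum`.

Read generation draws reads from taxa proportional to abundance, with uniform
start positions, uniform strand, per-base substitution errors and flat
quality scores; it writes standard (optionally gzipped) FASTQ.  Perturbation
operators emulate the two study designs relevant to streaming microbiome
comparison: an abundance shift (e.g. a diet change moving mass between taxa)
and a taxon swap (replacement of community members).

Everything is deterministic under its seed; streams regenerate
byte-identically.
"""

from __future__ import annotations

import gzip
import io
import json
import math
from dataclasses import dataclass

import numpy as np

from .histosketch import KmerSpectrum, assign_bin
from .sequence_stream import SequenceRecord, encode_canonical_kmers, reverse_complement

__all__ = [
    "SyntheticCommunity",
    "make_community",
    "perturb_community",
    "generate_reads",
    "exact_spectrum",
    "weighted_jaccard_spectra",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticCommunity:
    """Random genomes plus a relative-abundance vector summing to 1."""

    taxa: list[str]
    abundances: np.ndarray
    seed: int

    def __post_init__(self):
        self.abundances = np.asarray(self.abundances, dtype=np.float64)
        if len(self.taxa) != len(self.abundances):
            raise ValueError("one abundance per taxon required")
        if self.abundances.min(initial=0.0) < 0:
            raise ValueError("abundances must be non-negative")
        total = self.abundances.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("abundances must sum to 1")

    def to_json(self) -> str:
        return json.dumps(
            {"taxa": self.taxa, "abundances": self.abundances.tolist(), "seed": self.seed}
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticCommunity":
        d = json.loads(text)
        return cls(d["taxa"], np.asarray(d["abundances"]), d["seed"])


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_community(
    n_taxa: int,
    genome_length: int,
    abundance_profile: str = "uniform",
    seed: int = 0,
    abundances=None,
) -> SyntheticCommunity:
    """Build a community of ``n_taxa`` random genomes.

    ``abundance_profile`` is ``uniform``, ``lognormal`` (sigma = 1, a typical
    skew for microbial communities) or ``explicit`` (pass ``abundances``).
    Deterministic under ``seed``.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    taxa = [_random_genome(rng, genome_length) for _ in range(n_taxa)]
    if abundance_profile == "uniform":
        ab = np.full(n_taxa, 1.0 / n_taxa)
    elif abundance_profile == "lognormal":
        ab = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
        ab /= ab.sum()
    elif abundance_profile == "explicit":
        ab = np.asarray(abundances, dtype=np.float64)
        if ab.shape != (n_taxa,):
            raise ValueError(f"explicit profile must have length {n_taxa}")
        ab = ab / ab.sum()
    else:
        raise ValueError(f"unknown abundance profile {abundance_profile!r}")
    return SyntheticCommunity(taxa, ab, seed)


def perturb_community(
    base: SyntheticCommunity, shift: float, mode: str = "taxon-swap", seed: int = 0
) -> SyntheticCommunity:
    """Perturbed copy of a community.

    ``abundance-shift`` moves ``shift`` of the total relative abundance onto a
    random (Dirichlet) profile; ``taxon-swap`` replaces ``ceil(shift *
    n_taxa)`` genomes with fresh random ones of the same length.  ``shift=0``
    returns the base unchanged.
    """
    if not 0 <= shift <= 1:
        raise ValueError("shift must be in [0, 1]")
    if shift == 0:
        return base
    rng = np.random.default_rng(seed)
    n = len(base.taxa)
    if mode == "abundance-shift":
        target = rng.dirichlet(np.ones(n))
        ab = (1.0 - shift) * base.abundances + shift * target
        return SyntheticCommunity(list(base.taxa), ab / ab.sum(), seed)
    if mode == "taxon-swap":
        n_swap = math.ceil(shift * n)
        swap_idx = rng.choice(n, size=n_swap, replace=False)
        taxa = list(base.taxa)
        for i in swap_idx:
            taxa[i] = _random_genome(rng, len(taxa[i]))
        return SyntheticCommunity(taxa, base.abundances.copy(), seed)
    raise ValueError(f"unknown perturbation mode {mode!r}")


def generate_reads(
    community: SyntheticCommunity,
    n_reads: int,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
    quality: int = 40,
    gzipped: bool = False,
) -> bytes:
    """FASTQ byte stream of ``n_reads`` reads sampled from the community.

    Taxa are drawn proportional to abundance, start positions and strand
    uniformly; substitution errors occur per base at ``error_rate``; quality
    scores are flat at ``quality``.  Deterministic under ``seed``.
    """
    if any(read_length > len(t) for t in community.taxa):
        raise ValueError("read_length exceeds a genome length")
    rng = np.random.default_rng(seed)
    qual_line = chr(quality + 33) * read_length
    taxon_idx = rng.choice(len(community.taxa), size=n_reads, p=community.abundances)
    out = io.BytesIO()
    handle = gzip.GzipFile(fileobj=out, mode="wb", mtime=0) if gzipped else out
    for r, t in enumerate(taxon_idx):
        genome = community.taxa[t]
        start = int(rng.integers(0, len(genome) - read_length + 1))
        read = genome[start : start + read_length]
        if rng.integers(0, 2):
            read = reverse_complement(read)
        if error_rate > 0:
            bases = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
            hit = np.flatnonzero(rng.random(read_length) < error_rate)
            for pos in hit:
                choices = [b for b in b"ACGT" if b != bases[pos]]
                bases[pos] = choices[int(rng.integers(0, 3))]
            read = bases.tobytes().decode("ascii")
        handle.write(f"@r{r} taxon={t}\n{read}\n+\n{qual_line}\n".encode("ascii"))
    if gzipped:
        handle.close()
    return out.getvalue()


def exact_spectrum(source, k: int, num_bins: int, master_seed: int) -> KmerSpectrum:
    """Ground-truth k-mer spectrum by exact dictionary counting.

    ``source`` is a :class:`SyntheticCommunity` (per-genome canonical k-mer
    counts weighted by abundance) or an iterable of
    :class:`~microsketch.sequence_stream.SequenceRecord` (unit weight per
    k-mer occurrence).  This is the oracle the count-min and histosketch
    approximations are validated against.
    """
    weights = np.zeros(num_bins, dtype=np.float64)
    if isinstance(source, SyntheticCommunity):
        for genome, ab in zip(source.taxa, source.abundances):
            kmers = encode_canonical_kmers(genome, k)
            if kmers.size:
                bins = assign_bin(kmers, num_bins, master_seed)
                weights += ab * np.bincount(
                    np.asarray(bins, dtype=np.intp), minlength=num_bins
                )
    else:
        for record in source:
            kmers = encode_canonical_kmers(record.bases, k)
            if kmers.size:
                bins = assign_bin(kmers, num_bins, master_seed)
                weights += np.bincount(
                    np.asarray(bins, dtype=np.intp), minlength=num_bins
                )
    return KmerSpectrum(num_bins, weights)


def weighted_jaccard_spectra(a: KmerSpectrum, b: KmerSpectrum) -> float:
    """Exact weighted Jaccard similarity sum(min)/sum(max) of two spectra."""
    if a.num_bins != b.num_bins:
        raise ValueError("spectra have different bin counts")
    union = np.maximum(a.weights, b.weights).sum()
    if union == 0:
        return 1.0
    return float(np.minimum(a.weights, b.weights).sum() / union)
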