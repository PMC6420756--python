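"""Deterministic 64-bit hashing primitives.

Every source of (pseudo-)randomness in the sketching pipeline — bin
assignment, count-min table hashing, and the consistent-weighted-sampling
draws — is derived from counter-based splitmix64 streams.  This makes each
quantity a pure function of (key, master seed): reproducible across calls,
processes and platforms, and vectorizable with numpy uint64 arithmetic.
"""

from __future__ import annotations

import numpy as np

U64 = np.uint64

GOLDEN = U64(0x9E3779B97F4A7C15)

# Domain-separation salts so the bin-assignment hash, the count-min table
# hashes and the CWS streams are independent even under a shared master seed.
SALT_BIN = U64(0xA5A5A5A55F3759DF)
SALT_CMS = U64(0xC0FFEE123456789B)
SALT_CWS = U64(0x5EEDFACE0F1E2D3C)

_M1 = U64(0xBF58476D1CE4E5B9)
_M2 = U64(0x94D049BB133111EB)
_S30 = U64(30)
_S27 = U64(27)
_S31 = U64(31)
_S11 = U64(11)

_INV_2_53 = 2.0 ** -53


def seed_u64(seed: int) -> np.uint64:
    """Map an arbitrary Python integer seed onto uint64 (two's complement wrap)."""
    return U64(int(seed) & 0xFFFFFFFFFFFFFFFF)


def mix64(x):
    """splitmix64 finalizer: a bijective avalanche mix on uint64 scalars/arrays.

    uint64 wrap-around is the intended modular arithmetic.
    """
    x = np.asarray(x, dtype=np.uint64)
    with np.errstate(over="ignore"):
        x = (x ^ (x >> _S30)) * _M1
        x = (x ^ (x >> _S27)) * _M2
        return x ^ (x >> _S31)


def u64_mul_add(a, b, c):
    """(a * b + c) mod 2**64 without overflow warnings."""
    with np.errstate(over="ignore"):
        return np.asarray(a, dtype=np.uint64) * b + c


def hash_u64(keys, seed: np.uint64):
    """Seeded 64-bit hash of integer keys (vectorized)."""
    return mix64(np.asarray(keys, dtype=np.uint64) ^ mix64(seed))


def to_unit(x) -> np.ndarray:
    """Map uint64 words to floats strictly inside (0, 1).

    The top 53 bits are used, offset by half an ulp so 0 and 1 are never
    produced (both endpoints would break the log transforms downstream).
    """
    return ((np.asarray(x, dtype=np.uint64) >> _S11).astype(np.float64) + 0.5) * _INV_2_53
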