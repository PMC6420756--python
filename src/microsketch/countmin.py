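"""Count-min sketch: fixed-memory approximate frequency counting.

The sketch holds a ``depth x width`` matrix of real-valued counters.  Adding
``amount`` for a key increments one counter per table (row), addressed by an
independent seeded 64-bit hash of the key; the frequency estimate is the
minimum over tables and therefore never underestimates the true added total.
With depth and width derived from a relative-accuracy factor ``epsilon`` and a
confidence ``delta`` (see :func:`derive_cms_dimensions`), the overestimate for
any key is at most ``epsilon * N`` with probability at least ``delta``, where
``N`` is the total mass added.

Counters are floats, not integers, so that the uniform decay scaling used for
concept-drift forgetting composes cleanly with counting.
"""

from __future__ import annotations

import math

import numpy as np

from ._hash import GOLDEN, SALT_CMS, mix64, seed_u64

__all__ = ["CountMinSketch", "derive_cms_dimensions"]


def derive_cms_dimensions(epsilon: float, delta: float) -> tuple[int, int]:
    """Derive (depth, width) from relative accuracy ``epsilon`` and confidence
    ``delta``: ``depth = ceil(log(1 - delta) / log(0.5))`` and
    ``width = ceil(2 / epsilon)``.

    At the defaults (epsilon=0.0001, delta=0.9) this gives 4 tables of 20,000
    counters each.
    """
    if not 0 < epsilon < 1:
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    if not 0 < delta < 1:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    depth = _ceil_tol(math.log(1.0 - delta) / math.log(0.5))
    width = _ceil_tol(2.0 / epsilon)
    return depth, width


def _ceil_tol(x: float, rel_tol: float = 1e-9) -> int:
    """Ceiling that forgives float round-off just above an integer."""
    r = round(x)
    if abs(x - r) <= rel_tol * max(1.0, abs(x)):
        return int(r)
    return int(math.ceil(x))


class CountMinSketch:
    """Approximate counter over integer keys.

    Parameters
    ----------
    epsilon, delta
        Accuracy/confidence controlling the dimensions (defaults reproduce
        4 x 20,000 counters).
    master_seed
        Seeds the per-table hash functions; two sketches fed identical add
        sequences under the same seed are identical.
    """

    def __init__(self, epsilon: float = 1e-4, delta: float = 0.9, master_seed: int = 42):
        self.epsilon = float(epsilon)
        self.delta = float(delta)
        self.master_seed = int(master_seed)
        self.depth, self.width = derive_cms_dimensions(epsilon, delta)
        with np.errstate(over="ignore"):
            base = mix64(seed_u64(master_seed) + SALT_CMS)
            self.table_seeds = mix64(base + np.arange(self.depth, dtype=np.uint64) * GOLDEN)
        self.counters = np.zeros((self.depth, self.width), dtype=np.float64)
        self.total_added = 0.0

    # -- hashing ---------------------------------------------------------

    def _columns(self, keys: np.ndarray) -> np.ndarray:
        """(depth, n) counter column indices for each key."""
        keys = np.asarray(keys, dtype=np.uint64).ravel()
        h = mix64(keys[None, :] ^ self.table_seeds[:, None])
        return (h % np.uint64(self.width)).astype(np.intp)

    # -- counting --------------------------------------------------------

    def add(self, key: int, amount: float = 1.0) -> "CountMinSketch":
        if amount <= 0:
            raise ValueError("amount must be positive")
        cols = self._columns(np.array([key], dtype=np.uint64))[:, 0]
        self.counters[np.arange(self.depth), cols] += amount
        self.total_added += amount
        return self

    def add_many(self, keys, amounts) -> "CountMinSketch":
        """Vectorized add; ``amounts`` broadcast against ``keys``."""
        keys = np.asarray(keys, dtype=np.uint64).ravel()
        amounts = np.broadcast_to(np.asarray(amounts, dtype=np.float64), keys.shape)
        if keys.size == 0:
            return self
        if amounts.min() <= 0:
            raise ValueError("amounts must be positive")
        cols = self._columns(keys)
        for t in range(self.depth):
            np.add.at(self.counters[t], cols[t], amounts)
        self.total_added += float(amounts.sum())
        return self

    def estimate(self, key: int) -> float:
        return float(self.estimate_many(np.array([key], dtype=np.uint64))[0])

    def estimate_many(self, keys) -> np.ndarray:
        """Minimum-over-tables estimates for an array of keys."""
        keys = np.asarray(keys, dtype=np.uint64).ravel()
        if keys.size == 0:
            return np.empty(0, dtype=np.float64)
        cols = self._columns(keys)
        rows = np.arange(self.depth)[:, None]
        return self.counters[rows, cols].min(axis=0)

    def scale(self, factor: float) -> "CountMinSketch":
        """Multiply every counter by ``factor`` in (0, 1] (gradual forgetting)."""
        if not 0 < factor <= 1:
            raise ValueError("scale factor must be in (0, 1]")
        if factor != 1.0:
            self.counters *= factor
            self.total_added *= factor
        return self

    def reset(self) -> "CountMinSketch":
        self.counters[:] = 0.0
        self.total_added = 0.0
        return self
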