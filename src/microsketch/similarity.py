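"""Sketch-level similarity and distance estimation.

Plain Jaccard similarity between two histosketches is the fraction of slots
holding the same bin identifier — an unbiased estimate of the spectra's
similarity because each slot is an independent weighted sample.

The weighted metrics additionally use the stored minimal hash values.  Since
a slot's hash is (up to a shared random factor) inversely proportional to the
winning bin's weight, ``u_j = 1 / A_j`` serves as a per-slot weight
surrogate.  The weighted Jaccard distance is

    1 - sum_j min(u_j, v_j) [where S_j agree] / sum_j max(u_j, v_j)

with the intersection term restricted to slots whose bin identifiers agree
(disagreeing slots share no mass); Bray-Curtis and Euclidean are the standard
formulas over the surrogate vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, euclidean

from .exceptions import IncompatibleSketchError, MicrosketchError
from .histosketch import HistoSketch, _require_comparable

__all__ = [
    "jaccard_similarity",
    "weighted_jaccard_distance",
    "weighted_jaccard_similarity",
    "vector_distance",
    "pairwise_matrix",
    "DistanceMatrix",
    "METRICS",
]

#: metric name -> (callable, kind); "similarity" metrics have diagonal 1,
#: "distance" metrics diagonal 0.
METRICS = {}


def _check_pair(a: HistoSketch, b: HistoSketch) -> None:
    _require_comparable(a.config, b.config)
    if not (a.filled and b.filled):
        raise MicrosketchError("cannot compare sketches with unfilled slots")


def jaccard_similarity(a: HistoSketch, b: HistoSketch) -> float:
    """Fraction of slots where the two sketches hold the same bin."""
    _check_pair(a, b)
    return float(np.mean(a.S == b.S))


def _surrogate(hs: HistoSketch, kind: str = "inverse") -> np.ndarray:
    """Per-slot weight surrogate derived from the stored hash values.

    ``inverse`` (default): 1/A, monotone in the underlying bin weight.
    ``raw``: the hash values themselves.  ``rank``: inverse rank of A
    (largest hash -> 1), a scale-free alternative.
    """
    if not np.all(np.isfinite(hs.A)):
        raise MicrosketchError("sketch has non-finite hash values")
    if kind == "inverse":
        return 1.0 / hs.A
    if kind == "raw":
        return hs.A.copy()
    if kind == "rank":
        order = np.argsort(np.argsort(-hs.A))
        return (order + 1.0) / len(hs.A)
    raise ValueError(f"unknown weight surrogate {kind!r}")


def weighted_jaccard_distance(
    a: HistoSketch, b: HistoSketch, surrogate: str = "inverse"
) -> float:
    """Weighted Jaccard distance over per-slot weight surrogates in [0, 1]."""
    _check_pair(a, b)
    u = _surrogate(a, surrogate)
    v = _surrogate(b, surrogate)
    agree = a.S == b.S
    inter = np.minimum(u, v)[agree].sum()
    union = np.maximum(u, v).sum()
    if union == 0:
        return 0.0
    return float(1.0 - inter / union)


def weighted_jaccard_similarity(
    a: HistoSketch, b: HistoSketch, surrogate: str = "inverse"
) -> float:
    return 1.0 - weighted_jaccard_distance(a, b, surrogate)


def vector_distance(a: HistoSketch, b: HistoSketch, metric: str = "braycurtis") -> float:
    """Bray-Curtis dissimilarity or Euclidean norm over the weight surrogates."""
    _check_pair(a, b)
    u = _surrogate(a)
    v = _surrogate(b)
    if metric in ("braycurtis", "bray-curtis"):
        return float(braycurtis(u, v))
    if metric == "euclidean":
        return float(euclidean(u, v))
    raise ValueError(f"unknown metric {metric!r}")


METRICS.update(
    {
        "jaccard": (jaccard_similarity, "similarity"),
        "weighted-jaccard": (weighted_jaccard_distance, "distance"),
        "weighted-jaccard-similarity": (weighted_jaccard_similarity, "similarity"),
        "braycurtis": (lambda a, b: vector_distance(a, b, "braycurtis"), "distance"),
        "euclidean": (lambda a, b: vector_distance(a, b, "euclidean"), "distance"),
    }
)


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise metric values."""

    labels: list
    values: np.ndarray
    metric: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (condensed) form, for scipy hierarchical clustering."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def pairwise_matrix(sketches, labels, metric: str = "jaccard") -> DistanceMatrix:
    """All-vs-all metric matrix over >= 2 comparable sketches."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if len(sketches) < 2:
        raise MicrosketchError("need >= 2 sketches for a pairwise matrix")
    if len(sketches) != len(labels):
        raise ValueError("labels must match sketches in length")
    func, kind = METRICS[metric]
    n = len(sketches)
    values = np.zeros((n, n), dtype=np.float64)
    diag = 1.0 if kind == "similarity" else 0.0
    np.fill_diagonal(values, diag)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[i, j] = values[j, i] = func(sketches[i], sketches[j])
            except IncompatibleSketchError as exc:
                raise IncompatibleSketchError(
                    f"pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
    return DistanceMatrix(list(labels), values, metric)
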