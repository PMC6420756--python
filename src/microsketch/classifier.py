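"""Random-forest classification of histosketches, including streaming
prediction that can terminate a data stream early.

Features are the raw S-vectors (the Z winning bin identifiers); the hash
values A are discarded.  Training uses a stratified 80/20 split and a forest
of 1000 bootstrapped trees, reporting held-out accuracy/F1/precision/recall
plus a stratified 10-fold cross-validation summary.  An optional frequency
(one-hot-count) encoding of the S-vectors is available because tree splits on
arbitrary integer identifiers are representation-sensitive; the default stays
with the raw identifiers.

For streaming classification, sketch snapshots arriving from an in-progress
stream are classified one by one; the first prediction whose maximum class
probability reaches the threshold is returned together with the number of
snapshots consumed, signalling upstream that sketching may stop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

from .exceptions import IncompatibleSketchError, MicrosketchError
from .histosketch import EMPTY_SLOT, HistoSketch, SketchConfig, _require_comparable

__all__ = [
    "LabelledSketchSet",
    "TrainedModel",
    "StreamPrediction",
    "train",
    "predict",
    "predict_stream",
    "save_model",
    "load_model",
]


@dataclass
class LabelledSketchSet:
    """Sketch S-vectors as a feature matrix plus per-sample class labels."""

    features: np.ndarray  # (n_samples, Z) integer bin identifiers
    labels: np.ndarray
    config: SketchConfig

    @classmethod
    def from_sketches(cls, sketches, labels) -> "LabelledSketchSet":
        if len(sketches) != len(labels):
            raise ValueError("labels must match sketches in length")
        if len(sketches) == 0:
            raise MicrosketchError("empty sketch set")
        cfg = sketches[0].config
        rows = []
        for sk in sketches:
            _require_comparable(cfg, sk.config)
            if np.any(sk.S == EMPTY_SLOT):
                raise MicrosketchError("cannot featurize a sketch with unfilled slots")
            rows.append(sk.S)
        return cls(np.vstack(rows).astype(np.int64), np.asarray(labels), cfg)


@dataclass
class TrainedModel:
    """A fitted forest plus the comparability header and training report."""

    forest: RandomForestClassifier
    config: SketchConfig
    metrics: dict
    cv_scores: np.ndarray
    seed: int
    encoding: str = "raw"

    @property
    def classes(self):
        return self.forest.classes_

    def _featurize(self, sketch: HistoSketch) -> np.ndarray:
        _require_comparable(self.config, sketch.config)
        return _encode(sketch.S[None, :], self.encoding, self.config.num_bins)


def _encode(S: np.ndarray, encoding: str, num_bins: int) -> np.ndarray:
    """Feature encoding of S-vector rows: raw identifiers or bin frequencies."""
    if encoding == "raw":
        return S.astype(np.float64)
    if encoding == "frequency":
        out = np.zeros((S.shape[0], num_bins), dtype=np.float64)
        for i, row in enumerate(S):
            np.add.at(out[i], row, 1.0)
        return out
    raise ValueError(f"unknown encoding {encoding!r}")


def train(
    sketch_set: LabelledSketchSet,
    seed: int = 0,
    n_estimators: int = 1000,
    test_size: float = 0.2,
    cv_folds: int = 10,
    encoding: str = "raw",
) -> TrainedModel:
    """Fit a bootstrapped random forest on a stratified 80% split.

    Held-out metrics come from the remaining 20%; a stratified k-fold
    cross-validation over the full data (fresh forests per fold) is reported
    alongside.  Deterministic under ``seed``.
    """
    y = np.asarray(sketch_set.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise MicrosketchError("training needs >= 2 classes")
    if len(y) < 10:
        raise MicrosketchError("training needs >= 10 samples")
    X = _encode(sketch_set.features, encoding, sketch_set.config.num_bins)

    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators, bootstrap=True, random_state=seed, n_jobs=1
    )
    forest.fit(X_train, y_train)
    y_pred = forest.predict(X_test)
    average = "binary" if len(classes) == 2 else "weighted"
    pos_label = classes[1] if len(classes) == 2 else 1
    metrics = {
        "accuracy": float(accuracy_score(y_test, y_pred)),
        "f1": float(f1_score(y_test, y_pred, average=average, pos_label=pos_label)),
        "precision": float(
            precision_score(y_test, y_pred, average=average, pos_label=pos_label, zero_division=0)
        ),
        "recall": float(
            recall_score(y_test, y_pred, average=average, pos_label=pos_label, zero_division=0)
        ),
        "n_train": int(len(y_train)),
        "n_test": int(len(y_test)),
    }
    folds = min(cv_folds, int(counts.min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_scores = cross_val_score(clone(forest), X, y, cv=cv)
    return TrainedModel(forest, sketch_set.config, metrics, cv_scores, seed, encoding)


def predict(model: TrainedModel, sketch: HistoSketch):
    """(label, class-probability vector) for one sketch."""
    proba = model.forest.predict_proba(model._featurize(sketch))[0]
    return model.classes[int(np.argmax(proba))], proba


class StreamPrediction(NamedTuple):
    label: object
    probability: float
    snapshots_consumed: int
    reached_threshold: bool


def predict_stream(
    model: TrainedModel,
    snapshots: Iterable[HistoSketch],
    prob_threshold: float = 0.9,
) -> StreamPrediction:
    """Classify sketch snapshots as they arrive; stop at the threshold.

    Returns the first prediction whose maximum class probability is at least
    ``prob_threshold`` (the caller should then terminate the stream).  If the
    stream ends first, the final snapshot's prediction is returned with
    ``reached_threshold=False``.
    """
    if not 0.5 < prob_threshold <= 1:
        raise ValueError("prob_threshold must be in (0.5, 1]")
    last = None
    consumed = 0
    for snapshot in snapshots:
        consumed += 1
        label, proba = predict(model, snapshot)
        p = float(proba.max())
        last = StreamPrediction(label, p, consumed, p >= prob_threshold)
        if last.reached_threshold:
            return last
    if last is None:
        raise MicrosketchError("empty snapshot stream")
    return last


def save_model(model: TrainedModel, path: str) -> None:
    """Serialize the forest plus header; writes a JSON training-report sidecar."""
    cfg = model.config
    joblib.dump(
        {
            "forest": model.forest,
            "config": cfg,
            "metrics": model.metrics,
            "cv_scores": model.cv_scores,
            "seed": model.seed,
            "encoding": model.encoding,
        },
        path,
    )
    report = {
        "header": {
            "k": cfg.k,
            "sketch_size": cfg.sketch_size,
            "num_bins": cfg.num_bins,
            "master_seed": cfg.master_seed,
        },
        "metrics": model.metrics,
        "cv_mean_accuracy": float(np.mean(model.cv_scores)),
        "cv_scores": [float(s) for s in model.cv_scores],
        "seed": model.seed,
        "encoding": model.encoding,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(report, fh, indent=2)


def load_model(path: str) -> TrainedModel:
    d = joblib.load(path)
    return TrainedModel(
        d["forest"], d["config"], d["metrics"], d["cv_scores"], d["seed"], d["encoding"]
    )
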