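"""Three-class object classification: PositiveCell / NegativeCell / NoCell.

Detections in high-ECM, low-cellularity tissue (disc, cartilage) include
artifacts — DAB debris, fold fragments — that rival true nuclei in number.
A supervised classifier over the morphometric + stain-OD features assigns
each detection one of three labels; "NoCell" detections are retained in
outputs but excluded from positivity rates.

Two classifier families share the predict surface:

* :class:`CellObjectClassifier` — a seeded random forest (sklearn-style
  estimator: ``fit`` / ``predict`` / ``get_params``), class-weighted
  against the typically scarce NoCell examples;
* :class:`ThresholdCellClassifier` — a one-feature cut on mean nucleus DAB
  OD, used as a deterministic baseline and for bootstrapping annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .detection import (
    FEATURE_NAMES,
    KNOWN_LABELS,
    LABEL_NEGATIVE,
    LABEL_NOCELL,
    LABEL_POSITIVE,
)
from .errors import (
    FeatureMismatchError,
    InsufficientTrainingError,
    InvalidParameterError,
)


@dataclass
class TrainingSet:
    """Labelled feature maps harvested from annotated detections."""

    examples: list = field(default_factory=list)  # (feature dict, label)
    provenance: list = field(default_factory=list)

    def add(self, features: dict, label: str, provenance: str = ""):
        if label not in KNOWN_LABELS:
            raise InvalidParameterError(f"unknown label {label!r}")
        self.examples.append((dict(features), label))
        self.provenance.append(provenance)

    def class_counts(self) -> dict:
        counts = {c: 0 for c in KNOWN_LABELS}
        for _, lab in self.examples:
            counts[lab] += 1
        return counts

    def validate(self):
        missing = [c for c, n in self.class_counts().items() if n == 0]
        if missing:
            raise InsufficientTrainingError(missing)


def _features_to_matrix(feature_maps, feature_names):
    rows = []
    for fm in feature_maps:
        missing = [f for f in feature_names if f not in fm]
        if missing:
            raise FeatureMismatchError(missing)
        rows.append([fm[f] for f in feature_names])
    return np.asarray(rows, dtype=float)


class CellObjectClassifier(BaseEstimator, ClassifierMixin):
    """Seeded random-forest classifier over detection features.

    Parameters
    ----------
    feature_names : sequence of str
        Ordered features consumed; frozen at fit time.
    n_estimators : int
        Trees in the forest.
    seed : int
        Random state; fixed seed + fixed inputs gives byte-identical
        serialized models and labels.
    """

    def __init__(self, feature_names=FEATURE_NAMES, n_estimators=200, seed=0):
        self.feature_names = tuple(feature_names)
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X, y):
        """Fit on feature maps (list of dicts) or an (n, p) array."""
        if len(X) and isinstance(X[0], dict):
            X = _features_to_matrix(X, self.feature_names)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        present = set(y.tolist())
        missing = [c for c in KNOWN_LABELS if c not in present]
        if missing:
            raise InsufficientTrainingError(missing)
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=self.seed,
            class_weight="balanced",
        )
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        self.feature_names_ = tuple(self.feature_names)
        acc = {}
        pred = self.model_.predict(X)
        for c in KNOWN_LABELS:
            sel = y == c
            acc[c] = float((pred[sel] == c).mean()) if sel.any() else float("nan")
        self.training_summary_ = {
            "per_class_counts": {c: int((y == c).sum()) for c in KNOWN_LABELS},
            "per_class_training_accuracy": acc,
            "training_accuracy": float((pred == y).mean()),
        }
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        if len(X) and isinstance(X[0], dict):
            X = _features_to_matrix(X, self.feature_names_)
        if len(X) == 0:
            return np.asarray([], dtype=object)
        return self.model_.predict(np.asarray(X, dtype=float))

    def save(self, path):
        """Serialize model to ``path`` with a JSON sidecar of metadata."""
        check_is_fitted(self, "model_")
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "kind": "trainable",
            "feature_names": list(self.feature_names_),
            "seed": self.seed,
            "training_summary": self.training_summary_,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )


class ThresholdCellClassifier(BaseEstimator, ClassifierMixin):
    """Baseline: PositiveCell iff mean nucleus DAB OD >= cut; never NoCell."""

    feature = "nucleus_dab_od_mean"

    def __init__(self, dab_mean_od_cut=0.2):
        if dab_mean_od_cut <= 0:
            raise InvalidParameterError("dab_mean_od_cut must be > 0")
        self.dab_mean_od_cut = dab_mean_od_cut
        self.feature_names_ = (self.feature,)

    def fit(self, X=None, y=None):  # stateless; present for API symmetry
        return self

    def predict(self, X):
        if len(X) and isinstance(X[0], dict):
            vals = []
            for fm in X:
                if self.feature not in fm:
                    raise FeatureMismatchError([self.feature])
                vals.append(fm[self.feature])
            vals = np.asarray(vals, dtype=float)
        else:
            vals = np.asarray(X, dtype=float).ravel()
        return np.where(vals >= self.dab_mean_od_cut, LABEL_POSITIVE, LABEL_NEGATIVE)

    def save(self, path):
        Path(path).write_text(
            json.dumps({"kind": "threshold", "dab_mean_od_cut": self.dab_mean_od_cut})
        )


def threshold_classifier(dab_mean_od_cut: float) -> ThresholdCellClassifier:
    return ThresholdCellClassifier(dab_mean_od_cut)


def train_classifier(train: TrainingSet, seed: int = 0) -> CellObjectClassifier:
    """Train the three-class forest; errors if any class is absent."""
    train.validate()
    X = [fm for fm, _ in train.examples]
    y = [lab for _, lab in train.examples]
    return CellObjectClassifier(seed=seed).fit(X, y)


def classify(objs, model):
    """Label every detection in place; NoCell objects are retained."""
    if not objs:
        return objs
    labels = model.predict([o.features for o in objs])
    for o, lab in zip(objs, labels):
        o.label = str(lab)
    return objs


def load_classifier(path):
    """Load a serialized classifier (threshold JSON or joblib forest)."""
    path = Path(path)
    head = path.read_bytes()[:1]
    if head == b"{":
        meta = json.loads(path.read_text())
        if meta.get("kind") == "threshold":
            return ThresholdCellClassifier(meta["dab_mean_od_cut"])
        raise InvalidParameterError(f"unknown classifier kind in {path}")
    return joblib.load(path)


def label_detections_from_points(objs, points_um, labels, max_distance_um=5.0):
    """Build a TrainingSet by matching annotation points to detections.

    Each annotation point adopts the nearest detection centroid within
    ``max_distance_um``; unmatched points are skipped (returned count).
    """
    ts = TrainingSet()
    skipped = 0
    if not objs:
        return ts, len(points_um)
    cents = np.asarray([o.centroid_um for o in objs], dtype=float)
    for (x, y), lab in zip(points_um, labels):
        d = np.hypot(cents[:, 0] - x, cents[:, 1] - y)
        i = int(np.argmin(d))
        if d[i] <= max_distance_um:
            ts.add(objs[i].features, lab, provenance=objs[i].object_id)
        else:
            skipped += 1
    return ts, skipped


__all__ = [
    "TrainingSet",
    "CellObjectClassifier",
    "ThresholdCellClassifier",
    "threshold_classifier",
    "train_classifier",
    "classify",
    "load_classifier",
    "label_detections_from_points",
    "LABEL_POSITIVE",
    "LABEL_NEGATIVE",
    "LABEL_NOCELL",
]
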