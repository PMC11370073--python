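"""Activity classification: 500-tree random forest over window features.

Five classes are predicted per 15-s window: sedentary (SED), light
activities and games (L_ACT_G), moderate-vigorous activities and games
(MV_ACT_G), walking (WALK) and running (RUN). Model evaluation uses
leave-one-subject-out (LOSO) cross-validation — every child's windows are
predicted by a forest trained on all other children, so the reported
metrics measure generalisation to unseen children rather than unseen
windows. Predicted classes map onto three intensity categories: SED →
sedentary, L_ACT_G → light physical activity (LPA), and the energetic-play
classes MV_ACT_G/WALK/RUN → MVPA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .signal import FEATURE_NAMES, WindowFeatures
from .synth import CLASS_LABELS, LabelledWindow

__all__ = [
    "ActivityModel",
    "ClassMetrics",
    "INTENSITY_MAP",
    "train",
    "predict",
    "loso_cv",
    "map_to_intensity",
]

#: Class → intensity category. MVPA iff the class is one of the three
#: energetic-play classes.
INTENSITY_MAP: dict[str, str] = {
    "SED": "SEDENTARY",
    "L_ACT_G": "LPA",
    "MV_ACT_G": "MVPA",
    "WALK": "MVPA",
    "RUN": "MVPA",
}

# Fixed class order for deterministic vote tie-breaking.
_CLASS_TO_CODE = {label: i for i, label in enumerate(CLASS_LABELS)}


@dataclass
class ActivityModel:
    """A fitted activity classifier with its feature-name contract."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    class_labels: tuple[str, ...]
    seed: int
    n_trees: int

    def to_metadata(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "class_labels": list(self.class_labels),
            "seed": self.seed,
            "n_trees": self.n_trees,
        }


@dataclass
class ClassMetrics:
    """Pooled LOSO classification metrics.

    ``recall`` per class is the recognition accuracy (diagonal over row sum
    of the confusion matrix); ``macro_f1`` is the unweighted mean of the
    per-class F-scores.
    """

    labels: tuple[str, ...]
    confusion: np.ndarray = field(repr=False)
    recall: dict[str, float] = field(default_factory=dict)
    precision: dict[str, float] = field(default_factory=dict)
    f1: dict[str, float] = field(default_factory=dict)
    macro_f1: float = 0.0

    @classmethod
    def from_confusion(cls, confusion: np.ndarray, labels: tuple[str, ...]) -> "ClassMetrics":
        confusion = np.asarray(confusion, dtype=int)
        recall, precision, f1 = {}, {}, {}
        for i, lab in enumerate(labels):
            row = confusion[i].sum()
            col = confusion[:, i].sum()
            r = confusion[i, i] / row if row else 0.0
            p = confusion[i, i] / col if col else 0.0
            recall[lab], precision[lab] = float(r), float(p)
            f1[lab] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
        macro = float(np.mean([f1[lab] for lab in labels]))
        return cls(labels=labels, confusion=confusion, recall=recall,
                   precision=precision, f1=f1, macro_f1=macro)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion_matrix": self.confusion.tolist(),
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "macro_f1": self.macro_f1,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _design_matrix(windows: list[WindowFeatures]) -> np.ndarray:
    return np.vstack([w.features for w in windows]) if windows else np.empty((0, len(FEATURE_NAMES)))


def train(
    corpus: list[LabelledWindow],
    n_trees: int = 500,
    seed: int = 0,
) -> ActivityModel:
    """Fit the random forest on a labelled corpus.

    Hyperparameters beyond tree count follow common defaults: sqrt(25) = 5
    features per split, unlimited depth, no class weighting. Training is
    deterministic for a given seed. Raises on a single-class corpus.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    labels = {w.label for w in corpus}
    if len(labels) < 2:
        raise ValueError("corpus must contain at least 2 classes")
    X = _design_matrix([w.features for w in corpus])
    # class labels as fixed-order integer codes so vote ties break
    # deterministically in the order SED < L_ACT_G < MV_ACT_G < WALK < RUN
    y = np.array([_CLASS_TO_CODE[w.label] for w in corpus])
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return ActivityModel(
        forest=forest,
        feature_names=FEATURE_NAMES,
        class_labels=CLASS_LABELS,
        seed=seed,
        n_trees=n_trees,
    )


def predict(model: ActivityModel, windows: list[WindowFeatures]) -> list[str]:
    """Predict one class label per window.

    Inputs must honour the model's feature-name contract; ``WindowFeatures``
    built by this package always do, while raw arrays are rejected.
    """
    for w in windows:
        if not isinstance(w, WindowFeatures):
            raise ValueError("predict expects WindowFeatures instances")
    if model.feature_names != FEATURE_NAMES:
        raise ValueError("model feature contract does not match this package's feature set")
    if not windows:
        return []
    codes = model.forest.predict(_design_matrix(windows))
    return [model.class_labels[int(c)] for c in codes]


def loso_cv(
    corpus: list[LabelledWindow],
    n_trees: int = 500,
    seed: int = 0,
) -> ClassMetrics:
    """Leave-one-subject-out cross-validation with pooled metrics.

    For each subject the forest is retrained on all other subjects and the
    held-out subject's windows are predicted; predictions are pooled into a
    single confusion matrix, so its total equals the corpus size.
    """
    subjects = sorted({w.subject_id for w in corpus})
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    confusion = np.zeros((len(CLASS_LABELS), len(CLASS_LABELS)), dtype=int)
    for held_out in subjects:
        train_set = [w for w in corpus if w.subject_id != held_out]
        test_set = [w for w in corpus if w.subject_id == held_out]
        model = train(train_set, n_trees=n_trees, seed=seed)
        preds = predict(model, [w.features for w in test_set])
        for w, p in zip(test_set, preds):
            confusion[_CLASS_TO_CODE[w.label], _CLASS_TO_CODE[p]] += 1
    return ClassMetrics.from_confusion(confusion, CLASS_LABELS)


def map_to_intensity(label: str) -> str:
    """Map an activity class to its intensity category.

    SED → SEDENTARY; L_ACT_G → LPA; MV_ACT_G, WALK, RUN → MVPA.
    """
    try:
        return INTENSITY_MAP[label]
    except KeyError:
        raise ValueError(f"unknown activity class {label!r}") from None


def predictions_frame(
    windows: list[WindowFeatures], labels: list[str]
) -> pd.DataFrame:
    """Per-window prediction table: subject, window start, class, intensity."""
    return pd.DataFrame(
        {
            "subject_id": [w.subject_id for w in windows],
            "window_start": [w.window_start for w in windows],
            "predicted_class": labels,
            "intensity": [map_to_intensity(l) for l in labels],
            "vm_sd": [w.vm_sd for w in windows],
        }
    )
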