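"""Seed/background pixel classification on six color features.

Each pixel is described by its RGB values and their hexcone HSV transform,
all normalised to [0, 1]. Four supervised models are trained and compared —
k-nearest neighbours, an RBF support-vector machine, a random forest, and
gradient-boosted trees — and the best one (highest F1 on the held-out split,
ties broken by accuracy then fixed model order) produces the raw seed mask
that the adherent splitter refines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .containers import PixelSampleTable
from .errors import DegenerateInputError

#: Fixed model ordering; also the last-resort selection tie-break.
MODEL_ORDER = ("knn", "svm", "random_forest", "xgboost")


def extract_features(
    img: np.ndarray, sample_mask: np.ndarray | None = None
) -> PixelSampleTable:
    """Unlabeled six-feature table, one row per (sampled) pixel.

    Rows follow row-major pixel order (restricted to ``sample_mask`` pixels
    when given). R, G, B are scaled to [0, 1]; H, S, V come from the standard
    hexcone transform with H as a fraction of the hue circle.
    """
    rgb = img.astype(np.float64) / 255.0
    hsv = color.rgb2hsv(rgb)
    feats = np.concatenate([rgb, hsv], axis=-1).reshape(-1, 6)
    if sample_mask is not None:
        feats = feats[np.asarray(sample_mask, bool).ravel()]
    return PixelSampleTable(feats, None)


def split_dataset(
    table: PixelSampleTable, ratio: float = 0.8, rng_seed: int = 0
) -> tuple[PixelSampleTable, PixelSampleTable]:
    """Random disjoint split with ``n_train = floor(ratio * n)``."""
    if table.labels is None:
        raise DegenerateInputError("split_dataset requires a labeled table")
    n = len(table)
    if n < 2:
        raise DegenerateInputError("need at least 2 rows to split")
    if table.labels.all() or not table.labels.any():
        raise DegenerateInputError("both classes must be present")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(ratio * n))
    tr, te = perm[:n_train], perm[n_train:]
    return (
        PixelSampleTable(table.features[tr], table.labels[tr]),
        PixelSampleTable(table.features[te], table.labels[te]),
    )


def train_models(train: PixelSampleTable, rng_seed: int = 0) -> dict[str, object]:
    """Fit the four classifiers; distance/kernel models get z-scored features."""
    if train.labels is None or train.labels.all() or not train.labels.any():
        raise DegenerateInputError("training table must contain both classes")
    if np.ptp(train.features, axis=0).max() == 0:
        raise DegenerateInputError("all features are constant")
    X, y = train.features, train.labels.astype(int)
    models: dict[str, object] = {
        "knn": Pipeline([
            ("scale", StandardScaler()),
            ("model", KNeighborsClassifier(n_neighbors=5)),
        ]),
        "svm": Pipeline([
            ("scale", StandardScaler()),
            ("model", SVC(C=1.0, kernel="rbf", gamma="scale")),
        ]),
        "random_forest": RandomForestClassifier(
            n_estimators=100, random_state=rng_seed, n_jobs=1
        ),
        "xgboost": XGBClassifier(
            n_estimators=100, random_state=rng_seed, n_jobs=1,
            tree_method="hist", eval_metric="logloss", verbosity=0,
        ),
    }
    for m in models.values():
        m.fit(X, y)
    return models


@dataclass(frozen=True)
class ModelMetrics:
    """Positive-class (seed) confusion matrix and the derived scores."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()   # metrics reported as 0 by convention

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "ModelMetrics":
        n = tp + fp + fn + tn
        undefined: list[str] = []
        accuracy = (tp + tn) / n if n else 0.0
        precision = recall = f1 = 0.0
        if tp + fp:
            precision = tp / (tp + fp)
        else:
            undefined.append("precision")
        if tp + fn:
            recall = tp / (tp + fn)
        else:
            undefined.append("recall")
        if precision + recall:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            undefined.append("f1")
        return cls(tp, fp, fn, tn, accuracy, precision, recall, f1,
                   tuple(undefined))


@dataclass
class ClassifierReport:
    """Per-model metrics plus the selected model."""

    per_model: dict[str, ModelMetrics]
    selected_model: str
    n_train: int | None = None
    n_test: int | None = None
    rng_seed: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "selected_model": self.selected_model,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "rng_seed": self.rng_seed,
            "per_model": {
                name: {
                    "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
                    "accuracy": m.accuracy, "precision": m.precision,
                    "recall": m.recall, "f1": m.f1,
                    "undefined": list(m.undefined),
                }
                for name, m in self.per_model.items()
            },
        }


def evaluate_and_select(
    models: dict[str, object],
    test: PixelSampleTable,
    n_train: int | None = None,
    rng_seed: int | None = None,
) -> ClassifierReport:
    """Score every model on the test split and pick the best by F1.

    Ties break by accuracy, then by position in :data:`MODEL_ORDER`.
    """
    if len(test) == 0 or test.labels is None:
        raise DegenerateInputError("test split must be non-empty and labeled")
    y = test.labels
    per_model: dict[str, ModelMetrics] = {}
    for name in MODEL_ORDER:
        if name not in models:
            continue
        pred = np.asarray(models[name].predict(test.features)).astype(bool)
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = int(np.sum(~pred & y))
        tn = int(np.sum(~pred & ~y))
        per_model[name] = ModelMetrics.from_counts(tp, fp, fn, tn)
    ranked = sorted(
        per_model,
        key=lambda n: (-per_model[n].f1, -per_model[n].accuracy,
                       MODEL_ORDER.index(n)),
    )
    return ClassifierReport(per_model, ranked[0], n_train, len(test), rng_seed)


def predict_seed_mask(
    model: object,
    img: np.ndarray,
    restrict_to: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel classification into a boolean seed mask.

    With ``restrict_to`` given (e.g. the accession mask), pixels outside it
    are background by definition and are not classified.
    """
    h, w = img.shape[:2]
    out = np.zeros((h, w), bool)
    if restrict_to is not None:
        restrict_to = np.asarray(restrict_to, bool)
        if not restrict_to.any():
            return out
    table = extract_features(img, restrict_to)
    pred = np.asarray(model.predict(table.features)).astype(bool)
    if restrict_to is None:
        out = pred.reshape(h, w)
    else:
        out[restrict_to] = pred
    return out
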