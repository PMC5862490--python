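"""Metabolic-class prediction from the 3-feature space (g, s, delta_I).

Each measurement contributes one row: the pixel-averaged phasor coordinates
at a chosen harmonic plus the relative intensity change from baseline. Three
classifier families are supported — linear discriminant analysis (shared
pooled covariance, empirical priors), k-nearest neighbors (z-scored
features, default k=3, ties broken toward the lexicographically smallest
class), and Gaussian naive Bayes (per-class independent feature Gaussians
with a variance floor). Model quality is summarized by stratified K-fold
cross-validation error; a trained model can then label held-out measurements
(e.g. seizure-like acquisitions) and report the fraction assigned to each
class.

Glycolysis-inhibition and baseline measurements are excluded from training by
the default class map: only conditions separable from baseline carry class
information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .flim_data import MeasurementPoint

__all__ = [
    "FeatureTable",
    "ClassifierModel",
    "DEFAULT_CLASS_MAP",
    "ALGORITHMS",
    "build_feature_table",
    "train",
    "kfold_cv_error",
    "predict",
]

FEATURES = ("g", "s", "delta_I")
ALGORITHMS = ("lda", "knn", "nb")

DEFAULT_CLASS_MAP: dict[str, str | None] = {
    "tca_inhibition": "TCA",
    "etc_inhibition": "ETC",
    "oxphos_uncoupling": "OXPHOS",
    # excluded from training: baseline itself, the non-separable glycolysis
    # group, and the held-out seizure-like test condition
    "baseline": None,
    "glycolysis_inhibition": None,
    "seizure_like": None,
}


@dataclass
class FeatureTable:
    """Feature rows (g, s, delta_I, class_label) at one stated harmonic."""

    frame: pd.DataFrame
    harmonic: int

    def __post_init__(self) -> None:
        missing = [c for c in (*FEATURES, "class_label") if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        if self.frame[list(FEATURES)].isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["class_label"].to_numpy(dtype=object)

    @property
    def n_classes(self) -> int:
        return self.frame["class_label"].nunique()


def build_feature_table(
    measurements: list[MeasurementPoint],
    harmonic: int = 1,
    class_map: dict[str, str | None] | None = None,
) -> FeatureTable:
    """One row per mapped measurement; conditions mapped to None are dropped.

    Raises on an empty measurement list or a condition absent from the map.
    """
    if not measurements:
        raise ValueError("no measurements given")
    cmap = DEFAULT_CLASS_MAP if class_map is None else class_map
    rows = []
    for m in measurements:
        if m.condition not in cmap:
            raise ValueError(f"condition {m.condition!r} not in the class map")
        label = cmap[m.condition]
        if label is None:
            continue
        g, s, dI = m.features(harmonic)
        rows.append(
            {
                "condition": m.condition,
                "animal_id": m.animal_id,
                "location_id": m.location_id,
                "g": g,
                "s": s,
                "delta_I": dI,
                "class_label": label,
            }
        )
    if not rows:
        raise ValueError("class map excluded every measurement")
    return FeatureTable(pd.DataFrame(rows), int(harmonic))


def _make_estimator(algo: str, hyper: dict | None):
    hyper = dict(hyper or {})
    if algo == "lda":
        return LinearDiscriminantAnalysis(**hyper)
    if algo == "knn":
        k = hyper.pop("n_neighbors", 3)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("knn", KNeighborsClassifier(n_neighbors=k, **hyper)),
            ]
        )
    if algo == "nb":
        # absolute variance floor ~1e-12 relative to the largest feature
        # variance, guarding degenerate synthetic inputs
        hyper.setdefault("var_smoothing", 1e-12)
        return GaussianNB(**hyper)
    raise ValueError(f"unknown algorithm {algo!r}; choose from {ALGORITHMS}")


@dataclass
class ClassifierModel:
    algo: str
    estimator: object
    classes: tuple[str, ...]
    harmonic: int
    hyper: dict = field(default_factory=dict)


def train(table: FeatureTable, algo: str = "lda", hyper: dict | None = None) -> ClassifierModel:
    """Fit one classifier on the full feature table."""
    if table.n_classes < 2:
        raise ValueError("training requires at least 2 classes")
    est = _make_estimator(algo, hyper)
    est.fit(table.X, table.y)
    classes = est.classes_ if hasattr(est, "classes_") else est[-1].classes_
    return ClassifierModel(
        algo=algo,
        estimator=est,
        classes=tuple(str(c) for c in classes),
        harmonic=table.harmonic,
        hyper=dict(hyper or {}),
    )


def kfold_cv_error(
    table: FeatureTable,
    algo: str = "lda",
    hyper: dict | None = None,
    K: int = 5,
    seed: int = 0,
) -> float:
    """Stratified K-fold cross-validation misclassification fraction.

    Fold assignment is stratified by class and seeded; ``K == n`` switches to
    the (seed-free) leave-one-out loop. ``1 - error`` is the CV accuracy.
    """
    X, y = table.X, table.y
    n = len(y)
    if table.n_classes < 2:
        raise ValueError("cross-validation requires at least 2 classes")
    if not 2 <= K <= n:
        raise ValueError(f"K must be between 2 and n={n}, got {K}")
    if K == n:
        splitter = LeaveOneOut()
    else:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < K:
            raise ValueError(
                f"K={K} exceeds the smallest class size {counts.min()}; "
                "folds would lose a class"
            )
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    n_wrong = 0
    for train_idx, test_idx in splitter.split(X, y):
        est = _make_estimator(algo, hyper)
        est.fit(X[train_idx], y[train_idx])
        n_wrong += int(np.sum(est.predict(X[test_idx]) != y[test_idx]))
    return n_wrong / n


def predict(
    model: ClassifierModel,
    test: list[MeasurementPoint] | FeatureTable | np.ndarray,
    harmonic: int | None = None,
) -> tuple[list[str], dict[str, float]]:
    """Label held-out measurements; also report per-class assignment fractions.

    The fraction dictionary is the share of test measurements assigned to
    each trained class (the style of a held-out prediction summary).
    """
    if isinstance(test, FeatureTable):
        X = test.X
    elif isinstance(test, np.ndarray):
        X = np.atleast_2d(np.asarray(test, dtype=float))
    else:
        if not test:
            raise ValueError("empty test set")
        k = model.harmonic if harmonic is None else harmonic
        X = np.array([m.features(k) for m in test], dtype=float)
    labels = [str(lbl) for lbl in model.estimator.predict(X)]
    fractions = {c: labels.count(c) / len(labels) for c in model.classes}
    return labels, fractions
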