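"""Statistical-feature extraction and the four-classifier CV harness.

Five descriptive features characterize each selected (sensor, signal)
combination of a processed step: the segment *width* (duration in
samples, counted once per step), and per signal its *height*
(max - min), *mean*, *standard deviation*, and *power* (mean of squared
values, including the DC offset).  Feature dimensionality therefore
follows 4 * |sensors| * |signals| + 1, yielding 5 / 9 / 17 for the nine
sensor-signal configurations.

Classifiers: Gaussian Naive Bayes, an entropy-criterion decision tree
(C4.5-style), an RBF-kernel SVM, and k-nearest neighbours — all behind a
fold-local z-scoring pipeline.  Evaluation uses stratified five-fold
cross-validation, aggregating predictions over all five test folds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.model_selection import StratifiedKFold

from stepgait.augmentation import AugmentationConfig, Treatment, apply_treatment
from stepgait.evaluation import EvaluationReport, classification_report
from stepgait.preprocessing import (
    DEFAULT_CUTOFF_HZ,
    DEFAULT_SMOOTH_WIDTH,
    ProcessedStep,
    preprocess_step,
)
from stepgait.signal_model import StepDataset, class_histogram


class Sensor(enum.Enum):
    ACC = "acc"
    GYR = "gyr"


class Signal(enum.Enum):
    FD = "fd"
    XYZ = "xyz"


class Algorithm(enum.Enum):
    NAIVE_BAYES = "nb"
    DECISION_TREE = "c45"
    SVM = "svm"
    KNN = "knn"


@dataclass(frozen=True)
class FeatureConfig:
    """Which sensors and derived signals feed the feature vector."""

    sensors: tuple[Sensor, ...] = (Sensor.ACC, Sensor.GYR)
    signals: tuple[Signal, ...] = (Signal.FD, Signal.XYZ)

    def __post_init__(self) -> None:
        if not self.sensors or not self.signals:
            raise ValueError("need at least one sensor and one signal")

    @property
    def dimensionality(self) -> int:
        return 4 * len(self.sensors) * len(self.signals) + 1

    def feature_names(self) -> list[str]:
        names = ["width"]
        for sensor in self.sensors:
            for signal in self.signals:
                prefix = f"{sensor.value}_{signal.value}"
                names += [f"{prefix}_height", f"{prefix}_mean", f"{prefix}_sd", f"{prefix}_power"]
        return names


_SERIES_ATTR = {
    (Sensor.ACC, Signal.FD): "acc_fd",
    (Sensor.ACC, Signal.XYZ): "acc_xyz",
    (Sensor.GYR, Signal.FD): "gyr_fd",
    (Sensor.GYR, Signal.XYZ): "gyr_xyz",
}


def extract_features(step: ProcessedStep, config: FeatureConfig | None = None) -> np.ndarray:
    """Feature vector of one processed step; width is counted once."""
    config = config or FeatureConfig()
    values = [float(len(step))]
    for sensor in config.sensors:
        for signal in config.signals:
            series = getattr(step, _SERIES_ATTR[(sensor, signal)])
            values += [
                float(series.max() - series.min()),
                float(series.mean()),
                float(series.std()),
                float(np.mean(series**2)),
            ]
    return np.asarray(values)


def extract_feature_matrix(
    dataset: StepDataset,
    config: FeatureConfig | None = None,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess every segment and stack feature vectors; returns (X, y)."""
    config = config or FeatureConfig()
    rows = []
    labels = []
    for seg in dataset:
        step = preprocess_step(seg, cutoff=cutoff, smooth_width=smooth_width)
        rows.append(extract_features(step, config))
        labels.append(int(seg.label))
    return np.asarray(rows), np.asarray(labels, dtype=int)


def make_classifier(algorithm: Algorithm, hyperparams: dict | None = None, seed: int = 0):
    """A fresh classifier pipeline with fold-local z-scoring."""
    hp = dict(hyperparams or {})
    if algorithm is Algorithm.NAIVE_BAYES:
        model = GaussianNB(**hp)
    elif algorithm is Algorithm.DECISION_TREE:
        model = DecisionTreeClassifier(criterion="entropy", random_state=seed, **hp)
    elif algorithm is Algorithm.SVM:
        hp.setdefault("C", 1.0)
        hp.setdefault("gamma", "scale")
        model = SVC(kernel="rbf", random_state=seed, **hp)
    elif algorithm is Algorithm.KNN:
        hp.setdefault("n_neighbors", 5)
        model = KNeighborsClassifier(**hp)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown algorithm {algorithm}")
    return Pipeline([("scale", StandardScaler()), ("clf", model)])


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    algorithm: Algorithm,
    hyperparams: dict | None = None,
    seed: int = 0,
):
    """Fit one classifier on a feature matrix; needs at least two classes."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain at least two classes")
    if not np.isfinite(features).all():
        raise ValueError("features contain missing or non-finite values")
    model = make_classifier(algorithm, hyperparams, seed)
    model.fit(features, labels)
    return model


def run_cross_validation(
    dataset: StepDataset,
    treatment: Treatment,
    config: FeatureConfig | None = None,
    algorithm: Algorithm = Algorithm.SVM,
    seed: int = 0,
    augmentation: AugmentationConfig | None = None,
    hyperparams: dict | None = None,
    n_folds: int = 5,
    split_before_augment: bool = False,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of one (treatment, algorithm) cell.

    By default the treatment is applied to the whole dataset *before*
    splitting.  ``split_before_augment=True`` instead applies the treatment
    to each training partition only, which removes any synthetic/source
    leakage across folds at the cost of deviating from the
    treat-then-split protocol.
    """
    config = config or FeatureConfig()
    rng = np.random.default_rng(seed)

    def check_counts(d: StepDataset) -> None:
        for activity, count in class_histogram(d).items():
            if 0 < count < n_folds:
                raise ValueError(
                    f"class {activity.name} has only {count} instances (< {n_folds})"
                )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    if split_before_augment:
        check_counts(dataset)
        X_raw, y_raw = extract_feature_matrix(dataset, config)
        y_true_all, y_pred_all = [], []
        for train_idx, test_idx in skf.split(X_raw, y_raw):
            train_ds = StepDataset([dataset.segments[i] for i in train_idx])
            treated = apply_treatment(train_ds, treatment, rng, augmentation)
            X_tr, y_tr = extract_feature_matrix(treated, config)
            model = train_classifier(X_tr, y_tr, algorithm, hyperparams, seed)
            y_pred_all.append(model.predict(X_raw[test_idx]))
            y_true_all.append(y_raw[test_idx])
    else:
        treated = apply_treatment(dataset, treatment, rng, augmentation)
        check_counts(treated)
        X, y = extract_feature_matrix(treated, config)
        y_true_all, y_pred_all = [], []
        for train_idx, test_idx in skf.split(X, y):
            model = train_classifier(X[train_idx], y[train_idx], algorithm, hyperparams, seed)
            y_pred_all.append(model.predict(X[test_idx]))
            y_true_all.append(y[test_idx])

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    return classification_report(
        y_true,
        y_pred,
        metadata={
            "approach": "shallow",
            "treatment": treatment.value,
            "algorithm": algorithm.value,
            "sensors": [s.value for s in config.sensors],
            "signals": [s.value for s in config.signals],
            "seed": seed,
            "split_before_augment": split_before_augment,
        },
    )
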