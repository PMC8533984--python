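"""Cell line and cell state classification on feature tables.

Three classifier families are supported, mirroring common practice for
feature-based cell classification:

* SVM with linear / quadratic / cubic (inhomogeneous polynomial) / Gaussian
  kernels, one-vs-one multi-class;
* k-nearest neighbours with cosine or cubic (Minkowski p=3) metric and
  uniform or distance weighting;
* ensembles of decision trees (random forest or AdaBoost).

Samples travel as pandas DataFrames with named feature columns plus
``line_label`` / ``state_label`` columns.  Features are z-scored on training
statistics inside the fitted pipeline.  Tasks: ``lines`` (3-class),
``states`` (3-class within a line), ``nine_class`` (joint line x state).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.feature_selection import VarianceThreshold
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import OpticalConstants, PhaseImage
from .features import FEATURE_NAMES, dry_mass, qpi_features

logger = logging.getLogger(__name__)

TASKS = ("lines", "states", "nine_class")

#: Default predictor set: the 10 QPI features with dry mass standing in for
#: the phase volume it is proportional to (identical after z-scoring).
DEFAULT_QPI_PREDICTORS = tuple(FEATURE_NAMES)


@dataclass
class ClassifierSpec:
    family: str = "svm"                 # svm | knn | ec
    svm_kernel: str = "quadratic"       # linear | quadratic | cubic | gaussian
    svm_c: float = 1.0
    knn_metric: str = "cosine"          # cosine | cubic
    knn_weighting: str = "distance"     # uniform | distance
    knn_k: int = 7
    ec_method: str = "random_forest"    # random_forest | adaboost
    n_estimators: int = 200
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("svm", "knn", "ec"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.svm_kernel not in ("linear", "quadratic", "cubic", "gaussian"):
            raise ValueError(f"unknown SVM kernel {self.svm_kernel!r}")
        if self.knn_metric not in ("cosine", "cubic"):
            raise ValueError(f"unknown k-NN metric {self.knn_metric!r}")
        if self.knn_weighting not in ("uniform", "distance"):
            raise ValueError(f"unknown k-NN weighting {self.knn_weighting!r}")
        if self.ec_method not in ("random_forest", "adaboost"):
            raise ValueError(f"unknown ensemble method {self.ec_method!r}")


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    task: str
    feature_names: tuple[str, ...]
    pipeline: Pipeline
    classes: tuple[str, ...]
    n_per_class: dict[str, int]

    def predict(self, samples: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(samples, self.feature_names)
        return self.pipeline.predict(X)


@dataclass
class EvaluationReport:
    task: str
    accuracy_pct: float
    confusion: pd.DataFrame            # rows: true class, cols: predicted
    per_class_recall: dict[str, float]
    n_test: int
    spec: Optional[ClassifierSpec] = None


@dataclass
class TimeSeriesFractions:
    """Per-timepoint counts and fractions of live/apoptotic/necrotic cells."""

    table: pd.DataFrame   # time_min, n_cells, frac_live, frac_apoptotic, frac_necrotic
    dose_mw_cm2: Optional[float] = None


# ---------------------------------------------------------------------------
# Targets and design matrices
# ---------------------------------------------------------------------------

def task_labels(samples: pd.DataFrame, task: str) -> pd.Series:
    if task == "lines":
        return samples["line_label"]
    if task == "states":
        return samples["state_label"]
    if task == "nine_class":
        return samples["line_label"] + "/" + samples["state_label"]
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def _design_matrix(samples: pd.DataFrame, feature_names: Sequence[str]) -> np.ndarray:
    missing = [f for f in feature_names if f not in samples.columns]
    if missing:
        raise ValueError(f"samples are missing feature columns {missing}")
    X = samples[list(feature_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


# ---------------------------------------------------------------------------
# Split / train / evaluate
# ---------------------------------------------------------------------------

def split_train_test(
    samples: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split on the joint (line, state) label."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    joint = samples["line_label"].astype(str) + "/" + samples["state_label"].astype(str)
    counts = joint.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 samples cannot be split: {bad}")
    train, test = train_test_split(
        samples,
        test_size=test_fraction,
        random_state=seed,
        stratify=joint,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def build_estimator(spec: ClassifierSpec) -> Pipeline:
    if spec.family == "svm":
        kernel_map = {
            "linear": dict(kernel="linear"),
            "quadratic": dict(kernel="poly", degree=2, coef0=1.0, gamma="scale"),
            "cubic": dict(kernel="poly", degree=3, coef0=1.0, gamma="scale"),
            "gaussian": dict(kernel="rbf", gamma="scale"),
        }
        est = SVC(C=spec.svm_c, random_state=spec.seed, **kernel_map[spec.svm_kernel])
    elif spec.family == "knn":
        metric = (
            dict(metric="cosine")
            if spec.knn_metric == "cosine"
            else dict(metric="minkowski", p=3)
        )
        est = KNeighborsClassifier(
            n_neighbors=spec.knn_k, weights=spec.knn_weighting, **metric
        )
    else:
        if spec.ec_method == "random_forest":
            est = RandomForestClassifier(
                n_estimators=spec.n_estimators, random_state=spec.seed
            )
        else:
            est = AdaBoostClassifier(
                n_estimators=spec.n_estimators, random_state=spec.seed
            )
    steps = [("drop_constant", VarianceThreshold(threshold=0.0))]
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", est))
    return Pipeline(steps)


def train_classifier(
    train: pd.DataFrame,
    spec: ClassifierSpec,
    task: str = "nine_class",
    feature_names: Sequence[str] = DEFAULT_QPI_PREDICTORS,
) -> TrainedClassifier:
    """Fit a classifier of the requested family on a training table."""
    if len(train) == 0:
        raise ValueError("empty training set")
    y = task_labels(train, task)
    X = _design_matrix(train, feature_names)

    constant = [f for f, v in zip(feature_names, X.var(axis=0)) if v == 0.0]
    if constant:
        logger.warning("dropping zero-variance features: %s", constant)

    pipeline = build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipeline.fit(X, y.to_numpy())
    classes = tuple(pipeline.named_steps["clf"].classes_)
    return TrainedClassifier(
        spec=spec,
        task=task,
        feature_names=tuple(feature_names),
        pipeline=pipeline,
        classes=classes,
        n_per_class=y.value_counts().to_dict(),
    )


def evaluate(model: TrainedClassifier, test: pd.DataFrame) -> EvaluationReport:
    """Accuracy, confusion matrix and per-class recall on a test table."""
    y_true = task_labels(test, model.task).to_numpy()
    y_pred = model.predict(test)
    classes = list(model.classes)
    cm = sk_confusion_matrix(y_true, y_pred, labels=classes)
    accuracy = 100.0 * np.trace(cm) / max(cm.sum(), 1)
    recall = {}
    for i, cls in enumerate(classes):
        row = cm[i].sum()
        recall[cls] = float(cm[i, i] / row) if row else float("nan")
    return EvaluationReport(
        task=model.task,
        accuracy_pct=float(accuracy),
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        per_class_recall=recall,
        n_test=len(test),
        spec=model.spec,
    )


# ---------------------------------------------------------------------------
# Feature-importance progression
# ---------------------------------------------------------------------------

def feature_subset_analysis(
    samples: pd.DataFrame,
    spec: ClassifierSpec,
    ranking: Optional[Sequence[str]] = None,
    task: str = "lines",
    test_fraction: float = 0.2,
    seed: int = 0,
    feature_names: Sequence[str] = DEFAULT_QPI_PREDICTORS,
) -> pd.DataFrame:
    """Accuracy on nested prefixes of a feature ranking (fixed split).

    If ``ranking`` is None, a greedy-forward ranking is computed first: at
    each step the feature whose addition maximises test accuracy is appended.
    Returns a DataFrame with columns ``n_features``, ``features``,
    ``accuracy_pct``.
    """
    if ranking is not None and len(ranking) == 0:
        raise ValueError("ranking must not be empty")
    train, test = split_train_test(samples, test_fraction=test_fraction, seed=seed)

    def _accuracy(subset: Sequence[str]) -> float:
        model = train_classifier(train, spec, task=task, feature_names=subset)
        return evaluate(model, test).accuracy_pct

    if ranking is None:
        remaining = list(feature_names)
        ranking = []
        while remaining:
            scores = [(_accuracy(list(ranking) + [f]), f) for f in remaining]
            best = max(scores, key=lambda t: t[0])[1]
            ranking.append(best)
            remaining.remove(best)
    else:
        unknown = [f for f in ranking if f not in samples.columns]
        if unknown:
            raise ValueError(f"ranking contains unknown features {unknown}")

    rows = []
    for k in range(1, len(ranking) + 1):
        subset = list(ranking)[:k]
        rows.append(
            dict(
                n_features=k,
                features=",".join(subset),
                accuracy_pct=_accuracy(subset),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time-series fraction dynamics
# ---------------------------------------------------------------------------

def classify_time_series(
    frames: Sequence[tuple[float, PhaseImage]],
    model: TrainedClassifier,
    segment_config=None,
    constants: Optional[OpticalConstants] = None,
    dose_mw_cm2: Optional[float] = None,
) -> TimeSeriesFractions:
    """Segment, featurise and classify every frame of a monitoring series.

    The model must be trained on the ``states`` task with QPI features.
    Timepoints with zero segmented cells get NaN fractions (marked missing).
    """
    from .segmentation import segment_cells

    if model.task != "states":
        raise ValueError("time-series classification requires a 'states' model")
    if constants is None:
        constants = OpticalConstants()

    states = ("live", "apoptotic", "necrotic")
    rows = []
    for time_min, phase in frames:
        seg = segment_cells(phase, segment_config)
        feats = []
        for cell in seg.cells:
            if cell.contains_invalid_phase:
                continue
            mask = seg.mask_for(cell.label)
            try:
                f = qpi_features(phase, mask, constants)
            except ValueError:
                continue
            row = f.as_dict()
            row["dm_pg"] = dry_mass(phase, mask, constants)
            feats.append(row)
        row = dict(time_min=time_min, n_cells=len(feats))
        if not feats:
            for s in states:
                row[f"frac_{s}"] = float("nan")
        else:
            table = pd.DataFrame(feats)
            pred = model.pipeline.predict(
                _design_matrix(table, model.feature_names)
            )
            counts = pd.Series(pred).value_counts()
            for s in states:
                row[f"frac_{s}"] = float(counts.get(s, 0)) / len(feats)
        rows.append(row)
    return TimeSeriesFractions(table=pd.DataFrame(rows), dose_mw_cm2=dose_mw_cm2)


def label_permutation_accuracy(
    samples: pd.DataFrame,
    spec: ClassifierSpec,
    task: str = "lines",
    n_permutations: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    feature_names: Sequence[str] = DEFAULT_QPI_PREDICTORS,
) -> np.ndarray:
    """Test accuracies under random label permutation (chance-level null)."""
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_permutations):
        shuffled = samples.copy()
        perm = rng.permutation(len(shuffled))
        shuffled["line_label"] = shuffled["line_label"].to_numpy()[perm]
        shuffled["state_label"] = shuffled["state_label"].to_numpy()[perm]
        train, test = split_train_test(
            shuffled, test_fraction=test_fraction, seed=int(rng.integers(0, 2**31 - 1))
        )
        model = train_classifier(train, spec, task=task, feature_names=feature_names)
        accs.append(evaluate(model, test).accuracy_pct)
    return np.asarray(accs)
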