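"""Supervised pairwise classification of cranium-atlas correspondence.

The pairwise dataset is severely skewed: for n individuals there are n
correspondent pairs hidden among n^2 candidates, so non-correspondents
outnumber correspondents by a factor of n.  Accuracy is therefore
meaningless and the evaluation centres on the positive predictive value
(PPV) alongside sensitivity, specificity and ROC AUC, all pooled over the
out-of-fold predictions of a stratified k-fold cross-validation.

Six classifier families are covered: linear discriminant analysis,
logistic regression, quadratic discriminant analysis, a Gaussian-kernel
SVM, boosted trees (50 learners) and a single-hidden-layer feed-forward
network (50 tanh units with early stopping on an internal validation
split).  A fraction-valued metric is ``None`` ("n.a.") when its
denominator is empty — notably the PPV when a model never predicts a
single positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .osteometry import FEATURE_NAMES, MEASUREMENT_PAIRINGS, MeasurementSet

__all__ = [
    "CLASSIFIER_FAMILIES",
    "ClassifierSpec",
    "ClassificationMetrics",
    "compute_ppv",
    "cross_validate",
    "correlation_report",
    "correlation_category",
    "PairClassification",
    "PairClassificationResults",
    "metrics_frame",
]

CLASSIFIER_FAMILIES = (
    "linear_discriminant",
    "logistic_regression",
    "quadratic_discriminant",
    "svm_gaussian",
    "boosted_trees",
    "neural_network",
)

POSITIVE_LABEL = "correspondent"


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its fixed hyperparameters.

    ``n_learners`` applies to boosted trees, ``hidden_units`` and
    ``validation_fraction`` to the neural network; the remaining families
    run at library defaults.  No hyperparameter search is performed.
    """

    family: str
    n_learners: int = 50
    hidden_units: int = 50
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {CLASSIFIER_FAMILIES}")
        if self.n_learners <= 0 or self.hidden_units <= 0:
            raise ValueError("n_learners and hidden_units must be positive")


@dataclass(frozen=True)
class ClassificationMetrics:
    """Pooled out-of-fold confusion counts and derived metrics.

    ``ppv`` and ``sensitivity`` are ``None`` when the model never issued a
    positive prediction (rendered "n.a." in reports); specificity and AUC
    are always defined on a two-class dataset.
    """

    family: str
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    seed: int

    @property
    def ppv(self) -> float | None:
        return compute_ppv(self.tp, self.fp)

    @property
    def sensitivity(self) -> float | None:
        if self.tp + self.fp == 0:
            return None  # never predicted a positive: "n.a."
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_ppv(tp: int, fp: int) -> float | None:
    """Positive predictive value tp/(tp+fp); ``None`` ("n.a.") when no positives predicted."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        return None
    return tp / (tp + fp)


def _make_estimator(spec: ClassifierSpec):
    seed = spec.seed
    if spec.family == "linear_discriminant":
        return LinearDiscriminantAnalysis()
    if spec.family == "logistic_regression":
        return LogisticRegression(max_iter=2000)
    if spec.family == "quadratic_discriminant":
        return QuadraticDiscriminantAnalysis()
    if spec.family == "svm_gaussian":
        # standardised inputs: the RBF kernel scale is otherwise dominated
        # by the largest-variance feature
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    if spec.family == "boosted_trees":
        return AdaBoostClassifier(n_estimators=spec.n_learners, random_state=seed)
    if spec.family == "neural_network":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(spec.hidden_units,),
                activation="tanh",
                early_stopping=True,
                validation_fraction=spec.validation_fraction,
                max_iter=300,
                random_state=seed,
            ),
        )
    raise ValueError(f"unknown family {spec.family!r}")


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class score for ROC analysis."""
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)
        pos = list(estimator.classes_).index(1)
        return proba[:, pos]
    return estimator.decision_function(X)


def cross_validate(
    dataset: pd.DataFrame,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int | None = None,
    feature_columns: Sequence[str] = FEATURE_NAMES,
) -> ClassificationMetrics:
    """Stratified k-fold cross-validation with pooled out-of-fold metrics.

    The dataset is partitioned into k disjoint folds stratified on the
    label (with only n positives in n^2 rows, unstratified folds can be
    positive-free).  For each fold the model is trained on the remaining
    k-1 folds and its hard predictions and continuous scores on the held
    out fold are pooled; the confusion matrix, PPV, sensitivity and
    specificity come from the pooled hard predictions (0.5
    probability/score threshold, i.e. the estimator's ``predict``), and
    the AUC from the pooled scores.
    """
    if seed is None:
        seed = spec.seed
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(dataset):
        raise ValueError(f"k={k} exceeds dataset size {len(dataset)}")
    y = (dataset["label"] == POSITIVE_LABEL).astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both correspondent and non-correspondent rows")
    X = dataset[list(feature_columns)].to_numpy(dtype=float)

    spec = replace(spec, seed=seed)
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_pred = np.empty(len(y), dtype=int)
    pooled_score = np.empty(len(y), dtype=float)
    seen = np.zeros(len(y), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QDA collinearity / MLP convergence chatter
        for train_idx, test_idx in folds.split(X, y):
            est = _make_estimator(spec)
            est.fit(X[train_idx], y[train_idx])
            pooled_pred[test_idx] = est.predict(X[test_idx])
            pooled_score[test_idx] = _scores(est, X[test_idx])
            seen[test_idx] = True
    assert seen.all(), "folds must cover the dataset exactly once"

    tp = int(np.sum((pooled_pred == 1) & (y == 1)))
    fp = int(np.sum((pooled_pred == 1) & (y == 0)))
    tn = int(np.sum((pooled_pred == 0) & (y == 0)))
    fn = int(np.sum((pooled_pred == 0) & (y == 1)))
    auc = float(roc_auc_score(y, pooled_score))
    return ClassificationMetrics(family=spec.family, tp=tp, fp=fp, tn=tn, fn=fn,
                                 auc=auc, seed=seed)


def correlation_category(r: float) -> str:
    """Correlation-strength band: poor < 0.3 < low <= 0.5 < moderate <= 0.7 < strong."""
    if np.isnan(r):
        return "undefined"
    if r > 0.7:
        return "strong"
    if r > 0.5:
        return "moderate"
    if r > 0.3:
        return "low"
    return "poor"


def correlation_report(individuals: Iterable[MeasurementSet]) -> pd.DataFrame:
    """Pearson correlation between correspondent occipital/atlas measurements.

    One row per measurement pairing plus the norm pairing, with r, R^2,
    the two-sided p value and the strength band.  A pairing whose column
    has zero variance is reported undefined (NaN).
    """
    people = list(individuals)
    if len(people) < 3:
        raise ValueError("need at least 3 individuals for a correlation report")
    oc = np.stack([p.oc_vector() for p in people])
    c1 = np.stack([p.c1_vector() for p in people])
    pairs = [(f"f{i+1}", f"{a} - {b}", oc[:, i], c1[:, i])
             for i, (a, b) in enumerate(MEASUREMENT_PAIRINGS)]
    pairs.append(("f9", "norm_OC - norm_C1",
                  np.linalg.norm(oc, axis=1), np.linalg.norm(c1, axis=1)))
    rows = []
    for feature, desc, x, yv in pairs:
        if np.std(x) == 0 or np.std(yv) == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = stats.pearsonr(x, yv)
        rows.append({"feature": feature, "pairing": desc, "r": float(r),
                     "r_squared": float(r) ** 2, "p_value": float(p),
                     "category": correlation_category(float(r))})
    return pd.DataFrame(rows)


def metrics_frame(metrics: Iterable[ClassificationMetrics]) -> pd.DataFrame:
    """Tabulate per-family metrics; undefined values become NaN (written "n.a.")."""
    rows = []
    for m in metrics:
        rows.append({
            "family": m.family,
            "ppv": np.nan if m.ppv is None else m.ppv,
            "sensitivity": np.nan if m.sensitivity is None else m.sensitivity,
            "specificity": m.specificity,
            "auc": m.auc,
            "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
            "seed": m.seed,
        })
    return pd.DataFrame(rows)


class PairClassification:
    """Model object for the pairwise-correspondence classification arm.

    Parameters
    ----------
    dataset : pandas.DataFrame
        Pairwise dataset with columns ``f1..f9`` and ``label``
        (see :func:`craniosort.osteometry.build_pairwise_dataset`).
    feature_columns : sequence of str
        Feature columns to use; defaults to all nine.

    Examples
    --------
    >>> model = PairClassification(pairs)            # doctest: +SKIP
    >>> res = model.fit(k=10, seed=1)                # doctest: +SKIP
    >>> print(res.summary())                         # doctest: +SKIP
    """

    def __init__(self, dataset: pd.DataFrame,
                 feature_columns: Sequence[str] = FEATURE_NAMES):
        missing = set(feature_columns) | {"label"}
        missing -= set(dataset.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        self.dataset = dataset
        self.feature_columns = tuple(feature_columns)
        self.n_positive = int((dataset["label"] == POSITIVE_LABEL).sum())

    def fit(self, families: Sequence[str] = CLASSIFIER_FAMILIES,
            k: int = 10, seed: int = 0, **spec_kwargs) -> "PairClassificationResults":
        """Cross-validate each requested family and collect pooled metrics."""
        metrics = []
        for family in families:
            spec = ClassifierSpec(family=family, seed=seed, **spec_kwargs)
            metrics.append(cross_validate(self.dataset, spec, k=k, seed=seed,
                                          feature_columns=self.feature_columns))
        return PairClassificationResults(self, metrics, k=k, seed=seed)


class PairClassificationResults:
    """Cross-validated metrics for one or more classifier families."""

    def __init__(self, model: PairClassification,
                 metrics: list[ClassificationMetrics], k: int, seed: int):
        self.model = model
        self.metrics_list = metrics
        self.k = k
        self.seed = seed
        self.metrics = metrics_frame(metrics)

    def __getitem__(self, family: str) -> ClassificationMetrics:
        for m in self.metrics_list:
            if m.family == family:
                return m
        raise KeyError(family)

    def to_csv(self, path) -> None:
        """Write the metrics table; undefined entries are rendered "n.a."."""
        self.metrics.to_csv(path, index=False, na_rep="n.a.")

    def summary(self) -> str:
        """Human-readable metrics table.

        "n.a." marks a metric whose denominator is empty — e.g. the PPV of
        a model that never predicted a single correspondent pair.
        """
        lines = [
            "Pairwise correspondence classification "
            f"({self.k}-fold stratified CV, seed {self.seed}, "
            f"{len(self.model.dataset)} pairs, {self.model.n_positive} correspondent)",
            f"{'family':<22}{'PPV':>8}{'sens':>8}{'spec':>8}{'AUC':>8}{'tp':>6}{'fp':>8}",
        ]
        for m in self.metrics_list:
            ppv = "n.a." if m.ppv is None else f"{m.ppv:.3f}"
            sens = "n.a." if m.sensitivity is None else f"{m.sensitivity:.3f}"
            lines.append(
                f"{m.family:<22}{ppv:>8}{sens:>8}{m.specificity:>8.3f}"
                f"{m.auc:>8.3f}{m.tp:>6d}{m.fp:>8d}"
            )
        lines.append('"n.a.": no positive prediction was ever emitted.')
        return "\n".join(lines)
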