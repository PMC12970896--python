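"""Leakage-safe evaluation: recording-stratified CV, classifiers, metrics.

The evaluation protocol keeps all windows of a recording in the same fold
(recording-stratified k-fold, default 10) and derives every normalization
statistic — the min–max scaler and the DFI normalization bounds — from the
training fold only, applying them to the test fold with clipping.  Five
classifiers are supported with fixed, unoptimized hyperparameters: SVM
(RBF kernel, C=1), decision tree (max_depth=10), random forest and XGBoost
(100 estimators, max_depth=10) and KNN (5 neighbours).  Metrics (accuracy,
specificity, sensitivity, precision, F1) are computed per fold from the
test-fold confusion matrix — binary with the seizure/ictal class positive,
or macro-averaged one-vs-rest for multiclass — and reported as the mean
over folds; confusion matrices are summed over folds.

Feature subsets follow the ablation structure PLF (wave energies), NDF
(HFD + PE), DFI, and their combinations, written ``"plf"``, ``"ndf"``,
``"plf+ndf"``, ``"all"`` (= ``"plf+ndf+dfi"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamic import BASE_FEATURES, dfi, fit_bounds, normalize_sequence

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "MetricSet",
    "build_fold_plan",
    "fit_fold_scaler",
    "apply_scaler",
    "prepare_fold_features",
    "make_classifier",
    "compute_metrics",
    "run_task",
    "cross_dataset_eval",
    "permute_recording_labels",
    "subset_columns",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("dt", "rf", "knn", "svm", "xgb")

_SUBSET_FAMILIES = {
    "plf": ["spike_energy", "sharp_energy"],
    "ndf": ["hfd", "pe"],
    "dfi": ["dfi"],
}


def subset_columns(subset: str) -> list[str]:
    """Feature columns for an ablation subset spec like ``"plf+ndf"``.

    ``"all"`` expands to PLF+NDF+DFI.
    """
    if subset == "all":
        subset = "plf+ndf+dfi"
    cols: list[str] = []
    for part in subset.split("+"):
        part = part.strip().lower()
        if part not in _SUBSET_FAMILIES:
            raise ValueError(f"unknown feature family {part!r}")
        cols.extend(_SUBSET_FAMILIES[part])
    if not cols:
        raise ValueError("empty feature subset")
    return cols


def _child_seed(seed: int, counter: int) -> int:
    """Deterministic fan-out of a master seed via a counter scheme."""
    return int((seed * 1_000_003 + counter) % (2**31 - 1))


@dataclass
class FoldPlan:
    """Assignment of whole recordings to folds, stratified by label."""

    n_folds: int
    assignment: dict[str, int]
    seed: int

    def train_test_ids(self, fold: int) -> tuple[list[str], list[str]]:
        train = [r for r, f in self.assignment.items() if f != fold]
        test = [r for r, f in self.assignment.items() if f == fold]
        return train, test


def build_fold_plan(
    labels_by_recording: Mapping[str, str],
    n_folds: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Stratified recording-level fold assignment, deterministic given seed.

    Within each label class the recording ids are shuffled and dealt
    round-robin to folds, so per-fold class counts differ by at most one
    and no recording is split across folds.

    Raises
    ------
    ValueError
        If any class has fewer recordings than folds.
    """
    by_label: dict[str, list[str]] = {}
    for rid, lab in labels_by_recording.items():
        by_label.setdefault(lab, []).append(rid)
    for lab, rids in by_label.items():
        if len(rids) < n_folds:
            raise ValueError(
                f"class {lab!r} has {len(rids)} recordings < {n_folds} folds"
            )
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for lab in sorted(by_label):
        rids = sorted(by_label[lab])
        rng.shuffle(rids)
        for i, rid in enumerate(rids):
            assignment[rid] = i % n_folds
    return FoldPlan(n_folds=n_folds, assignment=assignment, seed=seed)


def fit_fold_scaler(
    train_features: pd.DataFrame,
    feature_cols: Sequence[str] = tuple(BASE_FEATURES),
) -> dict[str, tuple[float, float]]:
    """Per-feature (min, max) statistics from training rows only.

    Zero-variance features get degenerate bounds that map every value to 0
    (with a warning), matching the DFI normalization convention.
    """
    if len(train_features) == 0:
        raise ValueError("empty training table")
    scaler: dict[str, tuple[float, float]] = {}
    for col in feature_cols:
        bounds = fit_bounds(train_features[col].to_numpy())
        if bounds[0] == bounds[1]:
            warnings.warn(f"feature {col!r} has zero variance in train fold")
        scaler[col] = bounds
    return scaler


def apply_scaler(
    features: pd.DataFrame, scaler: Mapping[str, tuple[float, float]]
) -> pd.DataFrame:
    """Min–max scale columns to [0, 1] with clipping (train-fold bounds)."""
    out = features.copy()
    for col, bounds in scaler.items():
        out[col] = normalize_sequence(features[col].to_numpy(), bounds)
    return out


def prepare_fold_features(
    features: pd.DataFrame,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    dfi_convention: str = "sum_abs",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train/test tables with all 5 features, normalized leakage-free.

    Normalization bounds for both the model inputs and the DFI are fit on
    training-fold rows only; test rows are scaled with clipping.  The DFI
    is computed per recording (never differencing across recordings) from
    the normalized base-feature sequences.
    """
    train = features[features["recording_id"].isin(set(train_ids))].copy()
    test = features[features["recording_id"].isin(set(test_ids))].copy()
    bounds = fit_fold_scaler(train)
    train_dfi = dfi(train, bounds, convention=dfi_convention)
    test_dfi = dfi(test, bounds, convention=dfi_convention) if len(test) else \
        pd.Series(dtype=float)
    train = apply_scaler(train, bounds)
    train["dfi"] = train_dfi
    if len(test):
        test = apply_scaler(test, bounds)
        test["dfi"] = test_dfi
    else:
        test["dfi"] = pd.Series(dtype=float)
    return train, test


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the five classifiers with the fixed settings.

    No hyperparameter optimization: SVM uses an RBF kernel with C=1; the
    tree models use max_depth=10 with 100 estimators for the ensembles;
    KNN uses 5 neighbours.  All other settings are library defaults.
    """
    name = name.lower()
    if name == "svm":
        from sklearn.svm import SVC
        return SVC(kernel="rbf", C=1.0, probability=True, random_state=seed)
    if name == "dt":
        from sklearn.tree import DecisionTreeClassifier
        return DecisionTreeClassifier(max_depth=10, random_state=seed)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(n_estimators=100, max_depth=10,
                                      random_state=seed)
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier
        return KNeighborsClassifier(n_neighbors=5)
    if name == "xgb":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=100, max_depth=10,
                             random_state=seed, n_jobs=1)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class ConfusionMatrix:
    """Counts[true_class, predicted_class] over a fixed class order."""

    classes: list[str]
    counts: np.ndarray

    @classmethod
    def empty(cls, classes: Sequence[str]) -> "ConfusionMatrix":
        k = len(classes)
        return cls(list(classes), np.zeros((k, k), dtype=int))

    @classmethod
    def from_labels(
        cls, y_true: Sequence[str], y_pred: Sequence[str],
        classes: Sequence[str],
    ) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(list(classes), counts)

    @classmethod
    def from_binary_counts(
        cls, tp: int, fn: int, tn: int, fp: int,
        positive: str = "epileptic", negative: str = "non-epileptic",
    ) -> "ConfusionMatrix":
        return cls([negative, positive],
                   np.array([[tn, fp], [fn, tp]], dtype=int))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class order mismatch")
        return ConfusionMatrix(list(self.classes), self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricSet:
    """Accuracy / specificity / sensitivity / precision / F1, in [0, 1]."""

    acc: float
    spe: float
    sen: float
    pre: float
    f1: float
    averaging: str = "binary"

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "spe": self.spe, "sen": self.sen,
                "pre": self.pre, "f1": self.f1}


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        warnings.warn("0/0 metric ratio defined as 0")
        return 0.0
    return num / den


def _binary_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, ...]:
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    spe = _safe_div(tn, tn + fp)
    sen = _safe_div(tp, tp + fn)
    pre = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * pre * sen, pre + sen) if (pre + sen) > 0 else 0.0
    return acc, spe, sen, pre, f1


def compute_metrics(
    cm: ConfusionMatrix,
    averaging: str = "binary",
    positive: str | None = None,
) -> MetricSet:
    """Metric set from a confusion matrix.

    Binary: the standard TP/TN/FP/FN formulas with ``positive`` the
    epileptic class (defaults to the last class in the matrix order).
    Macro: each class is scored one-vs-rest and the metrics averaged with
    equal class weight.  0/0 ratios are defined as 0 with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if averaging == "binary":
        if len(cm.classes) != 2:
            raise ValueError("binary averaging needs a 2x2 matrix")
        pos = positive if positive is not None else cm.classes[-1]
        p = cm.classes.index(pos)
        n = 1 - p
        tp, fn = cm.counts[p, p], cm.counts[p, n]
        fp, tn = cm.counts[n, p], cm.counts[n, n]
        return MetricSet(*_binary_metrics(tp, tn, fp, fn), averaging="binary")
    if averaging == "macro":
        per_class = []
        total = cm.total
        for i in range(len(cm.classes)):
            tp = cm.counts[i, i]
            fn = cm.counts[i].sum() - tp
            fp = cm.counts[:, i].sum() - tp
            tn = total - tp - fn - fp
            per_class.append(_binary_metrics(tp, tn, fp, fn))
        means = np.mean(per_class, axis=0)
        return MetricSet(*[float(v) for v in means], averaging="macro")
    raise ValueError(f"unknown averaging {averaging!r}")


def _apply_task(
    features: pd.DataFrame, task: Mapping[str, str] | None
) -> pd.DataFrame:
    """Map recording labels to task classes, dropping unmapped rows."""
    if task is None:
        return features.copy()
    out = features[features["label"].isin(task)].copy()
    out["label"] = out["label"].map(task)
    return out


def _fold_confusion(
    features: pd.DataFrame,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    clf_name: str,
    feature_cols: Sequence[str],
    classes: Sequence[str],
    seed: int,
    dfi_convention: str = "sum_abs",
) -> ConfusionMatrix:
    """Train on one fold's training recordings, evaluate on its test fold."""
    train, test = prepare_fold_features(features, train_ids, test_ids,
                                        dfi_convention)
    clf = make_classifier(clf_name, seed)
    class_index = {c: i for i, c in enumerate(classes)}
    y_train = train["label"].map(class_index).to_numpy()
    clf.fit(train[list(feature_cols)].to_numpy(), y_train)
    pred = clf.predict(test[list(feature_cols)].to_numpy())
    y_pred = [classes[int(i)] for i in pred]
    return ConfusionMatrix.from_labels(test["label"].tolist(), y_pred, classes)


def run_task(
    features: pd.DataFrame,
    plan: FoldPlan,
    task: Mapping[str, str] | None = None,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    feature_subsets: Sequence[str] = ("plf", "ndf", "plf+ndf", "all"),
    positive: str | None = None,
    seed: int = 0,
    dfi_convention: str = "sum_abs",
) -> dict[str, dict[str, dict]]:
    """Cross-validated ablation over classifiers and feature subsets.

    Returns ``results[subset][classifier] = {"metrics": MetricSet,
    "fold_metrics": [MetricSet per fold], "confusion": ConfusionMatrix}``
    where the headline metrics are the mean over the test folds and the
    confusion matrix is summed over folds.  Binary tasks (2 task classes)
    use the ``positive`` class (default: the seizure/ictal-like class if
    recognizable, else the last class alphabetically); multiclass tasks
    are macro-averaged.
    """
    data = _apply_task(features, task)
    if len(data) == 0:
        raise ValueError("no rows remain after applying task mapping")
    classes = sorted(data["label"].unique())
    averaging = "binary" if len(classes) == 2 else "macro"
    if averaging == "binary" and positive is None:
        ictal_like = [c for c in classes
                      if c in ("ictal", "seizure", "epileptic")]
        positive = ictal_like[0] if ictal_like else classes[-1]
    results: dict[str, dict[str, dict]] = {}
    for subset in feature_subsets:
        cols = subset_columns(subset)
        results[subset] = {}
        for ci, clf_name in enumerate(classifiers):
            fold_metrics = []
            total_cm = ConfusionMatrix.empty(classes)
            for fold in range(plan.n_folds):
                train_ids, test_ids = plan.train_test_ids(fold)
                cm = _fold_confusion(
                    data, train_ids, test_ids, clf_name, cols, classes,
                    seed=_child_seed(seed, 97 * ci + fold),
                    dfi_convention=dfi_convention,
                )
                fold_metrics.append(
                    compute_metrics(cm, averaging, positive=positive))
                total_cm = total_cm + cm
            mean = MetricSet(
                acc=float(np.mean([m.acc for m in fold_metrics])),
                spe=float(np.mean([m.spe for m in fold_metrics])),
                sen=float(np.mean([m.sen for m in fold_metrics])),
                pre=float(np.mean([m.pre for m in fold_metrics])),
                f1=float(np.mean([m.f1 for m in fold_metrics])),
                averaging=averaging,
            )
            results[subset][clf_name] = {
                "metrics": mean,
                "fold_metrics": fold_metrics,
                "confusion": total_cm,
            }
    return results


def cross_dataset_eval(
    train_features: pd.DataFrame,
    test_features: pd.DataFrame,
    classifier: str = "xgb",
    task: Mapping[str, str] | None = None,
    feature_subset: str = "all",
    positive: str | None = None,
    seed: int = 0,
    dfi_convention: str = "sum_abs",
) -> tuple[MetricSet, ConfusionMatrix]:
    """Train on one dataset, test on another (no CV, one pass).

    The scaler and DFI bounds are fit on the training table only.  Both
    tables must carry the same base-feature schema and task-mapped labels
    must coincide.
    """
    train = _apply_task(train_features, task)
    test = _apply_task(test_features, task)
    missing = [c for c in BASE_FEATURES if c not in test.columns]
    if missing or len(train) == 0 or len(test) == 0:
        raise ValueError("schema mismatch or empty table")
    classes = sorted(set(train["label"]) | set(test["label"]))
    averaging = "binary" if len(classes) == 2 else "macro"
    if averaging == "binary" and positive is None:
        ictal_like = [c for c in classes
                      if c in ("ictal", "seizure", "epileptic")]
        positive = ictal_like[0] if ictal_like else classes[-1]
    # Recording ids may collide across datasets; prefix to keep them apart.
    train = train.assign(recording_id="src::" + train["recording_id"].astype(str))
    test = test.assign(recording_id="tgt::" + test["recording_id"].astype(str))
    cm = _fold_confusion(
        pd.concat([train, test], ignore_index=True),
        train["recording_id"].unique().tolist(),
        test["recording_id"].unique().tolist(),
        classifier,
        subset_columns(feature_subset),
        classes,
        seed=_child_seed(seed, 1),
        dfi_convention=dfi_convention,
    )
    return compute_metrics(cm, averaging, positive=positive), cm


def permute_recording_labels(
    features: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Permute labels across recordings (all windows of a recording move
    together) — the null model for permutation sanity checks."""
    rng = np.random.default_rng(seed)
    rids = sorted(features["recording_id"].unique())
    labels = [features.loc[features["recording_id"] == r, "label"].iloc[0]
              for r in rids]
    shuffled = list(labels)
    rng.shuffle(shuffled)
    mapping = dict(zip(rids, shuffled))
    out = features.copy()
    out["label"] = out["recording_id"].map(mapping)
    return out
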