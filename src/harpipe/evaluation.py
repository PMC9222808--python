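"""Classifier training, the evaluation protocols, metrics, and the RF grid.

Three protocols are provided:

* ``subject_dependent_x10`` — 10 independent stratified 70/30 splits of the
  windows; one subject's windows may land on both sides of a split.  Reports
  per-run metrics and their mean/STD.
* ``stratified_10fold`` — stratified k-fold cross-validation (class
  proportions preserved per fold to within one record).
* ``leave_one_subject_out`` — each subject's windows form one test fold;
  measures generalization to unseen people.

Min-max normalization is re-fitted on the training side of every split so no
test-set information leaks into the transform.  Accuracy is correct/total;
precision and recall are per-class TP/(TP+FP) and TP/(TP+FN) with the 0/0
case defined as 0; the F-measure is reported both as the harmonic mean
(default) and as the arithmetic mean of precision and recall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .io_formats import FeatureRecord
from .features import apply_minmax, fit_minmax

__all__ = [
    "ClassifierConfig",
    "EvaluationReport",
    "subject_dependent_split",
    "stratified_kfold_indices",
    "leave_one_subject_out_indices",
    "train_classifier",
    "evaluate",
    "run_protocol",
    "sensitivity_grid",
    "PROTOCOLS",
]

PROTOCOLS = ("subject_dependent_x10", "stratified_10fold", "leave_one_subject_out")


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier family plus its hyper-parameters.

    Defaults follow the configurations this pipeline was designed around:
    RF with 200 trees of maximum depth 25 (min_samples_split 2); RBF-kernel
    SVM; a 75-neuron tanh MLP trained with a quasi-Newton solver (max 1000
    iterations, 15% validation fraction); Gaussian naive Bayes with
    maximum-likelihood moments.
    """

    kind: str = "rf"
    n_estimators: int = 200
    max_depth: int | None = 25
    min_samples_split: int = 2
    hidden_neurons: int = 75
    max_iter: int = 1000
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "svm", "mlp", "nb"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def build(self, seed: int | None = None):
        seed = self.random_seed if seed is None else seed
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
                random_state=seed,
                n_jobs=1,
            )
        if self.kind == "svm":
            return SVC(kernel="rbf", random_state=seed)
        if self.kind == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=(self.hidden_neurons,),
                activation="tanh",
                solver="lbfgs",
                max_iter=self.max_iter,
                validation_fraction=0.15,
                random_state=seed,
            )
        return GaussianNB()


def _records_to_xy(records: Sequence[FeatureRecord]):
    X = np.vstack([r.vector for r in records])
    y = np.asarray([r.label for r in records])
    return X, y


def subject_dependent_split(
    records: Sequence[FeatureRecord],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Stratified random split: exactly round(train_fraction * n) per class.

    Returns (train_indices, test_indices); disjoint, union = all records.
    Subjects may appear on both sides — this is the subject-dependent
    protocol, not leave-one-subject-out.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    labels = np.asarray([r.label for r in records])
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 records")
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return sorted(train_idx), sorted(test_idx)


def stratified_kfold_indices(
    records: Sequence[FeatureRecord],
    k: int = 10,
    seed: int = 0,
) -> list[tuple[list[int], list[int]]]:
    """Stratified k-fold partitions: per-fold class counts within 1 of ideal."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray([r.label for r in records])
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < k]
    if len(too_small):
        raise ValueError(f"classes smaller than k={k}: {too_small.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train.tolist(), test.tolist())
        for train, test in skf.split(np.zeros(len(labels)), labels)
    ]


def leave_one_subject_out_indices(
    records: Sequence[FeatureRecord],
) -> list[tuple[list[int], list[int]]]:
    """One fold per subject: that subject's windows are the test set."""
    subjects = np.asarray([r.subject_id for r in records])
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects for leave-one-subject-out")
    return [
        (np.flatnonzero(subjects != s).tolist(), np.flatnonzero(subjects == s).tolist())
        for s in uniq
    ]


def train_classifier(
    train_records: Sequence[FeatureRecord],
    config: ClassifierConfig,
    seed: int | None = None,
):
    """Fit the configured classifier; deterministic given the seed."""
    X, y = _records_to_xy(train_records)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    model = config.build(seed)
    model.fit(X, y)
    return model


@dataclass
class EvaluationReport:
    """Confusion matrix plus derived metrics, optionally aggregated over runs."""

    labels: list[str]
    confusion: np.ndarray
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_f1_arithmetic: float
    per_run: list["EvaluationReport"] = field(default_factory=list)
    accuracy_mean: float | None = None
    accuracy_std: float | None = None
    f1_mean: float | None = None
    f1_std: float | None = None

    def to_dict(self) -> dict:
        d = {
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_f1_arithmetic": self.macro_f1_arithmetic,
        }
        if self.per_run:
            d["runs"] = [r.to_dict() for r in self.per_run]
            d["accuracy_mean"] = self.accuracy_mean
            d["accuracy_std"] = self.accuracy_std
            d["f1_mean"] = self.f1_mean
            d["f1_std"] = self.f1_std
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def evaluate(model, test_records: Sequence[FeatureRecord]) -> EvaluationReport:
    """Confusion matrix and per-class precision/recall/F-measure on a test set."""
    if not len(test_records):
        raise ValueError("empty test set")
    X, y_true = _records_to_xy(test_records)
    y_pred = model.predict(X)
    labels = sorted(set(y_true) | set(y_pred))
    index = {lab: i for i, lab in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total)

    per_class = {}
    precisions, recalls, f1s, f1as = [], [], [], []
    for i, lab in enumerate(labels):
        tp = float(confusion[i, i])
        fp = float(confusion[:, i].sum() - tp)
        fn = float(confusion[i, :].sum() - tp)
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * prec * rec, prec + rec)
        f1a = (prec + rec) / 2
        per_class[lab] = {
            "precision": prec,
            "recall": rec,
            "f_measure": f1,
            "f_measure_arithmetic": f1a,
            "support": int(confusion[i, :].sum()),
        }
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
        f1as.append(f1a)
    return EvaluationReport(
        labels=labels,
        confusion=confusion,
        accuracy=accuracy,
        per_class=per_class,
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
        macro_f1_arithmetic=float(np.mean(f1as)),
    )


def _aggregate(reports: list[EvaluationReport]) -> EvaluationReport:
    accs = np.array([r.accuracy for r in reports])
    f1s = np.array([r.macro_f1 for r in reports])
    # merge confusions over the union label set
    labels = sorted({lab for r in reports for lab in r.labels})
    index = {lab: i for i, lab in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for r in reports:
        for i, li in enumerate(r.labels):
            for j, lj in enumerate(r.labels):
                confusion[index[li], index[lj]] += r.confusion[i, j]
    merged = evaluate_confusion(labels, confusion)
    merged.per_run = reports
    merged.accuracy_mean = float(accs.mean())
    merged.accuracy_std = float(accs.std())
    merged.f1_mean = float(f1s.mean())
    merged.f1_std = float(f1s.std())
    return merged


def evaluate_confusion(labels: list[str], confusion: np.ndarray) -> EvaluationReport:
    """Build a report directly from a confusion matrix (used for aggregation)."""
    total = confusion.sum()
    per_class = {}
    precisions, recalls, f1s, f1as = [], [], [], []
    for i, lab in enumerate(labels):
        tp = float(confusion[i, i])
        fp = float(confusion[:, i].sum() - tp)
        fn = float(confusion[i, :].sum() - tp)
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        per_class[lab] = {
            "precision": prec,
            "recall": rec,
            "f_measure": _safe_div(2 * prec * rec, prec + rec),
            "f_measure_arithmetic": (prec + rec) / 2,
            "support": int(confusion[i, :].sum()),
        }
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(per_class[lab]["f_measure"])
        f1as.append(per_class[lab]["f_measure_arithmetic"])
    return EvaluationReport(
        labels=labels,
        confusion=confusion,
        accuracy=float(np.trace(confusion) / total) if total else 0.0,
        per_class=per_class,
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
        macro_f1_arithmetic=float(np.mean(f1as)),
    )


def _fit_eval_split(
    records: Sequence[FeatureRecord],
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    config: ClassifierConfig,
    seed: int,
) -> EvaluationReport:
    train = [records[i] for i in train_idx]
    test = [records[i] for i in test_idx]
    params = fit_minmax(train)
    train_n = apply_minmax(train, params)
    test_n = apply_minmax(test, params)
    model = train_classifier(train_n, config, seed=seed)
    return evaluate(model, test_n)


def run_protocol(
    records: Sequence[FeatureRecord],
    protocol: str = "subject_dependent_x10",
    config: ClassifierConfig | None = None,
    seed: int = 0,
    n_runs: int = 10,
    k: int = 10,
) -> EvaluationReport:
    """Run one evaluation protocol end to end and aggregate the results.

    Each split re-fits min-max normalization on its training side and
    re-seeds the classifier (run seed = seed + run index), so repeated calls
    with the same inputs are bit-identical.
    """
    if not len(records):
        raise ValueError("no records")
    config = config or ClassifierConfig()
    if protocol == "subject_dependent_x10":
        splits = [
            subject_dependent_split(records, seed=seed + i) for i in range(n_runs)
        ]
    elif protocol == "stratified_10fold":
        splits = stratified_kfold_indices(records, k=k, seed=seed)
    elif protocol == "leave_one_subject_out":
        splits = leave_one_subject_out_indices(records)
    else:
        raise ValueError(f"unknown protocol {protocol!r}; use one of {PROTOCOLS}")
    reports = [
        _fit_eval_split(records, tr, te, config, seed=seed + i)
        for i, (tr, te) in enumerate(splits)
    ]
    return _aggregate(reports)


def sensitivity_grid(
    records: Sequence[FeatureRecord],
    sizes: Sequence[int] = (50, 100, 200, 400),
    depths: Sequence[int] = (15, 20, 25, 30, 40),
    protocol: str = "subject_dependent_x10",
    seed: int = 0,
    n_runs: int = 3,
) -> np.ndarray:
    """Mean accuracy for every (forest size, forest depth) cell.

    Returns a len(sizes) x len(depths) matrix; the default grid is the
    4 x 5 sweep of 50/100/200/400 trees by depth 15/20/25/30/40.
    """
    if not len(sizes) or not len(depths):
        raise ValueError("sizes and depths must be nonempty")
    grid = np.zeros((len(sizes), len(depths)))
    for i, size in enumerate(sizes):
        for j, depth in enumerate(depths):
            config = ClassifierConfig(kind="rf", n_estimators=size, max_depth=depth)
            report = run_protocol(
                records, protocol=protocol, config=config, seed=seed, n_runs=n_runs
            )
            grid[i, j] = (
                report.accuracy_mean
                if report.accuracy_mean is not None
                else report.accuracy
            )
    return grid
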