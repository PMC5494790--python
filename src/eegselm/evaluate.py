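"""Evaluation protocol: confusion matrix, metrics, k-fold CV, grid search.

The 3x3 confusion matrix is indexed [output class][desired class]: entry
``S_XY`` counts epochs truly of class Y predicted as class X.  Per-class
sensitivity is the diagonal over the column sum; per-class specificity
counts a sample of another class predicted as *any* other class as a true
negative (for class A: ``(S_DD + S_DE + S_ED + S_EE) / (S_D + S_E)``); and
total accuracy is the trace over the grand total.

Cross-validation uses k = 4 stratified folds assigned at the epoch level
with a seeded shuffle; a segment-level mode avoids leakage between the
overlapping epochs of one segment and is recommended for realistic error
estimates.  Fold metrics are reported both pooled (confusions summed over
folds) and per fold.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_synth import CLASS_LABELS
from .multiclass import MulticlassModel, predict_batch, train_multiclass
from .selm import KernelSpec, UpdateMode

__all__ = [
    "ConfusionMatrix3",
    "MetricsReport",
    "CVPlan",
    "GridSpec",
    "CVResult",
    "confusion",
    "metrics",
    "kfold_split",
    "cross_validate",
    "grid_search",
    "reference_settings",
]


@dataclass(frozen=True)
class ConfusionMatrix3:
    """Desired-vs-output counts; rows are outputs, columns desired classes."""

    counts: np.ndarray
    class_list: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_list)
        if counts.shape != (k, k) or np.any(counts < 0):
            raise ValueError(f"counts must be a non-negative {k}x{k} matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def true_counts(self) -> np.ndarray:
        """Per-class number of truly-that-class samples (column sums)."""
        return self.counts.sum(axis=0)

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        if self.class_list != other.class_list:
            raise ValueError("cannot add confusion matrices over different classes")
        return ConfusionMatrix3(self.counts + other.counts, self.class_list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"out_{c}" for c in self.class_list],
            columns=[f"true_{c}" for c in self.class_list],
        )


@dataclass(frozen=True)
class MetricsReport:
    """Per-class sensitivity/specificity and total accuracy, all in [0, 1]."""

    sensitivity: dict[str, float]
    specificity: dict[str, float]
    total_accuracy: float
    fold: str = "pooled"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "sensitivity": self.sensitivity[c],
                "specificity": self.specificity[c],
            }
            for c in self.sensitivity
        ]
        frame = pd.DataFrame(rows)
        frame["total_accuracy"] = self.total_accuracy
        frame["fold"] = self.fold
        return frame


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_list: Sequence[str] = CLASS_LABELS,
) -> ConfusionMatrix3:
    """Count desired-vs-output pairs into a confusion matrix."""
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label sequences must have equal length")
    class_list = tuple(class_list)
    index = {c: i for i, c in enumerate(class_list)}
    counts = np.zeros((len(class_list), len(class_list)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label pair ({t!r}, {p!r}) outside class list {class_list}")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix3(counts, class_list)


def metrics(cm: ConfusionMatrix3, fold: str = "pooled") -> MetricsReport:
    """Sensitivity, specificity and total accuracy from a confusion matrix.

    A class with no true samples has undefined sensitivity, reported as
    NaN with a warning.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts
    col_sums = cm.true_counts()
    sens: dict[str, float] = {}
    spec: dict[str, float] = {}
    for i, c in enumerate(cm.class_list):
        if col_sums[i] == 0:
            import warnings

            warnings.warn(f"no true samples of class {c}; sensitivity undefined")
            sens[c] = float("nan")
        else:
            sens[c] = counts[i, i] / col_sums[i]
        others = [j for j in range(len(cm.class_list)) if j != i]
        negatives = col_sums[others].sum()
        true_negatives = counts[np.ix_(others, others)].sum()
        spec[c] = float(true_negatives / negatives) if negatives else float("nan")
    accuracy = float(np.trace(counts) / cm.total)
    return MetricsReport(sensitivity=sens, specificity=spec, total_accuracy=accuracy, fold=fold)


@dataclass(frozen=True)
class CVPlan:
    """k-fold assignment policy: stratified, seeded, epoch- or segment-level."""

    k: int = 4
    seed: int = 0
    stratified: bool = True
    by_segment: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def _fold_assignment(
    labels: np.ndarray, groups: np.ndarray | None, plan: CVPlan
) -> np.ndarray:
    rng = np.random.default_rng(plan.seed)
    n = labels.size
    assignment = np.empty(n, dtype=int)
    if groups is not None:
        # assign whole groups (segments) to folds, stratified by group label
        uniq = pd.unique(groups)
        group_label = {g: labels[groups == g][0] for g in uniq}
        strata = (
            {lab: [g for g in uniq if group_label[g] == lab] for lab in dict.fromkeys(group_label.values())}
            if plan.stratified
            else {"all": list(uniq)}
        )
        fold_of_group: dict = {}
        for members in strata.values():
            order = rng.permutation(len(members))
            for pos, idx in enumerate(order):
                fold_of_group[members[idx]] = pos % plan.k
        for i in range(n):
            assignment[i] = fold_of_group[groups[i]]
        return assignment
    if plan.stratified:
        for lab in dict.fromkeys(labels.tolist()):
            idx = np.flatnonzero(labels == lab)
            order = rng.permutation(idx.size)
            assignment[idx[order]] = np.arange(idx.size) % plan.k
    else:
        order = rng.permutation(n)
        assignment[order] = np.arange(n) % plan.k
    return assignment


def kfold_split(
    labels: Sequence[str],
    plan: CVPlan = CVPlan(),
    groups: Sequence[str] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (seeded) k-fold partition into (train, test) index pairs.

    Folds are mutually exclusive and jointly exhaustive; with epoch-level
    stratification per-class fold sizes differ by at most one.  Passing
    ``groups`` (or ``plan.by_segment``) assigns whole segments to folds so
    overlapping epochs of one segment never straddle the train/test split.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size < plan.k:
        raise ValueError(f"dataset of size {labels.size} is smaller than k={plan.k}")
    garr = np.asarray(groups, dtype=object) if groups is not None else None
    assignment = _fold_assignment(labels, garr, plan)
    splits = []
    for fold in range(plan.k):
        test = np.flatnonzero(assignment == fold)
        train = np.flatnonzero(assignment != fold)
        splits.append((train, test))
    return splits


@dataclass(frozen=True)
class CVResult:
    pooled: MetricsReport
    per_fold: list[MetricsReport]
    pooled_confusion: ConfusionMatrix3


def cross_validate(
    X: np.ndarray,
    y: Sequence[str],
    strategy: str = "OAO",
    class_list: Sequence[str] = CLASS_LABELS,
    structure=None,
    C: float = 5.0,
    epsilon: float = 1e-3,
    kernel: KernelSpec = KernelSpec.gaussian(500.0),
    plan: CVPlan = CVPlan(),
    groups: Sequence[str] | None = None,
    max_iter: int | None = None,
    mode: UpdateMode = "newton",
) -> CVResult:
    """k-fold cross-validation of a multiclass SELM.

    Trains on k-1 folds, tests on the held-out fold, and pools the k test
    confusion matrices; per-fold reports are also returned.  Pooled
    accuracy equals total correct over total tested, exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=object)
    splits = kfold_split(y, plan, groups=groups)
    per_fold: list[MetricsReport] = []
    pooled_cm: ConfusionMatrix3 | None = None
    for fold_idx, (train, test) in enumerate(splits):
        model = train_multiclass(
            (X[train], y[train]),
            strategy=strategy,
            class_list=class_list,
            structure=structure,
            C=C,
            epsilon=epsilon,
            kernel=kernel,
            max_iter=max_iter,
            mode=mode,
        )
        pred = predict_batch(model, X[test])
        cm = confusion(y[test], pred, class_list)
        per_fold.append(metrics(cm, fold=f"fold{fold_idx}"))
        pooled_cm = cm if pooled_cm is None else pooled_cm + cm
    assert pooled_cm is not None
    return CVResult(
        pooled=metrics(pooled_cm, fold="pooled"),
        per_fold=per_fold,
        pooled_confusion=pooled_cm,
    )


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grids for the kernel-parameter search.

    Defaults: 8 values of C; 12 values of the Gaussian width 2*sigma^2;
    7 polynomial degrees.
    """

    C_values: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 30.0)
    two_sigma_sq_values: tuple[float, ...] = (
        1.0, 5.0, 10.0, 60.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0,
    )
    m_values: tuple[int, ...] = (1, 2, 3, 4, 5, 10, 20)

    def __post_init__(self) -> None:
        for values in (self.C_values, self.two_sigma_sq_values, self.m_values):
            if not values or any(v <= 0 for v in values):
                raise ValueError("grid values must be non-empty and positive")


def grid_search(
    X: np.ndarray,
    y: Sequence[str],
    strategy: str = "OAO",
    kernel_family: str = "gaussian",
    grid: GridSpec = GridSpec(),
    class_list: Sequence[str] = CLASS_LABELS,
    structure=None,
    epsilon: float = 1e-3,
    plan: CVPlan = CVPlan(),
    groups: Sequence[str] | None = None,
    max_iter: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Exhaustive (C, kernel-parameter) search by cross-validated accuracy.

    Returns the full accuracy table (figure-ready) and the best setting;
    ties prefer the smaller C, then the smaller kernel parameter.
    """
    if kernel_family == "gaussian":
        param_name, param_values = "two_sigma_sq", grid.two_sigma_sq_values
        make = KernelSpec.gaussian
    elif kernel_family == "polynomial":
        param_name, param_values = "m", grid.m_values
        make = KernelSpec.polynomial
    else:
        raise ValueError("grid search supports 'gaussian' and 'polynomial' kernels")
    rows = []
    for C in grid.C_values:
        for value in param_values:
            result = cross_validate(
                X,
                y,
                strategy=strategy,
                class_list=class_list,
                structure=structure,
                C=C,
                epsilon=epsilon,
                kernel=make(value),
                plan=plan,
                groups=groups,
                max_iter=max_iter,
            )
            row = {"C": C, param_name: value, "accuracy": result.pooled.total_accuracy}
            for c in class_list:
                row[f"sensitivity_{c}"] = result.pooled.sensitivity[c]
            rows.append(row)
    table = pd.DataFrame(rows)
    best_row = table.sort_values(
        ["accuracy", "C", param_name], ascending=[False, True, True], kind="mergesort"
    ).iloc[0]
    best = {"C": float(best_row["C"]), param_name: float(best_row[param_name]),
            "accuracy": float(best_row["accuracy"])}
    return table, best


def reference_settings() -> dict:
    """The published reference configuration (OAO, Gaussian, C=5, 2σ²=500).

    Loaded from the ``reference_settings.yaml`` file shipped with the
    package; pass the values straight to :func:`cross_validate` or the CLI.
    """
    text = (
        importlib.resources.files("eegselm")
        .joinpath("reference_settings.yaml")
        .read_text()
    )
    return yaml.safe_load(text)
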