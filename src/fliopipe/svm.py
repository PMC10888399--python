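"""Grouped stratified repeated cross-validation around an RBF-kernel SVM.

The protocol mirrors the clinical study design this pipeline targets:
subjects (not eyes) are dealt into k = 5 folds so that the proportions of
non-smokers, light smokers and heavy smokers are preserved as well as
possible and both eyes of a subject always share a fold; the classifier
is a soft-margin SVM with radial basis kernel k(x, y) = exp(-g ||x-y||^2)
on z-scored features; the whole procedure is repeated (default 20 times)
with freshly shuffled folds, confusion cells are summed over the k folds
of a repeat (each sample predicted exactly once per repeat) and then
averaged over repeats.  Consequently mean TP + mean FN equals the
positive sample count exactly, as in the published summary tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

from .etdrs import SUBSETS, subset_columns
from .model import CvResult, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "SvmConfig",
    "CvConfig",
    "make_folds",
    "train_svm",
    "run_cv",
    "confusion_metrics",
    "round_half_up",
]


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameters.

    Defaults are the de-facto standard for heterogeneous feature scales:
    per-feature z-scoring fitted on the training rows, C = 1, and the
    'scale' rule gamma = 1 / (d * pooled feature variance).
    """

    C: float = 1.0
    gamma: float | str = "scale"
    standardize: bool = True
    class_weight: str | dict | None = None

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not isinstance(self.gamma, str) and self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass(frozen=True)
class CvConfig:
    """Protocol parameters of the repeated grouped stratified CV."""

    k: int = 5
    repeats: int = 20
    positive_class: str = "smoker"  # or "heavy_smoker"
    seed: int = 0
    leakage_safe_selection: bool = True  # recompute t-test ranking per training fold

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.positive_class not in ("smoker", "heavy_smoker"):
            raise ValueError("positive_class must be 'smoker' or 'heavy_smoker'")


def make_folds(
    subject_strata: dict[str, str],
    cv: CvConfig,
    repeat_index: int,
) -> list[list[str]]:
    """Deal subjects into k stratified folds for one repeat.

    Within each stratum the subjects are shuffled with a per-repeat seed
    and dealt round-robin, so fold sizes within a stratum differ by at
    most one; fold identities are then permuted so no fold is
    systematically the largest.  Deterministic in (seed, repeat_index).
    """
    if not subject_strata:
        raise ValueError("no subjects to fold")
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([cv.seed, repeat_index]))
    )
    folds: list[list[str]] = [[] for _ in range(cv.k)]
    strata: dict[str, list[str]] = {}
    for sid in sorted(subject_strata):
        strata.setdefault(subject_strata[sid], []).append(sid)
    for stratum in sorted(strata):
        order = rng.permutation(len(strata[stratum]))
        for pos, idx in enumerate(order):
            folds[pos % cv.k].append(strata[stratum][idx])
    relabel = rng.permutation(cv.k)
    return [folds[i] for i in relabel]


def train_svm(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    config: SvmConfig = SvmConfig(),
):
    """Fit scaler (+ mean imputer when needed) + RBF-SVM as one pipeline."""
    from sklearn.impute import SimpleImputer
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    steps = []
    if np.isnan(X).any():
        logger.info("imputing missing feature values with training-fold means")
        steps.append(("impute", SimpleImputer(strategy="mean")))
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "svm",
            SVC(
                kernel="rbf",
                C=config.C,
                gamma=config.gamma,
                class_weight=config.class_weight,
                random_state=0,
            ),
        )
    )
    return Pipeline(steps).fit(X, y)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of the report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_metrics(tp: float, fn: float, fp: float, tn: float) -> tuple[float, float, float]:
    """(TPR, FPR, accuracy) as percentages from confusion cells.

    Zero denominators yield NaN for the affected rate with a warning
    rather than failing silently.
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("confusion cells must be non-negative")
    pos, neg = tp + fn, fp + tn
    tpr = tp / pos * 100.0 if pos > 0 else float("nan")
    fpr = fp / neg * 100.0 if neg > 0 else float("nan")
    total = pos + neg
    acc = (tp + tn) / total * 100.0 if total > 0 else float("nan")
    if pos == 0 or neg == 0:
        warnings.warn(
            "confusion metrics undefined for an empty class (zero denominator)",
            RuntimeWarning,
            stacklevel=2,
        )
    return tpr, fpr, acc


def _prepare_experiment(table: FeatureTable, cv: CvConfig) -> tuple[FeatureTable, np.ndarray]:
    if cv.positive_class == "heavy_smoker":
        table = table.restrict_statuses(("non_smoker", "heavy_smoker"))
    y = table.binary_labels(cv.positive_class)
    return table, y


def run_cv(
    table: FeatureTable,
    subset: str | Sequence[str],
    cv: CvConfig = CvConfig(),
    svm: SvmConfig = SvmConfig(),
) -> CvResult:
    """Repeated grouped stratified cross-validation of one feature subset.

    ``subset`` is a named subset (see :data:`fliopipe.etdrs.SUBSETS`) or
    an explicit list of feature columns.  For the ``heavy_smoker``
    experiment, light smokers' rows are dropped before anything else.
    With ``subset = 'ttest_top3'`` and leakage-safe selection (default)
    the t-test ranking is recomputed inside every training fold; in
    whole-dataset mode ("paper mode") it is computed once on all rows.
    """
    table, y = _prepare_experiment(table, cv)
    if len(table) == 0:
        raise ValueError("no samples left after class restriction")
    strata = {}
    for sid, lab in zip(table.subject_ids, table.labels):
        strata[sid] = lab

    dynamic_selection = isinstance(subset, str) and SUBSETS.get(subset, ...) is None
    if isinstance(subset, str):
        subset_name = subset
        if dynamic_selection and not cv.leakage_safe_selection:
            columns = subset_columns(subset, table, y)
        elif dynamic_selection:
            columns = None  # resolved per training fold
        else:
            columns = subset_columns(subset)
    else:
        subset_name = "custom"
        columns = list(subset)

    sids = np.array(table.subject_ids)
    all_features = table.features
    P = int(y.sum())
    N = int(len(y) - P)

    per_repeat: list[tuple[int, int, int, int]] = []
    for r in range(cv.repeats):
        folds = make_folds(strata, cv, r)
        tp = fn = fp = tn = 0
        for test_subjects in folds:
            test_mask = np.isin(sids, test_subjects)
            if not test_mask.any():
                continue
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)
            if columns is None:
                fold_table = table.select_rows(list(train_idx))
                cols = subset_columns(subset_name, fold_table, y[train_idx])
            else:
                cols = columns
            Xtr = all_features.loc[:, cols].to_numpy(float)[train_idx]
            Xte = all_features.loc[:, cols].to_numpy(float)[test_idx]
            model = train_svm(Xtr, y[train_idx], svm)
            pred = np.asarray(model.predict(Xte))
            truth = y[test_idx]
            tp += int(np.sum((pred == 1) & (truth == 1)))
            fn += int(np.sum((pred == 0) & (truth == 1)))
            fp += int(np.sum((pred == 1) & (truth == 0)))
            tn += int(np.sum((pred == 0) & (truth == 0)))
        if tp + fn != P or fp + tn != N:
            raise AssertionError(
                f"repeat {r}: confusion totals {tp + fn}/{fp + tn} do not match "
                f"class counts {P}/{N}"
            )
        per_repeat.append((tp, fn, fp, tn))

    arr = np.asarray(per_repeat, dtype=float)
    mean_tp, mean_fn, mean_fp, mean_tn = arr.mean(axis=0)
    tpr, fpr, acc = confusion_metrics(mean_tp, mean_fn, mean_fp, mean_tn)
    rep_rates = np.array([confusion_metrics(*row) for row in per_repeat])
    sds = rep_rates.std(axis=0, ddof=1) if len(per_repeat) > 1 else np.zeros(3)
    return CvResult(
        mean_tp=float(mean_tp),
        mean_fn=float(mean_fn),
        mean_fp=float(mean_fp),
        mean_tn=float(mean_tn),
        tpr=tpr,
        fpr=fpr,
        accuracy=acc,
        sd_tpr=float(sds[0]),
        sd_fpr=float(sds[1]),
        sd_accuracy=float(sds[2]),
        per_repeat=per_repeat,
        config={
            "subset": subset_name,
            "n_features": len(columns) if columns is not None else 3,
            "k": cv.k,
            "repeats": cv.repeats,
            "positive_class": cv.positive_class,
            "seed": cv.seed,
            "leakage_safe_selection": cv.leakage_safe_selection,
            "svm": asdict(SvmConfig(C=svm.C, gamma=svm.gamma, standardize=svm.standardize,
                                    class_weight=svm.class_weight)),
            "n_positive": P,
            "n_negative": N,
        },
    )
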