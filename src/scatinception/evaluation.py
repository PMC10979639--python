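"""Cross-validation splitting, confusion-matrix metrics, ROC/AUC, fold
aggregation and slice-to-case fusion.

Conventions: GBM is the positive class, MET the negative class.
Accuracy = (TP+TN)/(TP+FN+TN+FP), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP).  An undefined ratio (empty denominator) is
reported as NaN with a warning, never silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import InputError

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "FoldSplit",
    "ConfusionCounts",
    "MetricsReport",
    "make_folds",
    "assign_fixed_split",
    "confusion_counts",
    "compute_metrics",
    "roc_auc",
    "aggregate_folds",
    "case_level_predict",
]

POSITIVE = "GBM"
NEGATIVE = "MET"
LABELS = (POSITIVE, NEGATIVE)


@dataclass
class FoldSplit:
    """A stratified case-level partition for k-fold cross-validation."""

    k: int
    folds: list[list[str]]
    seed: int

    def train_test(self, fold: int) -> tuple[list[str], list[str]]:
        test = self.folds[fold]
        train = [c for i, f in enumerate(self.folds) if i != fold for c in f]
        return train, test


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float  # NaN when TP+FN == 0
    specificity: float  # NaN when TN+FP == 0
    auc: float | None
    n: int
    level: str = "case"  # "case" or "slice"
    counts: ConfusionCounts | None = field(default=None, repr=False)


def _case_table(manifest) -> pd.DataFrame:
    """Unique (case_id, class_label) rows from a manifest-like input."""
    if isinstance(manifest, pd.DataFrame):
        df = manifest[["case_id", "class_label"]].drop_duplicates()
    else:  # iterable of (case_id, class_label) or objects with those attrs
        rows = []
        for item in manifest:
            if isinstance(item, tuple):
                rows.append(item)
            else:
                rows.append((item.case_id, item.class_label))
        df = pd.DataFrame(rows, columns=["case_id", "class_label"]).drop_duplicates()
    if df["case_id"].duplicated().any():
        raise InputError("a case_id appears with more than one class label")
    return df.reset_index(drop=True)


def make_folds(manifest, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified, seeded, case-disjoint k-fold partition.

    Accepts a manifest DataFrame (one row per slice or per case) or any
    iterable of ``(case_id, class_label)``; all slices of a case land in
    one fold because folding is done at case level.
    """
    cases = _case_table(manifest)
    if k < 2:
        raise InputError("k must be >= 2")
    if len(cases) < k:
        raise InputError(f"cannot split {len(cases)} cases into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        sorted(cases.loc[test_idx, "case_id"].tolist())
        for _, test_idx in skf.split(cases["case_id"], cases["class_label"])
    ]
    return FoldSplit(k=k, folds=folds, seed=seed)


def assign_fixed_split(manifest, n_train: int, seed: int = 0) -> pd.DataFrame:
    """Tag cases 'train'/'test' with a fixed train-set size (stratified).

    Returns the manifest with its ``split`` column filled; used for the
    fixed 207/44-style split mode.
    """
    cases = _case_table(manifest)
    if not 0 < n_train < len(cases):
        raise InputError(f"n_train must be in (0, {len(cases)})")
    rng = np.random.default_rng(seed)
    train_ids: set[str] = set()
    frac = n_train / len(cases)
    by_class = {
        label: rng.permutation(grp["case_id"].to_numpy())
        for label, grp in cases.groupby("class_label")
    }
    quota = {lab: int(round(len(ids) * frac)) for lab, ids in by_class.items()}
    # fix rounding drift so the train side has exactly n_train cases
    drift = n_train - sum(quota.values())
    for lab in sorted(quota, reverse=drift > 0):
        if drift == 0:
            break
        quota[lab] += 1 if drift > 0 else -1
        drift += -1 if drift > 0 else 1
    for lab, ids in by_class.items():
        train_ids.update(ids[: quota[lab]])
    if isinstance(manifest, pd.DataFrame):
        out = manifest.copy()
        out["split"] = np.where(out["case_id"].isin(train_ids), "train", "test")
        return out
    out = cases.copy()
    out["split"] = np.where(out["case_id"].isin(train_ids), "train", "test")
    return out


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with GBM as the positive class."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise InputError("y_true and y_pred lengths differ")
    cc = ConfusionCounts()
    for t, p in zip(y_true, y_pred):
        if t not in LABELS or p not in LABELS:
            raise InputError(f"labels must be in {LABELS}, got ({t!r}, {p!r})")
        if t == POSITIVE:
            if p == POSITIVE:
                cc.tp += 1
            else:
                cc.fn += 1
        else:
            if p == NEGATIVE:
                cc.tn += 1
            else:
                cc.fp += 1
    return cc


def compute_metrics(
    cc: ConfusionCounts, auc: float | None = None, level: str = "case"
) -> MetricsReport:
    """Accuracy / sensitivity / specificity from confusion counts."""
    if cc.total == 0:
        raise InputError("cannot compute metrics over zero samples")
    accuracy = (cc.tp + cc.tn) / cc.total
    if cc.tp + cc.fn == 0:
        warnings.warn("no positive samples: sensitivity undefined", stacklevel=2)
        sensitivity = float("nan")
    else:
        sensitivity = cc.tp / (cc.tp + cc.fn)
    if cc.tn + cc.fp == 0:
        warnings.warn("no negative samples: specificity undefined", stacklevel=2)
        specificity = float("nan")
    else:
        specificity = cc.tn / (cc.tn + cc.fp)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        n=cc.total,
        level=level,
        counts=cc,
    )


def roc_auc(scores, labels) -> float:
    """AUC of the ROC curve; scores are positive-class probabilities.

    Equals the Mann-Whitney statistic: the fraction of (positive,
    negative) pairs where the positive scores higher, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if len(scores) != len(labels):
        raise InputError("scores and labels lengths differ")
    y = np.array([1 if lab == POSITIVE else 0 for lab in labels])
    if y.min() == y.max():
        raise InputError("roc_auc needs both classes present")
    return float(roc_auc_score(y, scores))


def aggregate_folds(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Arithmetic mean and population variance of each metric over folds."""
    if not reports:
        raise InputError("aggregate_folds needs at least one report")
    out: dict[str, dict[str, float]] = {}
    for name in ("accuracy", "sensitivity", "specificity", "auc"):
        values = [getattr(r, name) for r in reports]
        values = [v for v in values if v is not None and not np.isnan(v)]
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        out[name] = {
            "mean": float(arr.mean()),
            "variance": float(arr.var()),  # population variance (/n)
            "n_folds": len(arr),
        }
    return out


def case_level_predict(slice_probs, threshold: float = 0.5) -> str:
    """Majority vote over a case's thresholded slice probabilities.

    ``slice_probs`` are positive-class (GBM) probabilities for the case's
    slices; an odd slice count guarantees no ties.
    """
    probs = np.asarray(slice_probs, dtype=float)
    votes = int((probs >= threshold).sum())
    return POSITIVE if votes * 2 > probs.size else NEGATIVE
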