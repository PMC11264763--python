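"""Evaluation protocol: one-vs-rest confusion counts, the five summary
metrics (ACC, TPR, PPV, SPC, DSC), stratified group-aware 10-fold
cross-validation, a 40% holdout split, and one-vs-rest ROC/AUC.

Folds are stratified by label and grouped by parent image / patient id so
ROIs from one parent never straddle a train/test boundary.  Zero-denominator
metrics are defined as 0 with a logged warning.  DSC = 2TP/(2TP+FP+FN) is
the harmonic mean of PPV and TPR whenever both are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, train_test_split

from .fixtures_io import FeatureTable, ParameterError


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    per_class: dict
    macro: dict
    overall_accuracy: float
    per_fold: list = field(default_factory=list)
    auc: dict | None = None
    fold_assignments: list | None = None


METRIC_NAMES = ("ACC", "TPR", "PPV", "SPC", "DSC")


def confusion(y_true, y_pred, codebook) -> dict:
    """One-vs-rest TP/TN/FP/FN per class."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ParameterError("label sequences differ in length")
    for lab in np.concatenate([y_true, y_pred]):
        if lab not in codebook:
            raise ParameterError(f"label {lab!r} outside codebook")
    out = {}
    for cls in codebook:
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        tn = int(np.sum((y_true != cls) & (y_pred != cls)))
        out[cls] = ConfusionCounts(tp, tn, fp, fn)
    return out


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {name}; defining the metric as 0")
        return 0.0
    return num / den


def metrics(counts: dict) -> MetricsReport:
    """ACC, TPR, PPV, SPC and DSC per class plus the macro average."""
    per_class = {}
    n_total = 0
    n_correct_weight = 0.0
    for cls, c in counts.items():
        per_class[cls] = {
            "ACC": _safe_div(c.TP + c.TN, c.n, "ACC"),
            "TPR": _safe_div(c.TP, c.TP + c.FN, "TPR"),
            "PPV": _safe_div(c.TP, c.TP + c.FP, "PPV"),
            "SPC": _safe_div(c.TN, c.TN + c.FP, "SPC"),
            "DSC": _safe_div(2 * c.TP, 2 * c.TP + c.FP + c.FN, "DSC"),
        }
        n_total += c.TP + c.FN
        n_correct_weight += c.TP
    macro = {m: float(np.mean([per_class[c][m] for c in per_class]))
             for m in METRIC_NAMES}
    overall = _safe_div(n_correct_weight, n_total, "overall accuracy")
    return MetricsReport(per_class=per_class, macro=macro,
                         overall_accuracy=overall)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _table_parts(data: FeatureTable):
    if data.labels is None:
        raise ParameterError("labeled data required")
    y = np.asarray(data.labels)
    groups = np.asarray(data.groups) if data.groups is not None \
        else np.arange(len(y))
    return data.values, y, groups


def _subset(data: FeatureTable, idx) -> FeatureTable:
    return FeatureTable(
        data.values[idx], list(data.column_names),
        labels=[data.labels[i] for i in idx],
        groups=[data.groups[i] for i in idx] if data.groups is not None else None,
    )


def kfold_cv(model_factory, data: FeatureTable, k: int = 10,
             seed: int = 0, scores: bool = True) -> MetricsReport:
    """Stratified, group-aware k-fold cross-validation of a full pipeline.

    ``model_factory(train_table)`` must return a fitted object with
    ``predict(values) -> labels`` and optionally
    ``predict_scores(values) -> (n, n_classes)`` for AUC.  The factory is
    called fresh inside every fold, so scaling / reduction / classifier fits
    never see test rows.  Deterministic for a fixed seed.
    """
    X, y, groups = _table_parts(data)
    codebook = sorted(np.unique(y).tolist())
    if k > min(np.bincount(np.unique(y, return_inverse=True)[1])):
        raise ParameterError("k exceeds the smallest class count")
    skf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=object)
    score_rows = np.full((len(y), len(codebook)), np.nan)
    fold_of = np.empty(len(y), dtype=int)
    per_fold = []
    for f, (tr, te) in enumerate(skf.split(X, y, groups)):
        model = model_factory(_subset(data, tr))
        pred = np.asarray(model.predict(X[te]))
        y_pred[te] = pred
        fold_of[te] = f
        if scores and hasattr(model, "predict_scores"):
            score_rows[te] = model.predict_scores(X[te])
        fold_rep = metrics(confusion(y[te], pred, codebook))
        per_fold.append(fold_rep.macro | {"overall_accuracy": fold_rep.overall_accuracy})
    report = metrics(confusion(y, y_pred.astype(y.dtype), codebook))
    report.per_fold = per_fold
    report.fold_assignments = fold_of.tolist()
    if scores and not np.isnan(score_rows).any():
        report.auc = roc_auc(score_rows, y, codebook)
    return report


def holdout_split(data: FeatureTable, test_fraction: float = 0.40,
                  seed: int = 0) -> tuple:
    """Stratified, group-integral train/test split.

    With singleton groups this is a plain stratified split with
    ``round(test_fraction * n)`` test rows; otherwise whole groups are
    assigned per label stratum until the stratum's test quota is met.
    """
    X, y, groups = _table_parts(data)
    n = len(y)
    idx = np.arange(n)
    singleton = len(np.unique(groups)) == n
    if singleton:
        tr, te = train_test_split(idx, test_size=test_fraction,
                                  random_state=seed, stratify=y)
    else:
        rng = np.random.default_rng(seed)
        te_mask = np.zeros(n, dtype=bool)
        for cls in np.unique(y):
            cls_groups = np.unique(groups[y == cls])
            rng.shuffle(cls_groups)
            quota = round(test_fraction * np.sum(y == cls))
            taken = 0
            for g in cls_groups:
                if taken >= quota:
                    break
                sel = groups == g
                te_mask |= sel
                taken += int(np.sum(sel & (y == cls)))
        te = idx[te_mask]
        tr = idx[~te_mask]
    return _subset(data, np.sort(tr)), _subset(data, np.sort(te))


def roc_auc(scores, y_true, codebook) -> dict:
    """One-vs-rest trapezoidal AUC per class (midrank tie handling)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ParameterError("AUC undefined for single-class truth")
    out = {}
    for c, cls in enumerate(codebook):
        pos = (y_true == cls).astype(int)
        if pos.min() == pos.max():
            raise ParameterError(f"AUC undefined for class {cls!r}: "
                                 "only one outcome present")
        out[cls] = float(roc_auc_score(pos, scores[:, c]))
    return out
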