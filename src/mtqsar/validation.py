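"""Classification metrics, ROC/AUC, cross-validation and the applicability domain.

Metrics follow the standard binary-classification definitions with the
active class (+1) as the positive class.  Rates are reported in percent,
matching the field's reporting convention; the F-measure is the active-class
F1 in [0, 1] and MCC is the Matthews correlation coefficient in [−1, 1]
(defined as 0 when any confusion-matrix marginal is zero, never NaN).

The applicability domain uses the standardisation approach: with training
descriptor means μ_k and standard deviations σ_k, a query's standardised
absolute deviations are s_ki = |x_ki − μ_k| / σ_k and the query is

* inside  the domain when max_k s_ki ≤ 3,
* outside when min_k s_ki > 3,
* otherwise judged by s* = mean_k(s_ki) + 1.28 · sd_k(s_ki) (sample SD):
  outside iff s* > 3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .boxjenkins import ACTIVE, INACTIVE


class ValidationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt, yp = np.asarray(y_true), np.asarray(y_pred)
        return cls(
            tp=int(np.sum((yt == ACTIVE) & (yp == ACTIVE))),
            fn=int(np.sum((yt == ACTIVE) & (yp == INACTIVE))),
            tn=int(np.sum((yt == INACTIVE) & (yp == INACTIVE))),
            fp=int(np.sum((yt == INACTIVE) & (yp == ACTIVE))),
        )


@dataclass
class ClassificationReport:
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    f_measure: float  # active-class F1 in [0, 1]
    mcc: float
    auc: float | None = None
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        d = {
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.counts is not None:
            d["counts"] = self.counts.__dict__
        return d

    def __str__(self) -> str:
        lines = [
            f"sensitivity  {self.sensitivity:6.2f} %",
            f"specificity  {self.specificity:6.2f} %",
            f"accuracy     {self.accuracy:6.2f} %",
            f"F-measure    {self.f_measure:6.3f}",
            f"MCC          {self.mcc:6.3f}",
        ]
        if self.auc is not None:
            lines.append(f"AUC          {self.auc:6.3f}")
        return "\n".join(lines)


def classification_report(c: ConfusionCounts, auc: float | None = None) -> ClassificationReport:
    """Derived rates from confusion counts; requires both classes present."""
    if c.positives == 0 or c.negatives == 0:
        raise ValidationError("sensitivity/specificity undefined with an empty class")
    sens = 100.0 * c.tp / c.positives
    spec = 100.0 * c.tn / c.negatives
    acc = 100.0 * (c.tp + c.tn) / c.total
    if c.tp == 0:
        f1 = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
        recall = c.tp / c.positives
        f1 = 2 * precision * recall / (precision + recall)
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return ClassificationReport(sens, spec, acc, f1, mcc, auc, c)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve; ties count ½."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == ACTIVE))
    n_neg = int(np.sum(y == INACTIVE))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes")
    ranks = rankdata(s)  # average ranks → ties contribute 1/2
    u = ranks[y == ACTIVE].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# -- cross-validation ----------------------------------------------------------


def cross_validate(
    learner: Callable[[pd.DataFrame, np.ndarray], tuple[Callable, Callable]],
    X: pd.DataFrame,
    y: Sequence[int],
    folds: int = 10,
    seed: int | None = None,
) -> ClassificationReport:
    """Stratified k-fold CV; out-of-fold predictions pooled into one report.

    ``learner(X_train, y_train)`` must return ``(predict, score)`` callables
    mapping a held-out frame to ±1 labels and real decision scores.
    """
    y = np.asarray(y)
    if len(y) < folds:
        raise ValidationError(f"n={len(y)} < folds={folds}")
    class_counts = pd.Series(y).value_counts()
    if class_counts.min() < folds:
        # leave-one-out style folds cannot stratify the minority class further
        folds = int(class_counts.min())
        if folds < 2:
            raise ValidationError("a class is too small to cross-validate")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=None if seed is None else int(seed) % (2**32))
    pred = np.empty(len(y), dtype=int)
    score = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X.values, y):
        predict_fn, score_fn = learner(X.iloc[train_idx], y[train_idx])
        pred[test_idx] = predict_fn(X.iloc[test_idx])
        score[test_idx] = score_fn(X.iloc[test_idx])
    counts = ConfusionCounts.from_predictions(y, pred)
    return classification_report(counts, auc=roc_auc(score, y))


def lda_learner(columns: Sequence[str] | None = None):
    """Learner factory for :func:`cross_validate` backed by :func:`modeling.fit_lda`."""
    from .modeling import fit_lda

    def fit(X_train: pd.DataFrame, y_train) -> tuple[Callable, Callable]:
        sub = X_train[list(columns)] if columns is not None else X_train
        model = fit_lda(sub, y_train)
        cols = model.descriptor_names
        return (lambda X: model.classify(X[cols])), (lambda X: model.score(X[cols]))

    return fit


def rf_learner(cfg=None):
    """Learner factory for :func:`cross_validate` backed by :func:`modeling.fit_rf`."""
    from .modeling import fit_rf

    def fit(X_train: pd.DataFrame, y_train) -> tuple[Callable, Callable]:
        model = fit_rf(X_train, y_train, cfg)
        return model.predict, model.decision_scores

    return fit


# -- applicability domain ------------------------------------------------------


@dataclass
class ADResult:
    record_id: str
    max_s: float
    min_s: float
    s_star: float | None
    inside: bool


def applicability_domain(
    X_train: pd.DataFrame,
    X_query: pd.DataFrame,
    threshold: float = 3.0,
    quantile_factor: float = 1.28,
) -> list[ADResult]:
    """Standardisation-approach applicability domain flags for each query row.

    Descriptors with zero training SD carry no domain information and are
    excluded with a warning.
    """
    missing = [c for c in X_train.columns if c not in X_query.columns]
    if missing:
        raise ValidationError(f"query frame missing descriptors: {missing[:5]}")
    cols = list(X_train.columns)
    mu = X_train[cols].mean(axis=0).values
    sd = X_train[cols].std(axis=0, ddof=1).values
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance descriptor(s) from the applicability domain"
        )
        if not keep.any():
            raise ValidationError("no descriptor with positive training SD")
    mu, sd = mu[keep], sd[keep]
    used = [c for c, k in zip(cols, keep) if k]
    out: list[ADResult] = []
    for rid, row in X_query[used].iterrows():
        s = np.abs(row.values - mu) / sd
        s_star = None
        if s.max() <= threshold:
            inside = True
        elif s.min() > threshold:
            inside = False
        else:
            s_star = float(s.mean() + quantile_factor * np.std(s, ddof=1))
            inside = s_star <= threshold
        out.append(ADResult(str(rid), float(s.max()), float(s.min()), s_star, inside))
    return out
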