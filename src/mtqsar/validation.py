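"""Model validation: confusion statistics, ROC/AUC, cross-validation and
Y-randomization.

The metric battery mirrors standard classification QSAR reporting:
accuracy, sensitivity, specificity and precision as percentages,
F-measure and Matthews correlation coefficient (MCC) as fractions.  The
AUC uses the rank (Mann-Whitney) formulation with ties counted half.
Y-randomization refits the discriminant on label-scrambled data — many
times — to show the real model's Wilks lambda is far below what chance
models achieve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classifiers import _check_binary, fit_lda
from .feature_selection import wilks_lambda

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "YRandResult",
    "confusion",
    "metrics",
    "roc_auc",
    "cross_validated_scores",
    "y_randomization",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Derived statistics; percentages on the 0-100 scale, F and MCC as fractions.

    A metric whose denominator vanishes is NaN and listed in ``undefined``
    rather than silently zeroed.
    """

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    mcc: float
    auc: Optional[float] = None
    undefined: list[str] = field(default_factory=list)

    def rounded(self, ndigits_pct: int = 2, ndigits_frac: int = 4) -> dict:
        """Display form: percentages to 2 dp, fractions to 4 dp."""
        out = {
            "accuracy": round(self.accuracy, ndigits_pct),
            "sensitivity": round(self.sensitivity, ndigits_pct),
            "specificity": round(self.specificity, ndigits_pct),
            "precision": round(self.precision, ndigits_pct),
            "f_measure": round(self.f_measure, ndigits_frac),
            "mcc": round(self.mcc, ndigits_frac),
        }
        if self.auc is not None:
            out["auc"] = round(self.auc, ndigits_frac)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": self.counts.__dict__,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "precision_pct": self.precision,
            "f_measure": self.f_measure,
            "mcc": self.mcc,
            "auc": self.auc,
            "undefined": self.undefined,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally a binary confusion matrix with active as the positive class."""
    yt = _check_label_array(y_true)
    yp = _check_label_array(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _check_label_array(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        bad = set(np.unique(y)) - {"active", "inactive"}
        if bad:
            raise ValueError(f"non-binary labels: {sorted(bad)}")
        return (y == "active").astype(int)
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    return y


def metrics(counts: ConfusionCounts, auc: Optional[float] = None) -> MetricsReport:
    """Derive the full statistic battery from confusion counts.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), accuracy = (TP+TN)/total (all as percent);
    F = 2*prec*sens/(prec+sens) on fractions;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    acc = (tp + tn) / counts.total
    if math.isnan(sens) or math.isnan(prec) or (prec + sens) == 0:
        undefined.append("f_measure")
        f = math.nan
    else:
        f = 2 * prec * sens / (prec + sens)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        counts=counts,
        accuracy=acc * 100,
        sensitivity=sens * 100,
        specificity=spec * 100,
        precision=prec * 100,
        f_measure=f,
        mcc=mcc,
        auc=auc,
        undefined=undefined,
    )


def roc_auc(scores, y_true) -> tuple[float, pd.DataFrame]:
    """AUC by the Mann-Whitney rank formulation, plus the ROC curve.

    Ties count half.  The curve is tabulated at every distinct score
    threshold as (threshold, FPR, TPR), from the strictest threshold to
    the most permissive.
    """
    yt = _check_label_array(y_true)
    s = np.asarray(scores, dtype=float)
    if s.shape != yt.shape:
        raise ValueError("scores and labels length mismatch")
    n_pos = int(yt.sum())
    n_neg = int(yt.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = rankdata(s)  # average ranks: ties count half in the U statistic
    auc = (ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], yt[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    curve = pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s_sorted[distinct]],
            "fpr": np.r_[0.0, fps / n_neg],
            "tpr": np.r_[0.0, tps / n_pos],
        }
    )
    return float(auc), curve


def cross_validated_scores(
    X,
    y,
    fit: Callable,
    score: Callable,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Stratified k-fold out-of-fold scores, one per sample, in input order.

    ``fit(X_train, y_train) -> model`` and ``score(model, X_test) -> scores``
    define the model family; each sample is scored exactly once by a model
    that never saw it.  Deterministic given ``seed``.
    """
    yb = _check_binary(y)
    counts = np.bincount(yb)
    if k < 2 or k > counts.min():
        raise ValueError(
            f"infeasible fold count k={k} for class sizes {counts.tolist()}"
        )
    if isinstance(X, pd.DataFrame):
        take = lambda idx: X.iloc[idx]
    else:
        X = np.asarray(X, dtype=float)
        take = lambda idx: X[idx]
    out = np.full(yb.shape, np.nan)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(np.zeros_like(yb), yb):
        model = fit(take(train_idx), yb[train_idx])
        out[test_idx] = np.asarray(score(model, take(test_idx)), dtype=float)
    assert not np.isnan(out).any()
    return out


@dataclass
class YRandResult:
    lambda_original: float
    lambda_randomized: list[float]
    seed: int

    @property
    def mean_lambda_randomized(self) -> float:
        return float(np.mean(self.lambda_randomized))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "lambda_original": self.lambda_original,
                    "lambda_randomized": self.lambda_randomized,
                    "mean_lambda_randomized": self.mean_lambda_randomized,
                    "seed": self.seed,
                },
                indent=2,
            )
        )


def y_randomization(
    X, y, subset: Optional[Sequence[str]] = None, n_perm: int = 50, seed: int = 0
) -> YRandResult:
    """Label-scrambling robustness test on a fixed descriptor subset.

    The response is shuffled ``n_perm`` times; after each shuffle the
    discriminant is refitted on the *same* subset and its Wilks lambda
    recorded.  A real model's lambda should sit far below the scrambled
    mean.  Selection is intentionally not rerun per permutation, so the
    test isolates chance correlation from selection variance.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    yb = _check_binary(y)
    lam0 = fit_lda(X, yb, subset).wilks_lambda_train
    rng = np.random.default_rng(seed)
    lams: list[float] = []
    for _ in range(n_perm):
        y_shuffled = rng.permutation(yb)
        try:
            lam = fit_lda(X, y_shuffled, subset).wilks_lambda_train
        except ValueError:
            lam = 1.0  # a degenerate scrambled fit separates nothing
        lams.append(float(lam))
    return YRandResult(lambda_original=float(lam0), lambda_randomized=lams, seed=seed)
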