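"""Two-class discriminant and random-forest models over deviation features.

The linear model is a Fisher discriminant fitted on z-scored features:
coefficients are therefore *standardized* coefficients, comparable across
descriptors regardless of raw scale, and predictions are invariant to any
affine rescaling of the raw inputs.  The score is centred so that 0 is
the decision boundary (midpoint of the class mean scores, i.e. equal
priors); score > 0 predicts active.

The non-linear counterpart is a bagged CART ensemble (random forest,
Gini impurity) with majority voting; a tied vote predicts inactive so
that screening errs conservative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .feature_selection import wilks_lambda

__all__ = [
    "DiscriminantModel",
    "ForestConfig",
    "ForestModel",
    "fit_lda",
    "lda_predict",
    "fit_rf",
    "rf_predict",
]

_LABELS = np.array(["inactive", "active"])


def _check_binary(y) -> np.ndarray:
    """Map labels to 0/1 ints with active = 1."""
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        known = set(np.unique(y)) - {"active", "inactive"}
        if known:
            raise ValueError(f"unknown class labels: {sorted(known)}")
        y = (y == "active").astype(int)
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0/1 or active/inactive)")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    return y


def _columns(X, names: Sequence[str]) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor columns: {missing}")
        return X[list(names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(names):
        raise ValueError("feature matrix width does not match model descriptors")
    return X


@dataclass
class DiscriminantModel:
    """Fitted two-class Fisher discriminant on z-scored descriptors.

    ``coefficients`` act on z-scores; ``raw_coefficients`` (derived) act on
    the raw descriptor scale.  ``score = coefficients . z + intercept`` and
    the decision rule is ``score > threshold`` (threshold 0 after centring).
    """

    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    wilks_lambda_train: float
    threshold: float = 0.0
    training_confusion: Optional[dict] = None

    @property
    def raw_coefficients(self) -> np.ndarray:
        return self.coefficients / self.feature_sds

    @property
    def raw_intercept(self) -> float:
        return float(self.intercept - np.sum(self.coefficients * self.feature_means / self.feature_sds))

    def scores(self, X) -> np.ndarray:
        M = _columns(X, self.descriptor_names)
        Z = (M - self.feature_means) / self.feature_sds
        return Z @ self.coefficients + self.intercept

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "descriptor_names": self.descriptor_names,
                    "coefficients": self.coefficients.tolist(),
                    "intercept": self.intercept,
                    "feature_means": self.feature_means.tolist(),
                    "feature_sds": self.feature_sds.tolist(),
                    "wilks_lambda_train": self.wilks_lambda_train,
                    "threshold": self.threshold,
                    "raw_coefficients": self.raw_coefficients.tolist(),
                    "raw_intercept": self.raw_intercept,
                    "training_confusion": self.training_confusion,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscriminantModel":
        d = json.loads(Path(path).read_text())
        return cls(
            descriptor_names=d["descriptor_names"],
            coefficients=np.array(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            feature_means=np.array(d["feature_means"], dtype=float),
            feature_sds=np.array(d["feature_sds"], dtype=float),
            wilks_lambda_train=float(d["wilks_lambda_train"]),
            threshold=float(d["threshold"]),
            training_confusion=d.get("training_confusion"),
        )


def fit_lda(X, y, subset: Optional[Sequence[str]] = None, priors: str = "equal") -> DiscriminantModel:
    """Fit the two-class Fisher discriminant on a descriptor subset.

    Columns are z-scored by training mean/sd; the discriminant direction is
    ``pooled_cov^{-1} (mu_active - mu_inactive)`` in z-space.  With
    ``priors="equal"`` (default) the boundary sits at the midpoint of the
    two class mean scores; ``priors="prevalence"`` shifts it by the log
    class-frequency ratio.
    """
    if isinstance(X, pd.DataFrame):
        names = list(subset) if subset is not None else list(X.columns)
        M = _columns(X, names)
    else:
        M = np.asarray(X, dtype=float)
        idx = [int(s) for s in subset] if subset is not None else range(M.shape[1])
        M = M[:, list(idx)]
        names = [str(i) for i in idx]
    yb = _check_binary(y)

    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    zero_var = [names[i] for i in np.flatnonzero(sds == 0)]
    if zero_var:
        raise ValueError(f"zero-variance descriptor columns: {zero_var}")
    Z = (M - means) / sds

    mu0 = Z[yb == 0].mean(axis=0)
    mu1 = Z[yb == 1].mean(axis=0)
    n0, n1 = int((yb == 0).sum()), int((yb == 1).sum())
    S0 = np.cov(Z[yb == 0], rowvar=False, ddof=1) if n0 > 1 else np.zeros((Z.shape[1],) * 2)
    S1 = np.cov(Z[yb == 1], rowvar=False, ddof=1) if n1 > 1 else np.zeros((Z.shape[1],) * 2)
    Sp = np.atleast_2d(((n0 - 1) * S0 + (n1 - 1) * S1) / max(n0 + n1 - 2, 1))
    try:
        w = np.linalg.solve(Sp, mu1 - mu0)
    except np.linalg.LinAlgError:
        raise ValueError("singular pooled covariance; drop collinear descriptors") from None

    midpoint = 0.5 * (Z[yb == 1] @ w).mean() + 0.5 * (Z[yb == 0] @ w).mean()
    intercept = -float(midpoint)
    if priors == "prevalence":
        intercept += float(np.log(n1 / n0))
    elif priors != "equal":
        raise ValueError("priors must be 'equal' or 'prevalence'")

    model = DiscriminantModel(
        descriptor_names=names,
        coefficients=w,
        intercept=intercept,
        feature_means=means,
        feature_sds=sds,
        wilks_lambda_train=wilks_lambda(M, yb),
    )
    scores = Z @ w + intercept
    pred = scores > model.threshold
    model.training_confusion = {
        "tp": int(np.sum(pred & (yb == 1))),
        "fp": int(np.sum(pred & (yb == 0))),
        "tn": int(np.sum(~pred & (yb == 0))),
        "fn": int(np.sum(~pred & (yb == 1))),
    }
    return model


def lda_predict(model: DiscriminantModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Scores and class labels for new data; active iff score > threshold."""
    scores = model.scores(X)
    labels = _LABELS[(scores > model.threshold).astype(int)]
    return scores, labels


@dataclass
class ForestConfig:
    n_trees: int = 100
    max_depth: Optional[int] = None
    features_per_split: str = "sqrt"
    bootstrap: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ForestModel:
    """Random forest plus the metadata needed to predict safely."""

    estimator: RandomForestClassifier
    descriptor_names: list[str]
    config: ForestConfig = field(default_factory=ForestConfig)

    def save(self, path: str | Path) -> None:
        # native persistent form plus a JSON sidecar of config + seed
        import joblib

        path = Path(path)
        joblib.dump(self.estimator, path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"descriptor_names": self.descriptor_names, "config": self.config.__dict__},
                indent=2,
            )
        )


def fit_rf(X, y, config: Optional[ForestConfig] = None) -> ForestModel:
    """Fit a bagged Gini CART ensemble; deterministic given ``config.seed``."""
    config = config or ForestConfig()
    config.validate()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = [str(i) for i in range(M.shape[1])]
    yb = _check_binary(y)
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=config.features_per_split,
        criterion="gini",
        bootstrap=config.bootstrap,
        random_state=config.seed,
    )
    est.fit(M, yb)
    return ForestModel(estimator=est, descriptor_names=names, config=config)


def rf_predict(model: ForestModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-tree vote fractions and majority labels (tie -> inactive).

    The vote fraction is the share of trees predicting active, tallied
    tree by tree (not the averaged leaf probability), so it matches a
    manual per-tree count exactly.
    """
    M = _columns(X, model.descriptor_names)
    votes = np.stack([tree.predict(M) for tree in model.estimator.estimators_])
    fractions = (votes == 1).mean(axis=0)
    labels = _LABELS[(fractions > 0.5).astype(int)]
    return fractions, labels
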