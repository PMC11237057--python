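"""Standardization-approach applicability domain (AD).

Each query descriptor is standardized against the training distribution,
s_k = |x_k - mean_k| / sd_k, and three rules decide membership:

* every s_k <= 3            -> inside  (``all_within``)
* every s_k  > 3            -> outside (``all_beyond``)
* otherwise the upper-tail statistic S = mean(s) + 1.28 * sd(s) is
  compared with 3            -> inside iff S <= 3 (``tail_test``)

The 3-sigma threshold and the 1.28 tail multiplier (the 90th-percentile
normal quantile) are the method's conventional constants; both are
configurable.  The AD lives in the fitted model's selected descriptor
space, where predictions are actually made.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ADModel", "ADVerdict", "ad_fit", "ad_assess", "ad_assess_batch"]


@dataclass
class ADModel:
    descriptor_names: list[str]
    means: np.ndarray
    sds: np.ndarray  # sample (n-1) standard deviations
    threshold: float = 3.0
    tail_multiplier: float = 1.28

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "descriptor_names": self.descriptor_names,
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "threshold": self.threshold,
                    "tail_multiplier": self.tail_multiplier,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ADModel":
        d = json.loads(Path(path).read_text())
        return cls(
            descriptor_names=d["descriptor_names"],
            means=np.array(d["means"], dtype=float),
            sds=np.array(d["sds"], dtype=float),
            threshold=float(d["threshold"]),
            tail_multiplier=float(d["tail_multiplier"]),
        )


@dataclass
class ADVerdict:
    compound_id: str
    s_values: np.ndarray
    rule: str  # all_within | all_beyond | tail_test
    inside: bool
    tail_statistic: float | None = None

    @property
    def max_s(self) -> float:
        return float(self.s_values.max())


def ad_fit(
    X_train,
    threshold: float = 3.0,
    tail_multiplier: float = 1.28,
) -> ADModel:
    """Store per-descriptor training mean and sample sd.

    ``X_train`` holds the training rows over the model's selected
    descriptors.  A zero-variance descriptor is rejected by name, since
    its standardized deviate is undefined.
    """
    if isinstance(X_train, pd.DataFrame):
        names = list(X_train.columns)
        M = X_train.to_numpy(dtype=float)
    else:
        M = np.asarray(X_train, dtype=float)
        names = [str(i) for i in range(M.shape[1])]
    if M.shape[0] < 2:
        raise ValueError("AD fitting needs at least two training compounds")
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    zero = [names[i] for i in np.flatnonzero(sds == 0)]
    if zero:
        raise ValueError(f"zero-variance descriptors cannot define an AD: {zero}")
    return ADModel(
        descriptor_names=names,
        means=means,
        sds=sds,
        threshold=threshold,
        tail_multiplier=tail_multiplier,
    )


def ad_assess(model: ADModel, x, compound_id: str = "") -> ADVerdict:
    """Apply the three standardization rules to one query vector."""
    if isinstance(x, pd.Series):
        missing = [n for n in model.descriptor_names if n not in x.index]
        if missing:
            raise KeyError(f"query lacks descriptors: {missing}")
        v = x[model.descriptor_names].to_numpy(dtype=float)
    else:
        v = np.asarray(x, dtype=float)
        if v.shape != (len(model.descriptor_names),):
            raise ValueError("query vector length does not match AD descriptors")
    s = np.abs(v - model.means) / model.sds
    if s.max() <= model.threshold:
        return ADVerdict(compound_id, s, "all_within", True)
    if s.min() > model.threshold:
        return ADVerdict(compound_id, s, "all_beyond", False)
    tail = float(s.mean() + model.tail_multiplier * s.std(ddof=1))
    return ADVerdict(compound_id, s, "tail_test", tail <= model.threshold, tail_statistic=tail)


def ad_assess_batch(model: ADModel, X) -> pd.DataFrame:
    """Verdicts for every row of a query table (id, rule, inside, max_s, S_new)."""
    if isinstance(X, pd.DataFrame):
        rows = [(str(idx), X.loc[idx]) for idx in X.index]
    else:
        X = np.asarray(X, dtype=float)
        rows = [(str(i), X[i]) for i in range(X.shape[0])]
    records = []
    for cid, x in rows:
        v = ad_assess(model, x, cid)
        records.append(
            {
                "compound_id": cid,
                "rule": v.rule,
                "inside": v.inside,
                "max_s": v.max_s,
                "S_new": v.tail_statistic,
            }
        )
    return pd.DataFrame(records)
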