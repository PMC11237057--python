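"""Consensus virtual screening of a designed-compound library.

A library compound is selected as a candidate dual inhibitor only if,
under every evaluated experimental condition,

* it falls inside the applicability domain of the models, and
* both the discriminant and the random-forest model call it active for
  the ACE condition(s) *and* the NEP condition(s).

The conditions applied to a library (which carries no measured activity)
are synthesized per target, with standard type and assay type fixed to
supplied values — by convention the majority values of the training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .applicability_domain import ADModel, ad_assess
from .box_jenkins import ConditionAverages, deviation_transform_library
from .classifiers import DiscriminantModel, ForestModel, lda_predict, rf_predict
from .curation import AssayType, CompoundRecord, ConditionVector, StandardType, Target

__all__ = ["ScreeningDecision", "screen_library", "default_conditions", "decisions_to_frame"]


@dataclass
class ScreeningDecision:
    compound_id: str
    per_condition: dict = field(default_factory=dict)  # str(condition) -> outcome dict
    selected: bool = False
    reasons: list[str] = field(default_factory=list)


def default_conditions(
    records: Sequence[CompoundRecord],
    targets: Sequence[Target] = (Target.ACE, Target.NEP),
) -> list[ConditionVector]:
    """One condition per target with the majority training st/at values."""
    st_counts: dict[str, int] = {}
    at_counts: dict[str, int] = {}
    for r in records:
        st_counts[r.standard_type.value] = st_counts.get(r.standard_type.value, 0) + 1
        at_counts[r.assay_type.value] = at_counts.get(r.assay_type.value, 0) + 1
    st = StandardType(max(st_counts, key=lambda k: st_counts[k]))
    at = AssayType(max(at_counts, key=lambda k: at_counts[k]))
    return [ConditionVector(t, st, at) for t in targets]


def screen_library(
    library: pd.DataFrame,
    averages: ConditionAverages,
    lda_model: DiscriminantModel,
    rf_model: ForestModel,
    ad_model: ADModel,
    conditions: Sequence[ConditionVector],
    require_both_targets: bool = True,
) -> list[ScreeningDecision]:
    """Apply the consensus rule to every library compound.

    ``library`` is a raw descriptor matrix (compound id index) in the
    training descriptor space; each condition is evaluated with the
    *training* condition averages, the AD model and both classifiers.
    With ``require_both_targets`` every target among the conditions must
    be predicted active; otherwise one passing target suffices.
    """
    if not conditions:
        raise ValueError("at least one condition must be evaluated")
    decisions = {
        str(cid): ScreeningDecision(compound_id=str(cid)) for cid in library.index
    }
    per_target_active: dict[str, dict[str, bool]] = {
        str(cid): {} for cid in library.index
    }
    for condition in conditions:
        features = deviation_transform_library(library, averages, condition)
        ad_features = features[ad_model.descriptor_names]
        lda_scores, lda_labels = lda_predict(lda_model, features)
        rf_fracs, rf_labels = rf_predict(rf_model, features)
        for i, cid in enumerate(features.index):
            cid = str(cid)
            verdict = ad_assess(ad_model, ad_features.iloc[i], cid)
            outcome = {
                "lda_label": str(lda_labels[i]),
                "lda_score": float(lda_scores[i]),
                "rf_label": str(rf_labels[i]),
                "rf_vote_fraction": float(rf_fracs[i]),
                "inside_ad": bool(verdict.inside),
                "ad_rule": verdict.rule,
            }
            decisions[cid].per_condition[str(condition)] = outcome
            target = condition.tn.value
            both_active = lda_labels[i] == "active" and rf_labels[i] == "active"
            prev = per_target_active[cid].get(target, True)
            per_target_active[cid][target] = prev and both_active

    for cid, decision in decisions.items():
        reasons: list[str] = []
        outcomes = decision.per_condition.values()
        if not all(o["inside_ad"] for o in outcomes):
            reasons.append("outside_ad")
        for target, ok in per_target_active[cid].items():
            if not ok:
                cond_outcomes = [
                    o
                    for c, o in decision.per_condition.items()
                    if c.startswith(target)
                ]
                if any(o["lda_label"] != "active" for o in cond_outcomes):
                    reasons.append(f"lda_inactive_{target}")
                if any(o["rf_label"] != "active" for o in cond_outcomes):
                    reasons.append(f"rf_inactive_{target}")
        targets_ok = (
            all(per_target_active[cid].values())
            if require_both_targets
            else any(per_target_active[cid].values())
        )
        decision.selected = targets_ok and "outside_ad" not in reasons
        decision.reasons = reasons if reasons else ["all_pass"]
    return [decisions[str(cid)] for cid in library.index]


def decisions_to_frame(decisions: Sequence[ScreeningDecision]) -> pd.DataFrame:
    """One row per compound x condition, plus the summary ``selected`` flag."""
    rows = []
    for d in decisions:
        for cond, o in d.per_condition.items():
            rows.append(
                {
                    "compound_id": d.compound_id,
                    "condition": cond,
                    **o,
                    "selected": d.selected,
                    "reasons": ";".join(d.reasons),
                }
            )
    return pd.DataFrame(rows)


def summary_json(decisions: Sequence[ScreeningDecision], path: str | Path) -> dict:
    counts: dict[str, int] = {}
    for d in decisions:
        for reason in d.reasons:
            counts[reason] = counts.get(reason, 0) + 1
    payload = {
        "n_library": len(decisions),
        "n_selected": sum(d.selected for d in decisions),
        "reason_counts": counts,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload
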