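"""Bioactivity curation for multi-target classification datasets.

A curated record couples one measured activity (IC50 or Ki, normalised to
nM) with the experimental condition under which it was obtained: the
target enzyme (ACE or NEP), the standard type (IC50 or Ki) and the assay
type (binding ``B`` or functional ``F``).  Compounds at or below a 600 nM
cutoff are labelled active.  The module also produces the random 70/30
train/test partition used downstream.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Target",
    "StandardType",
    "AssayType",
    "ConditionVector",
    "CompoundRecord",
    "DatasetSplit",
    "CurationReport",
    "ACTIVITY_CUTOFF_NM",
    "normalize_units",
    "assign_class",
    "deduplicate",
    "curate_records",
    "split_train_test",
    "read_activity_table",
    "write_activity_table",
    "records_to_frame",
]

ACTIVITY_CUTOFF_NM = 600.0

#: exact decimal factors to nanomolar
_UNIT_TO_NM = {
    "pM": 1e-3,
    "nM": 1.0,
    "uM": 1e3,
    "µM": 1e3,
    "μM": 1e3,  # micro sign vs greek mu
    "mM": 1e6,
    "M": 1e9,
}


class Target(str, enum.Enum):
    ACE = "ACE"
    NEP = "NEP"


class StandardType(str, enum.Enum):
    IC50 = "IC50"
    KI = "Ki"


class AssayType(str, enum.Enum):
    B = "B"
    F = "F"


@dataclass(frozen=True)
class ConditionVector:
    """Experimental condition triple (target, standard type, assay type)."""

    tn: Target
    st: StandardType
    at: AssayType

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.tn.value, self.st.value, self.at.value)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.tn.value}/{self.st.value}/{self.at.value}"


@dataclass
class CompoundRecord:
    """One curated bioactivity measurement.

    ``activity_nM`` is always in nanomolar after curation; ``class_label``
    is ``"active"``, ``"inactive"`` or ``"unassigned"``.
    """

    compound_id: str
    activity_nM: float
    standard_type: StandardType
    target: Target
    assay_type: AssayType
    smiles: Optional[str] = None
    class_label: str = "unassigned"

    @property
    def condition(self) -> ConditionVector:
        return ConditionVector(self.target, self.standard_type, self.assay_type)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (
            self.compound_id,
            self.target.value,
            self.standard_type.value,
            self.assay_type.value,
        )

    @property
    def is_active(self) -> bool:
        return self.class_label == "active"


@dataclass
class CurationReport:
    """Counts of records dropped during curation, by reason."""

    n_input: int = 0
    n_retained: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    retained_ids: list[str] = field(default_factory=list)

    def add_drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_input": self.n_input,
                    "n_retained": self.n_retained,
                    "dropped": self.dropped,
                    "retained_ids": self.retained_ids,
                },
                indent=2,
            )
        )


@dataclass(frozen=True)
class DatasetSplit:
    """Random train/test partition of record keys (as opaque id strings)."""

    train_ids: frozenset
    test_ids: frozenset
    seed: int
    test_fraction: float

    def __post_init__(self) -> None:
        if self.train_ids & self.test_ids:
            raise ValueError("train and test sets overlap")


def normalize_units(value: float, unit: str) -> float:
    """Convert an activity value in ``unit`` to nanomolar.

    Accepted units: pM, nM, uM/µM, mM, M.  Raises ``ValueError`` for an
    unknown unit or a non-positive value.
    """
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"activity value must be positive and finite, got {value!r}")
    unit = unit.strip()
    try:
        factor = _UNIT_TO_NM[unit]
    except KeyError:
        raise ValueError(f"unknown activity unit {unit!r}") from None
    return float(value) * factor


def assign_class(activity_nM: float, cutoff_nM: float = ACTIVITY_CUTOFF_NM) -> str:
    """Label a compound active iff its activity is at or below the cutoff.

    The comparison is inclusive: exactly 600 nM is active.
    """
    if activity_nM <= 0:
        raise ValueError("activity must be positive (nM)")
    return "active" if activity_nM <= cutoff_nM else "inactive"


def _median_record(group: list[CompoundRecord]) -> CompoundRecord:
    # keep the record holding the (lower) median activity among duplicates:
    # stable and outlier-resistant
    ordered = sorted(group, key=lambda r: r.activity_nM)
    return ordered[(len(ordered) - 1) // 2]


def deduplicate(
    records: Sequence[CompoundRecord], report: Optional[CurationReport] = None
) -> tuple[list[CompoundRecord], CurationReport]:
    """Collapse duplicate (compound, target, standard type, assay type) rows.

    The retained duplicate is the one with the median activity.  The same
    compound measured under different conditions is *not* a duplicate.
    """
    if report is None:
        report = CurationReport(n_input=len(records))
    groups: dict[tuple, list[CompoundRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        if rec.key not in groups:
            groups[rec.key] = []
            order.append(rec.key)
        groups[rec.key].append(rec)
    kept: list[CompoundRecord] = []
    for key in order:
        group = groups[key]
        for _ in range(len(group) - 1):
            report.add_drop("duplicate")
        kept.append(_median_record(group))
    report.n_retained = len(kept)
    report.retained_ids = [r.compound_id for r in kept]
    return kept, report


def curate_records(
    table: pd.DataFrame, cutoff_nM: float = ACTIVITY_CUTOFF_NM
) -> tuple[list[CompoundRecord], CurationReport]:
    """Normalise, label and deduplicate a raw activity table.

    The table needs columns ``compound_id``, ``activity_value``,
    ``activity_unit``, ``standard_type``, ``target``, ``assay_type``
    (``smiles`` optional).  Rows missing the activity value, the unit or
    any condition field are dropped and counted in the report; dropping is
    reported, never raised.
    """
    report = CurationReport(n_input=len(table))
    records: list[CompoundRecord] = []
    for _, row in table.iterrows():
        if pd.isna(row.get("activity_value")):
            report.add_drop("missing_activity")
            continue
        if pd.isna(row.get("activity_unit")) or str(row.get("activity_unit")).strip() == "":
            report.add_drop("missing_unit")
            continue
        missing_condition = False
        for col in ("standard_type", "target", "assay_type"):
            if pd.isna(row.get(col)) or str(row.get(col)).strip() == "":
                report.add_drop(f"missing_{col}")
                missing_condition = True
                break
        if missing_condition:
            continue
        try:
            activity = normalize_units(float(row["activity_value"]), str(row["activity_unit"]))
            rec = CompoundRecord(
                compound_id=str(row["compound_id"]),
                activity_nM=activity,
                standard_type=StandardType(str(row["standard_type"])),
                target=Target(str(row["target"])),
                assay_type=AssayType(str(row["assay_type"])),
                smiles=None if pd.isna(row.get("smiles")) else str(row.get("smiles")),
            )
        except ValueError as exc:
            report.add_drop(f"invalid_value ({exc})" if "unit" not in str(exc) else "unknown_unit")
            continue
        rec.class_label = assign_class(rec.activity_nM, cutoff_nM)
        records.append(rec)
    return deduplicate(records, report)


def _record_uid(rec: CompoundRecord) -> str:
    return "|".join(rec.key)


def split_train_test(
    records: Sequence[CompoundRecord],
    test_fraction: float = 0.30,
    seed: int = 0,
    stratify: bool = False,
) -> DatasetSplit:
    """Randomly partition curated records into train and test sets.

    The test size is ``round(test_fraction * n)`` (nearest integer,
    half-to-even), which for the 715-compound study gives 501 train / 214
    test.  Plain random by default; ``stratify=True`` balances the
    active/inactive ratio across the two sets.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least two records to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    uids = [_record_uid(r) for r in records]
    if len(set(uids)) != n:
        raise ValueError("records must be deduplicated before splitting")
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    if stratify:
        test_idx: list[int] = []
        for label in ("active", "inactive"):
            idx = [i for i, r in enumerate(records) if r.class_label == label]
            k = int(round(test_fraction * len(idx)))
            perm = rng.permutation(len(idx))
            test_idx.extend(idx[j] for j in perm[:k])
        test_set = set(test_idx)
    else:
        perm = rng.permutation(n)
        test_set = set(int(i) for i in perm[:n_test])
    test_ids = frozenset(uids[i] for i in test_set)
    train_ids = frozenset(u for u in uids if u not in test_ids)
    return DatasetSplit(train_ids, test_ids, seed=seed, test_fraction=test_fraction)


def records_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    """Tabulate records (one row per record, with the record uid)."""
    rows = []
    for r in records:
        rows.append(
            {
                "uid": _record_uid(r),
                "compound_id": r.compound_id,
                "smiles": r.smiles,
                "activity_nM": r.activity_nM,
                "standard_type": r.standard_type.value,
                "target": r.target.value,
                "assay_type": r.assay_type.value,
                "class_label": r.class_label,
            }
        )
    return pd.DataFrame(rows)


def read_activity_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited activity table with a header row."""
    return pd.read_csv(path, sep=None, engine="python")


def write_activity_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    frame = records_to_frame(records)
    cols = [
        "compound_id",
        "smiles",
        "activity_nM",
        "standard_type",
        "target",
        "assay_type",
        "class_label",
    ]
    frame[cols].rename(columns={"activity_nM": "activity_value"}).assign(
        activity_unit="nM"
    ).to_csv(path, index=False)
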