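"""Box-Jenkins condition-deviation descriptors.

A raw molecular descriptor carries no information about the experimental
condition a compound was assayed under, so a single model cannot
discriminate the same molecule tested against two targets.  The
Box-Jenkins operators fix this: for every element of each condition axis
(target ``tn``, standard type ``st``, assay type ``at``) the arithmetic
mean of each descriptor is taken over the *training-set actives* measured
under that element, and every data point is re-expressed as its deviation
from the averages of its own condition:

    delta(D)_e = D - avg(D)_e       for e in {tn, st, at}

yielding three suffixed features (``_tn``, ``_st``, ``_at``) per raw
descriptor.  Test and screening compounds reuse the training averages
unchanged, so no information leaks out of the training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .curation import CompoundRecord, ConditionVector, DatasetSplit, _record_uid

__all__ = [
    "AXES",
    "ConditionAverages",
    "condition_averages",
    "deviation_transform",
    "deviation_transform_library",
    "validate_descriptor_table",
    "read_descriptor_table",
    "write_descriptor_table",
]

#: condition axes in suffix order; each maps a record to its element value
AXES = ("tn", "st", "at")


def _element(record: CompoundRecord, axis: str) -> str:
    if axis == "tn":
        return record.target.value
    if axis == "st":
        return record.standard_type.value
    if axis == "at":
        return record.assay_type.value
    raise KeyError(axis)


def validate_descriptor_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a compounds-by-descriptors matrix: unique names, no missing values."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate descriptor names: {dupes}")
    if table.index.duplicated().any():
        raise ValueError("duplicate compound ids in descriptor table")
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(
            f"descriptor table contains missing values in columns {bad}; "
            "impute upstream or drop the compounds"
        )
    return table.astype(float)


@dataclass
class ConditionAverages:
    """Per-element training-active descriptor means (the avg(D)_e of the transform).

    ``averages[axis][element]`` is a Series of descriptor means.
    ``provenance_ids`` records the training-active ids the means came from.
    """

    averages: dict[str, dict[str, pd.Series]]
    descriptor_names: list[str]
    provenance_ids: list[str] = field(default_factory=list)
    actives_only: bool = True

    def lookup(self, axis: str, element: str) -> pd.Series:
        try:
            return self.averages[axis][element]
        except KeyError:
            raise KeyError(
                f"condition element {element!r} on axis {axis!r} has no training average"
            ) from None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "descriptor_names": self.descriptor_names,
            "actives_only": self.actives_only,
            "provenance_ids": self.provenance_ids,
            "averages": {
                axis: {el: series.to_dict() for el, series in by_el.items()}
                for axis, by_el in self.averages.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConditionAverages":
        payload = json.loads(Path(path).read_text())
        names = payload["descriptor_names"]
        averages = {
            axis: {
                el: pd.Series(vals).reindex(names)
                for el, vals in by_el.items()
            }
            for axis, by_el in payload["averages"].items()
        }
        return cls(
            averages=averages,
            descriptor_names=names,
            provenance_ids=payload.get("provenance_ids", []),
            actives_only=payload.get("actives_only", True),
        )


def condition_averages(
    raw: pd.DataFrame,
    records: Sequence[CompoundRecord],
    split: Optional[DatasetSplit] = None,
    actives_only: bool = True,
) -> ConditionAverages:
    """Average each descriptor over training-set actives, per condition element.

    ``raw`` is indexed by compound id.  If ``split`` is given, only records
    whose uid is in ``split.train_ids`` contribute; otherwise all records
    do (useful for worked examples).  By default only actives are averaged,
    the reference set the deviation is meant to measure distance from.
    Raises if any contributing record lacks a descriptor row, or if an
    encountered condition element has no contributing compounds.
    """
    raw = validate_descriptor_table(raw)
    train = [
        r
        for r in records
        if split is None or _record_uid(r) in split.train_ids
    ]
    reference = [r for r in train if (r.is_active or not actives_only)]
    missing = sorted({r.compound_id for r in reference} - set(raw.index))
    if missing:
        raise ValueError(f"descriptor rows missing for compounds: {missing[:5]}")

    averages: dict[str, dict[str, pd.Series]] = {axis: {} for axis in AXES}
    encountered = {axis: {_element(r, axis) for r in train} for axis in AXES}
    for axis in AXES:
        groups: dict[str, list[str]] = {}
        for r in reference:
            groups.setdefault(_element(r, axis), []).append(r.compound_id)
        for element in sorted(encountered[axis]):
            ids = groups.get(element, [])
            if not ids:
                raise ValueError(
                    f"no training actives under condition element "
                    f"{element!r} (axis {axis!r}); cannot form the average"
                )
            averages[axis][element] = raw.loc[ids].mean(axis=0)
    return ConditionAverages(
        averages=averages,
        descriptor_names=list(raw.columns),
        provenance_ids=sorted({r.compound_id for r in reference}),
        actives_only=actives_only,
    )


def _deviation_rows(
    raw: pd.DataFrame,
    averages: ConditionAverages,
    rows: list[tuple[str, str, ConditionVector]],
) -> pd.DataFrame:
    names = averages.descriptor_names
    if list(raw.columns) != names:
        missing = sorted(set(names) - set(raw.columns))
        if missing:
            raise ValueError(f"descriptor space mismatch; missing {missing[:5]}")
        raw = raw[names]
    import numpy as np

    elements = {"tn": lambda c: c.tn.value, "st": lambda c: c.st.value, "at": lambda c: c.at.value}
    values = raw.loc[[cid for _, cid, _ in rows]].to_numpy(dtype=float)
    blocks = []
    for axis in AXES:
        avg_rows = []
        for _, compound_id, condition in rows:
            element = elements[axis](condition)
            try:
                avg = averages.lookup(axis, element)
            except KeyError as exc:
                raise ValueError(f"compound {compound_id!r}: {exc.args[0]}") from None
            avg_rows.append(avg.to_numpy(dtype=float))
        blocks.append(values - np.vstack(avg_rows))
    columns = [f"{d}_{axis}" for axis in AXES for d in names]
    return pd.DataFrame(
        np.hstack(blocks), index=[uid for uid, _, _ in rows], columns=columns
    )


def deviation_transform(
    raw: pd.DataFrame,
    averages: ConditionAverages,
    records: Sequence[CompoundRecord],
) -> pd.DataFrame:
    """Build the deviation feature matrix for curated records.

    Output rows are indexed by record uid (compound|target|st|at) and the
    width is exactly three times the raw width, with ``_tn``/``_st``/``_at``
    suffixed names.  Raw descriptors are not carried through: the model
    space contains only deviation features.
    """
    raw = validate_descriptor_table(raw)
    rows = [(_record_uid(r), r.compound_id, r.condition) for r in records]
    missing = sorted({cid for _, cid, _ in rows} - set(raw.index))
    if missing:
        raise ValueError(f"descriptor rows missing for compounds: {missing[:5]}")
    return _deviation_rows(raw, averages, rows)


def deviation_transform_library(
    raw: pd.DataFrame,
    averages: ConditionAverages,
    condition: ConditionVector,
) -> pd.DataFrame:
    """Deviation features for a screening library under one fixed condition.

    Screening compounds carry no measured activity; every library row is
    transformed with the training averages of the supplied condition.
    Rows keep the library compound ids.
    """
    raw = validate_descriptor_table(raw)
    rows = [(cid, cid, condition) for cid in raw.index]
    return _deviation_rows(raw, averages, rows)


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited descriptor matrix whose first column is the compound id."""
    table = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return validate_descriptor_table(table)


def write_descriptor_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="compound_id")
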