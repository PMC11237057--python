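"""Synthetic multi-condition bioactivity data with known structure.

The generator emulates a curated two-target inhibition dataset: ~715
compounds split between ACE and NEP, activities spread log-normally over
several orders of magnitude with ~70% falling at or below the 600 nM
activity cutoff, and a descriptor matrix in which a small informative
subset separates actives from inactives by a tunable standardized effect
size.  Each target has its own informative descriptor set; the two sets
overlap partially, mirroring the dual-inhibitor structure in which some
chemistry drives both activities and some only one.  Standard type and
assay type are sampled independently of class, so their deviation
features carry little signal.

``worked_fixture`` returns a tiny hand-specified dataset whose
Box-Jenkins averages, deviations, Wilks lambda and metrics are frozen in
a golden sidecar (``data/worked_fixture_expected.json``) computed by hand
and by independent oracle arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .curation import (
    ACTIVITY_CUTOFF_NM,
    AssayType,
    CompoundRecord,
    StandardType,
    Target,
    assign_class,
)

__all__ = ["SimConfig", "generate", "worked_fixture", "worked_fixture_expected"]


@dataclass
class SimConfig:
    """Study-condition defaults: two targets of ~357/358 compounds, 70%
    prevalence at the 600 nM cutoff, a few hundred descriptors with a
    small informative subset."""

    n_ace: int = 357
    n_nep: int = 358
    p_raw: int = 200
    n_informative: int = 10
    effect_size: float = 1.5  # standardized class-mean separation per informative descriptor
    active_fraction: float = 0.70
    noise_sd: float = 1.0  # sd of the class-conditional informative descriptors
    sigma_log: float = 1.5  # spread of ln(activity), in ln-nM units
    p_ic50: float = 0.65  # P(standard type = IC50); rest Ki
    p_binding: float = 0.70  # P(assay type = B); rest F
    overlap_fraction: float = 0.6  # per-target informative set size / n_informative
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_ace, self.n_nep) < 2:
            raise ValueError("need at least two compounds per target")
        if not 0 < self.n_informative <= self.p_raw:
            raise ValueError("n_informative must lie in (0, p_raw]")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.effect_size < 0 or self.noise_sd <= 0 or self.sigma_log <= 0:
            raise ValueError("effect_size >= 0 and positive scales required")
        for p in (self.p_ic50, self.p_binding):
            if not 0.0 <= p <= 1.0:
                raise ValueError("condition-mix probabilities must lie in [0, 1]")
        if not 0.5 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0.5, 1] so the sets cover the pool")


def _informative_sets(config: SimConfig) -> dict[str, np.ndarray]:
    """Partially overlapping per-target informative descriptor indices.

    Each target gets ``round(overlap_fraction * n_informative)`` of the
    ``n_informative`` informative columns; the union covers all of them.
    """
    m = int(round(config.overlap_fraction * config.n_informative))
    m = min(max(m, 1), config.n_informative)
    ace = np.arange(0, m)
    nep = np.arange(config.n_informative - m, config.n_informative)
    return {"ACE": ace, "NEP": nep}


def generate(config: Optional[SimConfig] = None) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Draw records and a raw descriptor matrix; deterministic given the seed.

    Activities are log-normal with median calibrated so that the active
    fraction falls at or below the 600 nM cutoff.  An informative
    descriptor for a compound's own target is N(+d/2, noise_sd) for
    actives and N(-d/2, noise_sd) for inactives (d = effect_size *
    noise_sd); every other descriptor is standard normal noise.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_ace + config.n_nep
    targets = [Target.ACE] * config.n_ace + [Target.NEP] * config.n_nep

    # ln(activity) ~ N(mu, sigma); P(activity <= cutoff) = active_fraction
    mu = np.log(ACTIVITY_CUTOFF_NM) - config.sigma_log * norm.ppf(config.active_fraction)
    activities = np.exp(rng.normal(mu, config.sigma_log, size=n))
    st = rng.random(n) < config.p_ic50
    at = rng.random(n) < config.p_binding

    ids = [f"{t.value}{i:04d}" for i, t in enumerate(targets, start=1)]
    records = []
    for i in range(n):
        rec = CompoundRecord(
            compound_id=ids[i],
            activity_nM=float(activities[i]),
            standard_type=StandardType.IC50 if st[i] else StandardType.KI,
            target=targets[i],
            assay_type=AssayType.B if at[i] else AssayType.F,
        )
        rec.class_label = assign_class(rec.activity_nM)
        records.append(rec)

    sets = _informative_sets(config)
    X = rng.normal(0.0, 1.0, size=(n, config.p_raw))
    sign = np.array([1.0 if r.is_active else -1.0 for r in records])
    shift = 0.5 * config.effect_size * config.noise_sd
    for i, rec in enumerate(records):
        cols = sets[rec.target.value]
        X[i, cols] = rng.normal(sign[i] * shift, config.noise_sd, size=cols.size)
    names = [f"D{j + 1:03d}" for j in range(config.p_raw)]
    table = pd.DataFrame(X, index=pd.Index(ids, name="compound_id"), columns=names)
    return records, table


# --- worked fixture -------------------------------------------------------

_FIXTURE_ROWS = [
    # id, target, st, at, activity_nM, D1, D2, D3, D4
    ("M1", "ACE", "IC50", "B", 100.0, 1.0, 2.0, 0.0, 10.0),
    ("M2", "ACE", "IC50", "F", 300.0, 3.0, 0.0, 1.0, 8.0),
    ("M3", "ACE", "Ki", "B", 5000.0, 5.0, 1.0, 4.0, 0.0),
    ("M4", "ACE", "Ki", "F", 600.0, 2.0, 2.0, 2.0, 6.0),
    ("M5", "NEP", "IC50", "B", 200.0, 4.0, 1.0, 1.0, 9.0),
    ("M6", "NEP", "Ki", "F", 2000.0, 6.0, 3.0, 5.0, 1.0),
    ("M7", "NEP", "IC50", "F", 50.0, 2.0, 3.0, 1.0, 7.0),
    ("M8", "NEP", "Ki", "B", 10000.0, 8.0, 0.0, 6.0, 2.0),
]


def worked_fixture() -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Tiny deterministic dataset: 8 compounds x 4 descriptors, both targets.

    Five actives (600 nM sits exactly on the inclusive cutoff), three
    inactives, every condition element represented among the actives.
    Idempotent: every call returns equal objects.
    """
    records = []
    rows = []
    for cid, tn, st, at, act, *descs in _FIXTURE_ROWS:
        rec = CompoundRecord(
            compound_id=cid,
            activity_nM=act,
            standard_type=StandardType(st),
            target=Target(tn),
            assay_type=AssayType(at),
        )
        rec.class_label = assign_class(rec.activity_nM)
        records.append(rec)
        rows.append(descs)
    table = pd.DataFrame(
        rows,
        index=pd.Index([r[0] for r in _FIXTURE_ROWS], name="compound_id"),
        columns=["D1", "D2", "D3", "D4"],
        dtype=float,
    )
    return records, table


def worked_fixture_expected() -> dict:
    """Golden values (averages, deviations, lambda, metrics) for the fixture."""
    ref = resources.files("mtqsar.data").joinpath("worked_fixture_expected.json")
    return json.loads(ref.read_text())
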