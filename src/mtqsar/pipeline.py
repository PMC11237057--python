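"""End-to-end orchestration: curate -> split -> Box-Jenkins -> GA-LDA ->
random forest -> validation battery -> applicability domain -> screening.

A single run is driven by a :class:`RunConfig` (loadable from a flat YAML
document) and one master seed.  The master seed fans out to per-stage
seeds through a fixed counter scheme (seed + stage offset), so every
stage is independently reproducible and two runs with the same config are
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import box_jenkins, curation, screening, validation
from .applicability_domain import ADModel, ad_assess_batch, ad_fit
from .box_jenkins import ConditionAverages
from .classifiers import (
    DiscriminantModel,
    ForestConfig,
    ForestModel,
    fit_lda,
    fit_rf,
    lda_predict,
    rf_predict,
)
from .curation import CompoundRecord, DatasetSplit, _record_uid
from .feature_selection import GAConfig, SelectionResult, ga_select
from .synthetic import SimConfig, generate

logger = logging.getLogger("mtqsar")

__all__ = ["RunConfig", "FitBundle", "run_fit", "run_screen", "STAGE_SEED_OFFSETS"]

#: master-seed fan-out: stage seed = seed + offset (documented counter scheme)
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "split": 1,
    "ga": 2,
    "rf": 3,
    "cv": 4,
    "yrand": 5,
}


def stage_seed(seed: int, stage: str) -> int:
    return (seed + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    """Flat run configuration; ``seed`` is mandatory."""

    seed: int
    cutoff_nM: float = 600.0
    test_fraction: float = 0.30
    actives_only_averages: bool = True
    ga: GAConfig = field(default_factory=GAConfig)
    rf: ForestConfig = field(default_factory=ForestConfig)
    ad_threshold: float = 3.0
    ad_tail_multiplier: float = 1.28
    cv_folds: int = 10
    n_permutations: int = 50
    sim: SimConfig = field(default_factory=SimConfig)
    activity_path: Optional[str] = None
    descriptor_path: Optional[str] = None
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path, seed: Optional[int] = None) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            doc["seed"] = seed
        if "seed" not in doc:
            raise ValueError("config must supply a seed (or pass --seed)")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, sub in (("ga", GAConfig), ("rf", ForestConfig), ("sim", SimConfig)):
            if name in doc and isinstance(doc[name], dict):
                doc[name] = sub(**doc[name])
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                for k, v in dataclasses.asdict(self).items()
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FitBundle:
    """Everything a fitted run produces, ready for screening or serialization."""

    config: RunConfig
    records: list[CompoundRecord]
    split: DatasetSplit
    averages: ConditionAverages
    features_train: pd.DataFrame
    features_test: pd.DataFrame
    y_train: np.ndarray
    y_test: np.ndarray
    selection: SelectionResult
    lda_model: DiscriminantModel
    rf_model: ForestModel
    ad_model: ADModel
    metrics: dict
    yrand: validation.YRandResult
    roc: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": self.config.config_hash(), "seed": self.config.seed}
        self.averages.to_json(outdir / "condition_averages.json")
        self.lda_model.to_json(outdir / "lda_model.json")
        self.rf_model.save(outdir / "rf_model.joblib")
        self.ad_model.to_json(outdir / "ad_model.json")
        self.selection.to_json(outdir / "selection.json", self.config.ga)
        self.yrand.to_json(outdir / "y_randomization.json")
        (outdir / "metrics.json").write_text(json.dumps({**meta, **self.metrics}, indent=2))
        for name, (auc, curve) in self.roc.items():
            curve.to_csv(outdir / f"roc_{name}.csv", index=False)
        (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2))


def _labels(records: Sequence[CompoundRecord], uids: Sequence[str]) -> np.ndarray:
    by_uid = {_record_uid(r): r for r in records}
    return np.array([1 if by_uid[u].is_active else 0 for u in uids])


def run_fit(
    config: RunConfig,
    records: Optional[list[CompoundRecord]] = None,
    raw_descriptors: Optional[pd.DataFrame] = None,
) -> FitBundle:
    """Execute the full modelling pipeline and return the artifact bundle.

    Inputs may be passed in-memory; otherwise they are read from the
    configured paths, and if no activity path is configured the synthetic
    generator supplies the dataset (seeded from the master seed).
    """
    if records is None or raw_descriptors is None:
        if config.activity_path and config.descriptor_path:
            table = curation.read_activity_table(config.activity_path)
            records, report = curation.curate_records(table, config.cutoff_nM)
            raw_descriptors = box_jenkins.read_descriptor_table(config.descriptor_path)
            logger.info("curate: %d -> %d records, drops=%s", report.n_input, report.n_retained, report.dropped)
        else:
            sim = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
            records, raw_descriptors = generate(sim)
            logger.info("simulate: n=%d p=%d seed=%d", len(records), raw_descriptors.shape[1], sim.seed)

    split = curation.split_train_test(
        records, config.test_fraction, seed=stage_seed(config.seed, "split")
    )
    logger.info("split: train=%d test=%d", len(split.train_ids), len(split.test_ids))

    averages = box_jenkins.condition_averages(
        raw_descriptors, records, split, actives_only=config.actives_only_averages
    )
    features = box_jenkins.deviation_transform(raw_descriptors, averages, records)
    train_uids = [u for u in features.index if u in split.train_ids]
    test_uids = [u for u in features.index if u in split.test_ids]
    X_train, X_test = features.loc[train_uids], features.loc[test_uids]
    y_train, y_test = _labels(records, train_uids), _labels(records, test_uids)
    logger.info("box_jenkins: features=%d", features.shape[1])

    ga = dataclasses.replace(config.ga, seed=stage_seed(config.seed, "ga"))
    selection = ga_select(X_train, y_train, ga)
    logger.info("ga_select: |subset|=%d fitness=%.4f", len(selection.chosen), selection.fitness)

    lda_model = fit_lda(X_train, y_train, selection.chosen)
    # the forest uses the full deviation feature space (nonlinear models do not
    # need the subset restriction that keeps the discriminant parsimonious)
    rf_cfg = dataclasses.replace(config.rf, seed=stage_seed(config.seed, "rf"))
    rf_model = fit_rf(X_train, y_train, rf_cfg)

    metrics_report: dict = {"n_train": len(y_train), "n_test": len(y_test)}
    roc: dict = {}
    for name, model, predict in (
        ("lda", lda_model, lda_predict),
        ("rf", rf_model, rf_predict),
    ):
        for part, X_part, y_part in (("train", X_train, y_train), ("test", X_test, y_test)):
            scores, labels = predict(model, X_part)
            counts = validation.confusion(y_part, labels)
            auc, curve = validation.roc_auc(scores, y_part)
            roc[f"{name}_{part}"] = (auc, curve)
            report = validation.metrics(counts, auc=auc)
            metrics_report[f"{name}_{part}"] = {
                "counts": counts.__dict__,
                **report.rounded(),
            }
    logger.info(
        "validate: lda test acc=%.2f rf test acc=%.2f",
        metrics_report["lda_test"]["accuracy"],
        metrics_report["rf_test"]["accuracy"],
    )

    yrand = validation.y_randomization(
        X_train,
        y_train,
        selection.chosen,
        n_perm=config.n_permutations,
        seed=stage_seed(config.seed, "yrand"),
    )
    metrics_report["y_randomization"] = {
        "lambda_original": yrand.lambda_original,
        "mean_lambda_randomized": yrand.mean_lambda_randomized,
    }

    ad_model = ad_fit(
        X_train[selection.chosen],
        threshold=config.ad_threshold,
        tail_multiplier=config.ad_tail_multiplier,
    )
    ad_train = ad_assess_batch(ad_model, X_train[selection.chosen])
    ad_test = ad_assess_batch(ad_model, X_test[selection.chosen])
    metrics_report["ad_outliers"] = {
        "train": int((~ad_train["inside"]).sum()),
        "n_train": len(ad_train),
        "test": int((~ad_test["inside"]).sum()),
        "n_test": len(ad_test),
    }
    logger.info("ad: %s", metrics_report["ad_outliers"])

    bundle = FitBundle(
        config=config,
        records=records,
        split=split,
        averages=averages,
        features_train=X_train,
        features_test=X_test,
        y_train=y_train,
        y_test=y_test,
        selection=selection,
        lda_model=lda_model,
        rf_model=rf_model,
        ad_model=ad_model,
        metrics=metrics_report,
        yrand=yrand,
        roc=roc,
    )
    if config.output_dir:
        bundle.save(config.output_dir)
    return bundle


def run_screen(
    bundle: FitBundle,
    library: pd.DataFrame,
    conditions=None,
    require_both_targets: bool = True,
):
    """Screen a library descriptor table with a fitted bundle.

    Returns (decisions, summary dict); the per-compound table comes from
    :func:`mtqsar.screening.decisions_to_frame`.
    """
    if conditions is None:
        train_records = [r for r in bundle.records if _record_uid(r) in bundle.split.train_ids]
        conditions = screening.default_conditions(train_records)
    if library.empty:
        return [], {"n_library": 0, "n_selected": 0, "reason_counts": {}}
    decisions = screening.screen_library(
        library,
        bundle.averages,
        bundle.lda_model,
        bundle.rf_model,
        bundle.ad_model,
        conditions,
        require_both_targets=require_both_targets,
    )
    counts: dict[str, int] = {}
    for d in decisions:
        for reason in d.reasons:
            counts[reason] = counts.get(reason, 0) + 1
    summary = {
        "n_library": len(decisions),
        "n_selected": sum(d.selected for d in decisions),
        "reason_counts": counts,
    }
    logger.info("screen: %s", summary)
    return decisions, summary
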