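"""End-to-end experiment driver: the four-delineation comparison on a
synthetic cohort.

``run_experiment`` executes generate -> TBR-normalize -> build mask
variants -> extract features x4 -> harmonize -> redundancy-reduce ->
harmonized Monte-Carlo cross-validation -> evaluation, and (optionally)
writes every artifact of the run — feature tables, fold manifest,
pooled predictions, per-delineation metric summaries, feature-count
flow, ANOVA p-values and volume-decile counts — into a run directory
together with the resolved configuration.  Everything is a pure
function of the configuration, including its master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import aggregate_cv, anova_compare, volume_percentile_accuracy
from .extract import EngineConfig, extract_features
from .image_io import tbr_normalize
from .masks import DEFAULT_DILATION_VOXELS, DEFAULT_MIN_VOXELS, build_variants, check_min_voxels
from .pipeline import (
    DEFAULT_N_FOLDS,
    DEFAULT_TEST_FRACTION,
    cross_validate,
    make_mc_folds,
    select_feature_count,
)
from .synthetic import PhantomSpec, generate_cohort
from .tables import FeatureTable, build_feature_table, reduce_redundancy, validate_and_harmonize

__all__ = ["RunConfig", "ExperimentResult", "run_experiment"]

log = logging.getLogger("fuzzyrad")

DELINEATIONS = ("Ref-B", "Ref-F", "Ext-B", "Ext-F")


@dataclass
class RunConfig:
    """Resolved configuration of one experiment run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    fwhm_mm: float = 5.0
    dilation_voxels: int = DEFAULT_DILATION_VOXELS
    bin_width: float = 0.1
    epsilon: float = 1e-3
    min_voxels: int = DEFAULT_MIN_VOXELS
    rho_threshold: float = 0.9
    n_folds: int = DEFAULT_N_FOLDS
    test_fraction: float = DEFAULT_TEST_FRACTION
    master_seed: int = 0
    delineations: tuple[str, ...] = DELINEATIONS

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["phantom"] = asdict(self.phantom)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "phantom" in d:
            d["phantom"] = PhantomSpec(**d["phantom"])
        if "delineations" in d:
            d["delineations"] = tuple(d["delineations"])
        return cls(**d)


@dataclass
class ExperimentResult:
    config: RunConfig
    meta: pd.DataFrame
    tables: dict[str, FeatureTable]  # post-RR, per delineation
    harmonized: dict[str, FeatureTable]
    folds: list
    predictions: pd.DataFrame  # pooled over delineations
    summaries: dict[str, object]  # delineation -> CVSummary
    anova_p: dict[str, float]
    feature_counts: pd.DataFrame
    deciles: pd.DataFrame


def _seed_stream(master_seed: int) -> dict[str, int]:
    """Named substreams derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    cohort, folds, cv = ss.generate_state(3) % (2**31)
    return {"cohort": int(cohort), "folds": int(folds), "cv": int(cv)}


def run_experiment(config: RunConfig, out_dir=None) -> ExperimentResult:
    """Run the full four-delineation comparison; optionally write artifacts."""
    seeds = _seed_stream(config.master_seed)
    spec = dataclasses.replace(config.phantom, seed=seeds["cohort"])
    engine = EngineConfig(
        bin_width=config.bin_width, epsilon=config.epsilon, min_voxels=config.min_voxels
    )

    log.info("generating cohort: %d lesions", spec.lesion_count)
    samples, meta = generate_cohort(spec, min_voxels=config.min_voxels)
    log.info("cohort ready: %d lesions / %d patients",
             len(samples), meta["patient_id"].nunique())

    vectors: dict[str, dict] = {name: {} for name in config.delineations}
    for s in samples:
        tbr = tbr_normalize(s.volume, s.background)
        if not check_min_voxels(s.ref_b, config.min_voxels):
            continue  # gate on the reference mask, before variant generation
        variants = build_variants(s.ref_b, config.fwhm_mm, config.dilation_voxels)
        for name, mask in variants.as_dict().items():
            if name in vectors:
                vectors[name][s.lesion_id] = extract_features(tbr, mask, engine)

    raw_tables = [
        build_feature_table(vectors[name], meta, name) for name in config.delineations
    ]
    n_original = len(raw_tables[0].feature_names)
    harmonized = validate_and_harmonize(raw_tables)
    log.info("harmonized: %d lesions, %d features (of %d)",
             len(harmonized[0].data), len(harmonized[0].feature_names), n_original)

    reduced = {t.delineation: reduce_redundancy(t, config.rho_threshold)
               for t in harmonized}
    majority = int(np.bincount(harmonized[0].labels.to_numpy()).max())

    counts_rows = []
    for name in config.delineations:
        n_rr = len(reduced[name].feature_names)
        counts_rows.append(
            {
                "delineation": name,
                "features_original": n_original,
                "features_harmonized": len(harmonized[0].feature_names),
                "features_redundancy_reduced": n_rr,
                "features_selected": select_feature_count(majority, available=n_rr),
            }
        )
    feature_counts = pd.DataFrame(counts_rows)

    fold_meta = harmonized[0].data[["patient_id", "label"]]
    folds = make_mc_folds(fold_meta, config.n_folds, config.test_fraction,
                          seed=seeds["folds"])
    log.info("generated %d harmonized folds (%d test lesions per class)",
             len(folds), folds[0].test_per_class)

    predictions = []
    summaries = {}
    for name in config.delineations:
        preds = cross_validate(reduced[name], folds, seed=seeds["cv"])
        predictions.append(preds)
        summaries[name] = aggregate_cv(preds)
        log.info("%s: mean CV AUC %.3f", name, summaries[name].mean_auc)
    predictions = pd.concat(predictions, ignore_index=True)

    auc_sets = {name: summaries[name].per_fold["AUC"].to_numpy()
                for name in config.delineations}
    reference = "Ref-B" if "Ref-B" in auc_sets else config.delineations[0]
    anova_p = anova_compare(auc_sets, reference=reference) if len(auc_sets) > 1 else {}

    volumes = harmonized[0].data["lesion_volume_mm3"]
    vol_range = (float(volumes.min()), float(volumes.max()))
    deciles = volume_percentile_accuracy(predictions, volumes, range_mm3=vol_range)

    result = ExperimentResult(
        config=config, meta=meta, tables=reduced,
        harmonized={t.delineation: t for t in harmonized},
        folds=folds, predictions=predictions, summaries=summaries,
        anova_p=anova_p, feature_counts=feature_counts, deciles=deciles,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(r: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    r.config.to_yaml(out / "config.yaml")
    r.meta.to_csv(out / "labels.csv", index=False)
    for name, t in r.tables.items():
        t.data.to_csv(out / f"features_{name.replace('-', '_')}.csv")
        sidecar = {
            "delineation": name,
            "dropped_features": t.dropped_features,
            "clusters": t.clusters,
        }
        with open(out / f"features_{name.replace('-', '_')}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
    with open(out / "folds.json", "w") as fh:
        json.dump(
            [
                {"fold_id": f.fold_id, "train": list(f.train_ids),
                 "test": list(f.test_ids)}
                for f in r.folds
            ],
            fh, indent=1,
        )
    r.predictions.to_csv(out / "predictions.csv", index=False)
    r.feature_counts.to_csv(out / "feature_counts.csv", index=False)
    metric_rows = []
    for name, s in r.summaries.items():
        metric_rows.append(
            {
                "delineation": name,
                "mean_auc": s.mean_auc,
                "auc_ci_low": s.auc_ci[0],
                "auc_ci_high": s.auc_ci[1],
                "pooled_auc": s.pooled_auc,
                **{k: v for k, v in s.pooled_metrics.items()},
                "anova_p_vs_ref": r.anova_p.get(name, float("nan")),
            }
        )
    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
    r.deciles.to_csv(out / "deciles.csv", index=False)
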