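"""End-to-end orchestration: simulate -> features -> cohorts -> train ->
calibrate -> evaluate -> cluster, with reproducible artifacts.

A single global seed is fanned out to per-stage seeds by fixed offsets
(generator +1, cohort split +2, model +3, clustering +4), so each stage is
individually reproducible.  Every JSON artifact embeds the manifest hash
(SHA-256 of the canonical config), and two runs with equal manifests
produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import PPVCalibrator, T_HIGH, assign_risk_group
from .clustering import HighRiskClusterer, profile_clusters
from .cohorts import apply_exclusions, split_cohorts, stratify_six_subgroups
from .evaluation import DEFAULT_THRESHOLDS, evaluate
from .features import FeatureMatrix, build_pivot_table, variance_filter
from .model import EDRiskModel, MODEL_FORMAT_VERSION
from .synth import SyntheticConfig, generate_population, read_tables

__all__ = ["RunConfig", "SchemaError", "run_retrospective", "run_prospective",
           "compute_windows"]

log = logging.getLogger("edrisk")


class SchemaError(ValueError):
    """A scoring cohort is missing features the frozen model requires."""


@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    # input: either a directory of CSV tables or a synthetic draw
    input_dir: str | None = None
    n_patients: int = 20000
    index_date: dt.date = dt.date(2013, 1, 1)
    observation_days: int = 365
    outcome_days: int = 180
    # features
    keep_n: int = 40
    # model
    n_trees: int = 100
    bootstrap_fraction: float = 0.8
    max_depth: int = 8
    min_samples_leaf: int = 25
    review_fraction: float = 0.15
    ppv_target: float = 0.7
    max_features: int = 10
    mode: str = "survival"
    # calibration
    min_cell: int = 50
    # evaluation
    thresholds: tuple = DEFAULT_THRESHOLDS
    # clustering
    cluster_k: int = 6
    variance_target: float = 0.8
    restarts: int = 25
    # run
    seed: int = 0
    output_dir: str = "edrisk_run"

    def validate(self) -> None:
        if self.observation_days <= 0 or self.outcome_days <= 0:
            raise ValueError("window lengths must be positive")
        if self.input_dir is None and self.n_patients <= 0:
            raise ValueError("n_patients must be positive for synthetic runs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "index_date" in raw and isinstance(raw["index_date"], str):
            raw["index_date"] = dt.date.fromisoformat(raw["index_date"])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["index_date"] = self.index_date.isoformat()
        d["thresholds"] = list(self.thresholds)
        d["edrisk_version"] = __version__
        d["model_format_version"] = MODEL_FORMAT_VERSION
        return d


def _manifest_hash(manifest: dict) -> str:
    # the hash covers the scientific configuration, not artifact locations
    hashed = {k: v for k, v in manifest.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()).hexdigest()


def compute_windows(index_date: dt.date, observation_days: int,
                    outcome_days: int):
    """Observation window ends the day before the index date; the outcome
    window starts on it."""
    obs = (index_date - dt.timedelta(days=observation_days),
           index_date - dt.timedelta(days=1))
    out = (index_date, index_date + dt.timedelta(days=outcome_days - 1))
    return obs, out


def _load_population(config: RunConfig):
    if config.input_dir is not None:
        log.info("stage=load input_dir=%s", config.input_dir)
        return read_tables(config.input_dir)
    synth_cfg = SyntheticConfig(
        n_patients=config.n_patients, index_date=config.index_date,
        observation_days=config.observation_days,
        outcome_days=config.outcome_days, seed=config.seed + 1)
    log.info("stage=simulate n=%d seed=%d", config.n_patients,
             config.seed + 1)
    return generate_population(synth_cfg)


def _features_for(config: RunConfig, histories,
                  filter_variance: bool = True) -> FeatureMatrix:
    obs, out = compute_windows(config.index_date, config.observation_days,
                               config.outcome_days)
    matrix = build_pivot_table(histories, obs, out)
    if filter_variance:
        matrix = variance_filter(matrix, config.keep_n)
    log.info("stage=features rows=%d cols=%d", *matrix.values.shape)
    return matrix


def _cluster_high_risk(config: RunConfig, matrix: FeatureMatrix,
                       indices: np.ndarray, outdir: Path) -> None:
    high = indices >= T_HIGH
    n_high = int(high.sum())
    if n_high < max(config.cluster_k, 2):
        warnings.warn(
            f"only {n_high} high-risk patients; skipping clustering",
            stacklevel=2)
        return
    sub = matrix.subset_rows(matrix.patient_ids[high])
    clusterer = HighRiskClusterer(
        n_clusters=config.cluster_k, variance_target=config.variance_target,
        restarts=config.restarts, random_state=config.seed + 4)
    labels = clusterer.fit_predict(sub.values)
    profiles = profile_clusters(labels, sub)
    profiles.to_csv(outdir / "cluster_profiles.csv", index=False)
    pd.DataFrame({"patient_id": sub.patient_ids, "cluster": labels}).to_csv(
        outdir / "cluster_assignments.csv", index=False)
    with open(outdir / "cluster_summary.json", "w") as f:
        json.dump({
            "n_high_risk": n_high,
            "n_components": clusterer.n_components_,
            "explained_variance_ratio":
                clusterer.explained_variance_ratio_.tolist(),
            "cluster_sizes": profiles.set_index("cluster")["n"].to_dict(),
        }, f, indent=1, sort_keys=True)
    log.info("stage=cluster n_high=%d k=%d", n_high, config.cluster_k)


def _write_assessments(calibrator: PPVCalibrator, matrix: FeatureMatrix,
                       scores: np.ndarray, outdir: Path) -> pd.DataFrame:
    assess = calibrator.assess(matrix.patient_ids, scores)
    assess.to_csv(outdir / "assessments.csv", index=False)
    return assess


def run_retrospective(config: RunConfig) -> Path:
    """Retrospective modeling: exclusions -> features -> six-stratum split
    -> train on Cohort I -> calibrate on Cohort II -> blind-test report on
    Cohort III -> high-risk clustering.  Returns the artifact directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = config.to_manifest()
    manifest["run_kind"] = "retrospective"
    mhash = _manifest_hash(manifest)
    manifest["manifest_hash"] = mhash

    histories = _load_population(config)
    n_in = len(histories)
    histories, excl_log = apply_exclusions(histories)
    excl_log.to_csv(outdir / "exclusions.csv", index=False)
    log.info("stage=exclusions in=%d out=%d", n_in, len(histories))

    matrix = _features_for(config, histories)
    strata = stratify_six_subgroups(matrix)
    split = split_cohorts(strata, matrix.outcome, config.seed + 2)
    split.save(outdir / "cohorts.csv")
    log.info("stage=split cohorts=%s",
             split.assignment.value_counts().to_dict())

    m1 = matrix.subset_rows(split.cohort_ids("I"))
    model = EDRiskModel(
        n_trees=config.n_trees, bootstrap_fraction=config.bootstrap_fraction,
        max_depth=config.max_depth, min_samples_leaf=config.min_samples_leaf,
        review_fraction=config.review_fraction, ppv_target=config.ppv_target,
        max_features=config.max_features, mode=config.mode,
        random_state=config.seed + 3,
    ).fit_matrix(m1)
    log.info("stage=train n=%d", len(m1.patient_ids))

    m2 = matrix.subset_rows(split.cohort_ids("II"))
    calibrator = PPVCalibrator(min_cell=config.min_cell).fit(
        model.predict_score(m2.values), m2.outcome.to_numpy())
    log.info("stage=calibrate n=%d knots=%d", len(m2.patient_ids),
             calibrator.knots_score_.size)

    doc = {"format_version": MODEL_FORMAT_VERSION,
           "manifest_hash": mhash,
           "model": model.to_json_dict(),
           "calibration": calibrator.to_dict()}
    with open(outdir / "model.json", "w") as f:
        json.dump(doc, f)

    m3 = matrix.subset_rows(split.cohort_ids("III"))
    s3 = model.predict_score(m3.values)
    idx3 = calibrator.transform(s3)
    groups3 = np.asarray([assign_risk_group(v) for v in idx3])
    report = evaluate(
        idx3, m3.outcome.to_numpy(), m3.time_to_event.to_numpy(),
        m3.event_observed.to_numpy(), groups3,
        m3.outcome_ed_count.to_numpy(), feature_values=m3.values.to_numpy(),
        feature_names=m3.feature_names, scores=s3,
        thresholds=config.thresholds)
    rep = report.to_json_dict()
    rep["manifest_hash"] = mhash
    with open(outdir / "report.json", "w") as f:
        json.dump(rep, f, indent=1, sort_keys=True)
    report.ppv_table.to_csv(outdir / "report_ppv_table.csv", index=False)
    km = pd.concat([v.assign(risk_group=k)
                    for k, v in report.km_curves.items()],
                   ignore_index=True) if report.km_curves else pd.DataFrame()
    km.to_csv(outdir / "report_km_curves.csv", index=False)
    log.info("stage=evaluate auc=%.4f logrank_p=%.3g", report.auc,
             report.logrank_p)

    scores_all = model.predict_score(matrix.values)
    _write_assessments(calibrator, matrix, scores_all, outdir)
    idx_all = calibrator.transform(scores_all)
    _cluster_high_risk(config, matrix, idx_all, outdir)

    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return outdir


def load_frozen(model_path: str | Path) -> tuple[EDRiskModel, PPVCalibrator]:
    """Load a persisted model + calibration document (never refits)."""
    with open(model_path) as f:
        doc = json.load(f)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc.get('format_version')!r}")
    model = EDRiskModel(**doc["model"]["params"])
    from .model import SubgroupModel
    model.submodels_ = {k: SubgroupModel.from_dict(v)
                        for k, v in doc["model"]["submodels"].items()}
    model.selected_features_ = {k: list(v.selected_features)
                                for k, v in model.submodels_.items()}
    model.classes_ = np.array([0, 1])
    calibrator = PPVCalibrator.from_dict(doc["calibration"])
    return model, calibrator


def run_prospective(config: RunConfig, frozen_model_path: str | Path) -> Path:
    """Score a new cohort with a frozen model + calibration (no refitting),
    emitting the same report family as the retrospective run."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, calibrator = load_frozen(frozen_model_path)
    manifest = config.to_manifest()
    manifest["run_kind"] = "prospective"
    manifest["frozen_model"] = str(frozen_model_path)
    mhash = _manifest_hash(manifest)
    manifest["manifest_hash"] = mhash

    histories = _load_population(config)
    histories, excl_log = apply_exclusions(histories)
    excl_log.to_csv(outdir / "exclusions.csv", index=False)
    matrix = _features_for(config, histories, filter_variance=False)

    required = sorted({f for feats in model.selected_features_.values()
                       for f in feats} | {"prior_ed_count", "chronic_flag"})
    missing = [f for f in required if f not in matrix.values.columns]
    if missing:
        raise SchemaError(
            "scoring cohort is missing features required by the frozen "
            f"model: {missing}")

    scores = model.predict_score(matrix.values)
    indices = calibrator.transform(scores)
    groups = np.asarray([assign_risk_group(v) for v in indices])
    report = evaluate(
        indices, matrix.outcome.to_numpy(), matrix.time_to_event.to_numpy(),
        matrix.event_observed.to_numpy(), groups,
        matrix.outcome_ed_count.to_numpy(),
        feature_values=matrix.values.to_numpy(),
        feature_names=matrix.feature_names, scores=scores,
        thresholds=config.thresholds)
    rep = report.to_json_dict()
    rep["manifest_hash"] = mhash
    with open(outdir / "report.json", "w") as f:
        json.dump(rep, f, indent=1, sort_keys=True)
    report.ppv_table.to_csv(outdir / "report_ppv_table.csv", index=False)
    _write_assessments(calibrator, matrix, scores, outdir)
    _cluster_high_risk(config, matrix, indices, outdir)
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return outdir
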