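"""End-to-end experiment orchestration.

Runs the full study from one config: simulate a cohort, label outcomes,
split 70:20:10, featurize, train the recurrent model per feature set and
the static benchmarks, evaluate dynamically (per review period and severity
band), and run the error analysis.  Stage seeds are derived by hashing
(global seed, stage name), so adding a stage never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from icbt_dynamics import io as cio
from icbt_dynamics.cohort import GeneratorConfig, sample_cohort
from icbt_dynamics.errors import classify_errors
from icbt_dynamics.evaluation import (
    EvaluationReport,
    predict_cohort,
    stratified_evaluation,
)
from icbt_dynamics.labeling import label_cohort
from icbt_dynamics.models import (
    EmaClassifier,
    RnnConfig,
    SplitSpec,
    split_data,
    train_rnn,
    train_static_classifier,
)

logger = logging.getLogger(__name__)

STATIC_KINDS = ("logistic_regression", "random_forest", "gradient_boosting")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    n_clients: int = 2000
    generator_overrides: Mapping[str, object] = field(default_factory=dict)
    feature_sets: tuple[str, ...] = ("Q", "Qc", "I", "I+Q")
    targets: tuple[str, ...] = ("phq9", "gad7")
    models: tuple[str, ...] = ("rnn", "logistic_regression", "random_forest", "gradient_boosting", "ema")
    rnn: RnnConfig | None = None
    evaluate_on: str = "test"  # or "validation"
    min_t: int | None = None
    out_dir: str | None = None
    seed: int = 0


@dataclass
class ExperimentManifest:
    config: ExperimentConfig
    stage_seeds: dict[str, int]
    reports: dict[str, EvaluationReport]  # key "model/feature_set/target"
    error_sets: dict[str, dict]
    artifact_hashes: dict[str, str]
    durations: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "stage_seeds": self.stage_seeds,
            "artifacts": sorted(self.reports.keys()),
            "artifact_hashes": self.artifact_hashes,
            "durations_s": {k: round(v, 2) for k, v in self.durations.items()},
            "error_set_counts": self.error_sets,
        }


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def run_experiment(config: ExperimentConfig) -> ExperimentManifest:
    """Execute simulate -> label -> split -> train -> evaluate -> errors."""
    seeds = {
        stage: stage_seed(config.seed, stage)
        for stage in ("simulate", "split", "train", "evaluate")
    }
    durations: dict[str, float] = {}
    hashes: dict[str, str] = {}

    t0 = time.perf_counter()
    gen = GeneratorConfig(
        n_clients=config.n_clients, seed=seeds["simulate"], **dict(config.generator_overrides)
    )
    cohort = sample_cohort(gen)
    labels = label_cohort(cohort)
    obs, interactions = cio.cohort_to_frames(cohort)
    hashes["observations"] = _hash_frame(obs)
    hashes["interactions"] = _hash_frame(interactions)
    durations["simulate"] = time.perf_counter() - t0
    logger.info("simulate: %d clients in %.1fs", len(cohort), durations["simulate"])

    reports: dict[str, EvaluationReport] = {}
    error_counts: dict[str, dict] = {}
    records_by_id = {r.client_id: r for r in cohort}
    baselines_phq = {cid: lab.baseline_phq for cid, lab in labels.items()}
    baselines_gad = {cid: lab.baseline_gad for cid, lab in labels.items()}

    for target in config.targets:
        t0 = time.perf_counter()
        train_set, val_set, test_set = split_data(
            cohort, labels, target, SplitSpec(seed=seeds["split"])
        )
        durations[f"split/{target}"] = time.perf_counter() - t0
        eval_set = test_set if config.evaluate_on == "test" else val_set
        baselines = baselines_phq if target == "phq9" else baselines_gad

        for model_name in config.models:
            if model_name == "rnn":
                for fs in config.feature_sets:
                    key = f"rnn/{fs}/{target}"
                    t0 = time.perf_counter()
                    model = train_rnn(
                        (train_set, labels),
                        (val_set, labels),
                        fs,
                        target,
                        config.rnn or RnnConfig(seed=seeds["train"]),
                        n_interaction_types=gen.n_interaction_types,
                    )
                    preds = predict_cohort(model, eval_set, labels, target)
                    reports[key] = stratified_evaluation(
                        preds, baselines, target, min_t=config.min_t
                    )
                    durations[key] = time.perf_counter() - t0
                    hashes[key] = _hash_frame(preds)
                    if fs == "Q":
                        errs = classify_errors(preds, records_by_id, labels, t=3, instrument=target)
                        error_counts[key] = {k: len(v) for k, v in errs.items()}
                    logger.info("%s trained+evaluated in %.1fs", key, durations[key])
            else:
                key = f"{model_name}/benchmark/{target}"
                t0 = time.perf_counter()
                if model_name == "ema":
                    model = EmaClassifier(target)
                elif model_name in STATIC_KINDS:
                    model = train_static_classifier(
                        model_name, (train_set, labels), target, seed=seeds["train"]
                    )
                else:
                    raise ValueError(f"unknown model {model_name!r}")
                preds = predict_cohort(model, eval_set, labels, target)
                reports[key] = stratified_evaluation(preds, baselines, target, min_t=config.min_t)
                durations[key] = time.perf_counter() - t0
                hashes[key] = _hash_frame(preds)
                logger.info("%s evaluated in %.1fs", key, durations[key])

    manifest = ExperimentManifest(
        config=config,
        stage_seeds=seeds,
        reports=reports,
        error_sets=error_counts,
        artifact_hashes=hashes,
        durations=durations,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest.to_json_dict(), fh, indent=2)
        for key, report in reports.items():
            path = out / (key.replace("/", "_") + ".json")
            with open(path, "w") as fh:
                json.dump(report.to_json_dict(), fh, indent=2)
    return manifest


def compare_models(reports: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """Aligned per-review-period accuracy table, one column per model.

    Rows are review periods (plus the pooled "all" row); raises when the
    reports do not share time strata.
    """
    if not reports:
        raise ValueError("no reports to compare")
    tables = {}
    strata_sets = []
    for name, report in reports.items():
        overall = report.cells[report.cells["band"] == "overall"]
        tables[name] = overall.set_index(overall["t"].astype(str))["accuracy"]
        strata_sets.append(set(tables[name].index))
    common = set.intersection(*strata_sets)
    if any(s - common for s in strata_sets):
        raise ValueError("reports have misaligned time strata")
    df = pd.DataFrame({name: series.loc[sorted(common, key=str)] for name, series in tables.items()})
    df.index.name = "t"
    return df
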