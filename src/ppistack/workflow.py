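"""Configuration-driven orchestration of the prediction pipeline.

A single YAML experiment file declares the mode (train or test), the
datasets (tab-separated pair lists), the shared annotation store, the
resource files (ontology DAG, known domain interactions, optional
precomputed sequence scores) and the parallel job count. Each dataset is
an independent job: preprocessing (ingest of any new annotation records)
-> feature generation -> classification. Jobs run in parallel up to the
configured count, but every per-dataset random stream is derived from
(global seed, dataset name), so outputs are identical to a sequential run
and independent of scheduling order. A failing dataset aborts only its
own job.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml
from joblib import Parallel, delayed

from . import classifier as clf
from .features import (
    DomainInteractionSet,
    SequenceScoreTable,
    build_feature_vector,
    canonical_pair,
)
from .kb import AnnotationStore, read_records_jsonl
from .ontology import GoDag

logger = logging.getLogger(__name__)

CONFIG_FORMAT_VERSION = 1


class ConfigError(ValueError):
    """Raised with a field-by-field diagnostic on invalid configuration."""


@dataclass
class DatasetEntry:
    name: str
    pairs_path: Path
    labeled: bool = True


@dataclass
class ExperimentConfig:
    mode: str  # train | test
    datasets: list[DatasetEntry]
    store_path: Path
    go_dag_path: Path
    domain_interactions_path: Path
    output_dir: Path
    sequence_scores_path: Optional[Path] = None
    annotations_path: Optional[Path] = None
    model_path: Optional[Path] = None
    jobs: int = 1
    seed: int = 0
    domain_denominator: str = "union"


def dataset_seed(global_seed: int, dataset_name: str) -> int:
    """Stable per-dataset seed from (global seed, dataset name)."""
    digest = hashlib.sha256(f"{global_seed}:{dataset_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate an experiment file before any computation."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: not a mapping")
    problems: list[str] = []

    mode = raw.get("mode")
    if mode not in ("train", "test"):
        problems.append(f"mode: must be 'train' or 'test', got {mode!r}")
    jobs = raw.get("jobs", 1)
    if not isinstance(jobs, int) or jobs < 1:
        problems.append(f"jobs: must be an integer >= 1, got {jobs!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed: must be an integer, got {seed!r}")

    base = path.parent

    def resolve(key: str, required: bool, must_exist: bool = True) -> Optional[Path]:
        value = raw.get(key)
        if value is None:
            if required:
                problems.append(f"{key}: required but missing")
            return None
        p = (base / value).resolve() if not Path(value).is_absolute() else Path(value)
        if must_exist and not p.exists():
            problems.append(f"{key}: path does not exist: {p}")
        return p

    resources = raw.get("resources") or {}
    raw_with_resources = dict(raw)
    raw_with_resources.update({f"resources.{k}": v for k, v in resources.items()})

    def resolve_resource(key: str, required: bool) -> Optional[Path]:
        value = resources.get(key)
        if value is None:
            if required:
                problems.append(f"resources.{key}: required but missing")
            return None
        p = (base / value).resolve() if not Path(value).is_absolute() else Path(value)
        if not p.exists():
            problems.append(f"resources.{key}: path does not exist: {p}")
        return p

    store_path = resolve("store", required=True, must_exist=False)
    go_dag = resolve_resource("go_dag", required=True)
    domain_file = resolve_resource("domain_interactions", required=True)
    seq_scores = resolve_resource("sequence_scores", required=False)
    annotations = resolve("annotations", required=False)
    output_dir = resolve("output_dir", required=True, must_exist=False)

    model_value = raw.get("model")
    model_path: Optional[Path] = None
    if model_value is not None:
        model_path = (base / model_value).resolve() if not Path(model_value).is_absolute() else Path(model_value)
    if mode == "test":
        if model_path is None:
            problems.append("model: required in test mode (a previously trained model)")
        elif not model_path.exists():
            problems.append(f"model: path does not exist: {model_path}")

    datasets: list[DatasetEntry] = []
    raw_datasets = raw.get("datasets")
    if not raw_datasets:
        problems.append("datasets: at least one dataset entry is required")
    else:
        for i, entry in enumerate(raw_datasets):
            name = entry.get("name")
            if not name:
                problems.append(f"datasets[{i}].name: required")
                continue
            pairs_value = entry.get("pairs")
            if not pairs_value:
                problems.append(f"datasets[{i}].pairs: required")
                continue
            pairs_path = (base / pairs_value).resolve() if not Path(pairs_value).is_absolute() else Path(pairs_value)
            if not pairs_path.exists():
                problems.append(f"datasets[{i}].pairs: path does not exist: {pairs_path}")
            labeled = bool(entry.get("labeled", mode == "train"))
            if mode == "train" and not labeled:
                problems.append(f"datasets[{i}]: train mode requires labels (labeled: true)")
            datasets.append(DatasetEntry(name=name, pairs_path=pairs_path, labeled=labeled))

    if problems:
        raise ConfigError(f"{path}: invalid configuration:\n  - " + "\n  - ".join(problems))
    assert store_path and go_dag and domain_file and output_dir
    return ExperimentConfig(
        mode=mode,
        datasets=datasets,
        store_path=store_path,
        go_dag_path=go_dag,
        domain_interactions_path=domain_file,
        sequence_scores_path=seq_scores,
        annotations_path=annotations,
        model_path=model_path,
        output_dir=output_dir,
        jobs=jobs,
        seed=seed,
        domain_denominator=raw.get("domain_denominator", "union"),
    )


def read_pairs_file(path: str | Path) -> tuple[list[tuple[str, str]], Optional[list[int]]]:
    """Tab-separated ``idA<TAB>idB[<TAB>label]`` with deduplication.

    (A, B) and (B, A) are the same pair (canonical order lexicographic);
    duplicates are dropped with a warning. Self-pairs are allowed. Labels
    are returned only when every line carries one.
    """
    pairs: list[tuple[str, str]] = []
    labels: list[int] = []
    seen: set[tuple[str, str]] = set()
    any_label, all_label = False, True
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated columns")
            pair = canonical_pair(parts[0].strip(), parts[1].strip())
            if pair in seen:
                logger.warning("%s:%d: duplicate pair %s dropped", path, lineno, pair)
                continue
            seen.add(pair)
            pairs.append(pair)
            if len(parts) == 3:
                label = parts[2].strip()
                if label not in ("0", "1"):
                    raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label!r}")
                labels.append(int(label))
                any_label = True
            else:
                all_label = False
    if any_label and not all_label:
        raise ValueError(f"{path}: some lines have labels and some do not")
    return pairs, labels if (any_label and all_label) else None


@dataclass
class DatasetResult:
    name: str
    status: str  # ok | failed
    error: Optional[str] = None
    outputs: dict = field(default_factory=dict)


def _process_dataset(
    entry: DatasetEntry,
    config: ExperimentConfig,
    store: AnnotationStore,
    dag: GoDag,
    known: DomainInteractionSet,
    scorer: Optional[SequenceScoreTable],
) -> DatasetResult:
    out_dir = config.output_dir / entry.name
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        pairs, labels = read_pairs_file(entry.pairs_path)
        vectors = [
            build_feature_vector(
                pair, store, dag, known, scorer, config.domain_denominator
            )
            for pair in pairs
        ]
        matrix = clf.FeatureMatrix.from_vectors(vectors, labels=labels)
        matrix.to_csv(out_dir / "features.csv")
        outputs: dict = {"features": str(out_dir / "features.csv"), "n_pairs": len(pairs)}

        if config.mode == "train":
            if labels is None:
                raise ValueError(f"dataset {entry.name}: train mode requires labeled pairs")
            model, report = clf.train(matrix, seed=dataset_seed(config.seed, entry.name))
            model_path = out_dir / "model.joblib"
            model.save(model_path)
            (out_dir / "report.json").write_text(json.dumps(report.to_json(), indent=1))
            logger.info(
                "dataset %s: confusion matrix %s", entry.name, report.confusion.tolist()
            )
            outputs.update(
                {
                    "model": str(model_path),
                    "report": str(out_dir / "report.json"),
                    "cv_accuracy": report.accuracy,
                }
            )
        else:
            assert config.model_path is not None
            model = clf.TrainedModel.load(config.model_path)
            probs, calls, positives = clf.predict(model, matrix)
            with open(out_dir / "predictions.tsv", "w") as handle:
                for pair, p, c in zip(matrix.pairs, probs, calls):
                    handle.write(f"{pair[0]}\t{pair[1]}\t{p:.10g}\t{c}\n")
            with open(out_dir / "positive_pairs.tsv", "w") as handle:
                for pair in positives:
                    handle.write(f"{pair[0]}\t{pair[1]}\n")
            outputs.update(
                {
                    "predictions": str(out_dir / "predictions.tsv"),
                    "positives": str(out_dir / "positive_pairs.tsv"),
                    "n_positive": len(positives),
                }
            )
        return DatasetResult(name=entry.name, status="ok", outputs=outputs)
    except Exception as exc:  # fail-isolation: only this dataset aborts
        logger.error("dataset %s failed: %s", entry.name, exc)
        return DatasetResult(name=entry.name, status="failed", error=str(exc))


def run_experiment(config: ExperimentConfig) -> dict[str, DatasetResult]:
    """Run every dataset job; parallel output equals sequential output."""
    store = (
        AnnotationStore.load(config.store_path)
        if Path(config.store_path).exists()
        else AnnotationStore()
    )
    ingests_before = store.ingest_count
    if config.annotations_path is not None:
        store.ingest_many(read_records_jsonl(config.annotations_path), source="annotations")
    new_ingests = store.ingest_count - ingests_before
    store.save(config.store_path)

    dag = GoDag.load(config.go_dag_path)
    known = DomainInteractionSet.load(config.domain_interactions_path)
    scorer = (
        SequenceScoreTable.load(config.sequence_scores_path)
        if config.sequence_scores_path is not None
        else None
    )

    config.output_dir.mkdir(parents=True, exist_ok=True)
    # threads, not processes: jobs share the read-only store; per-dataset
    # seeds make results independent of scheduling order
    results = Parallel(n_jobs=config.jobs, backend="threading")(
        delayed(_process_dataset)(entry, config, store, dag, known, scorer)
        for entry in config.datasets
    )
    summary = {r.name: r for r in results}
    manifest = {
        "config_format_version": CONFIG_FORMAT_VERSION,
        "mode": config.mode,
        "seed": config.seed,
        "new_ingests": new_ingests,
        "datasets": {
            name: {"status": r.status, "error": r.error, "outputs": r.outputs}
            for name, r in sorted(summary.items())
        },
    }
    (config.output_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary
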