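"""End-to-end orchestration: generate -> preprocess -> extract -> classify ->
rank, with a persisted, hashable run configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify, ranking
from .classify import COMPARISONS, DataSplit, default_grid, normalize_features, split_by_participant
from .features import FEATURE_COLUMNS, FEATURE_NAMES, extract_features, save_features
from .preprocess import FilterSpec, preprocess
from .simulate import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Flat, JSON-serializable description of one full run."""

    out_dir: str = "runs/default"
    seed: int = 0
    n_hc: int = 8
    n_mci: int = 8
    n_ppa: int = 14
    length_range_s: tuple[float, float] = (120.0, 240.0)
    rate: float = 500.0
    effect: str = "default"
    filter_order: int = 5
    detrend: str = "auto"
    backend: str = "wavelet"
    n_random: int = 20
    train_ratio: float = 0.7
    comparisons: tuple[str, ...] = tuple(COMPARISONS)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_range_s"] = list(self.length_range_s)
        d["comparisons"] = list(self.comparisons)
        return d


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def cohort_feature_table(
    seed: int,
    effect: str = "default",
    backend: str = "wavelet",
    cohort: CohortSpec | None = None,
    filter_order: int = 5,
    detrend: str = "auto",
    n_random: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort, preprocess it and extract the feature table.

    Returns (features, truth).  This is the shared entry point for the
    pipeline, the test suite and the acceptance script.
    """
    spec = cohort or CohortSpec(seed=seed, effect=effect)
    recordings, truth = generate_cohort(spec)
    fspec = FilterSpec(order=filter_order)
    epochs = []
    for rec in recordings:
        epochs.extend(preprocess(rec, spec=fspec, detrend=detrend))
    features = extract_features(
        epochs, rate=spec.rate, backend=backend, n_random=n_random, seed=seed
    )
    return features, truth


def run_all(config: RunConfig) -> Path:
    """Execute every stage and write all artifacts into the run directory."""
    unknown = [c for c in config.comparisons if c not in COMPARISONS]
    if unknown:
        raise ValueError(f"unknown comparison(s) {unknown}; expected {list(COMPARISONS)}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_hash = config_hash(config)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    t0 = time.perf_counter()
    cohort = CohortSpec(
        n_hc=config.n_hc,
        n_mci=config.n_mci,
        n_ppa=config.n_ppa,
        length_range_s=config.length_range_s,
        rate=config.rate,
        seed=config.seed,
        effect=config.effect,
    )
    features, truth = cohort_feature_table(
        seed=config.seed,
        effect=config.effect,
        backend=config.backend,
        cohort=cohort,
        filter_order=config.filter_order,
        detrend=config.detrend,
        n_random=config.n_random,
    )
    log(
        f"[{run_hash}] cohort: {len(truth)} participants, {len(features)} epochs "
        f"({time.perf_counter() - t0:.1f}s)"
    )

    (out / "config.json").write_text(
        json.dumps({"config_hash": run_hash, **config.to_dict()}, indent=2)
    )
    truth.to_csv(out / "participants.csv", index=False)
    save_features(features, out / "features.csv")

    split = split_by_participant(truth, ratio=config.train_ratio, seed=config.seed)
    (out / "split.json").write_text(
        json.dumps(
            {
                "config_hash": run_hash,
                "train": list(split.train_participants),
                "test": list(split.test_participants),
            },
            indent=2,
        )
    )

    reports_dir = out / "reports"
    rankings_dir = out / "rankings"
    reports_dir.mkdir(exist_ok=True)
    rankings_dir.mkdir(exist_ok=True)
    summary = {"config_hash": run_hash, "comparisons": {}}
    for comparison in config.comparisons:
        t1 = time.perf_counter()
        results = classify.grid_search(features, split, comparison)
        best_spec, best_report = results[0]
        payload = {"config_hash": run_hash, "best": best_report.to_dict()}
        payload["grid"] = [
            {
                "classifier": spec.label(),
                "epoch_accuracy": rep.epoch_accuracy,
                "participant_accuracy": rep.participant_accuracy,
            }
            for spec, rep in results
        ]
        (reports_dir / f"{comparison}.json").write_text(json.dumps(payload, indent=2))

        table = _rank_comparison(features, split, comparison)
        table.to_csv(rankings_dir / f"{comparison}.csv", index=False)
        summary["comparisons"][comparison] = {
            "best_classifier": best_spec.label(),
            "epoch_accuracy": best_report.epoch_accuracy,
            "participant_accuracy": best_report.participant_accuracy,
        }
        log(
            f"[{run_hash}] {comparison}: best {best_spec.label()} "
            f"participant test acc {best_report.participant_accuracy['test']:.2f}% "
            f"({time.perf_counter() - t1:.1f}s)"
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


def _rank_comparison(
    features: pd.DataFrame, split: DataSplit, comparison: str
) -> pd.DataFrame:
    """C4.5 gain-ratio ranking of the 113 features on the training epochs."""
    classes = COMPARISONS[comparison]
    df = features[features["group"].isin(classes)]
    train = df[df["participant_id"].isin(split.train_participants)].reset_index(drop=True)
    cols = list(FEATURE_COLUMNS)
    train_n, _ = normalize_features(train, feature_cols=cols)
    tree = ranking.build_tree(train_n[cols].to_numpy(), train_n["group"].to_numpy())
    ranked = ranking.rank_features(tree, n_features=len(cols))
    return ranking.ranking_table(ranked, list(FEATURE_NAMES))
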