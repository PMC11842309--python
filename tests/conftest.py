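"""Shared fixtures and memoized full-pipeline runs.

The end-to-end recovery checks and the acceptance suite both need grid-search
results on seeded synthetic cohorts; those runs are memoized per seed so each
cohort is generated and featurized exactly once per session.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest

from rwefc.classify import evaluate, grid_search, knn, split_by_participant
from rwefc.pipeline import cohort_feature_table
from rwefc.recording import CANONICAL_CHANNELS, RawRecording

PAIRWISE = ("hc-mci", "hc-ppa", "mci-ppa")
ALL_COMPARISONS = PAIRWISE + ("hc-mci-ppa",)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_recording(
    data: np.ndarray,
    rate: float = 500.0,
    group: str = "HC",
    powerline_hz: float = 50.0,
    labels: tuple[str, ...] | None = None,
) -> RawRecording:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = CANONICAL_CHANNELS[: data.shape[0]]
    return RawRecording(
        participant_id="P01",
        group=group,
        data=data,
        rate=rate,
        channel_labels=labels,
        powerline_hz=powerline_hz,
    )


@functools.lru_cache(maxsize=None)
def recovery_run(seed: int) -> dict[str, float]:
    """Best grid-search test participant accuracy per comparison on the
    default synthetic cohort at ``seed``."""
    features, truth = cohort_feature_table(seed=seed, effect="default")
    split = split_by_participant(truth, seed=seed)
    out = {}
    for comparison in ALL_COMPARISONS:
        results = grid_search(features, split, comparison)
        out[comparison] = results[0][1].participant_accuracy["test"]
    return out


@functools.lru_cache(maxsize=None)
def zero_effect_run(seed: int) -> dict[str, float]:
    """Fixed-classifier (kNN k=1 cityblock) test participant accuracy per
    comparison on a zero-effect cohort; the fixed spec avoids the selection
    inflation of picking the grid maximum on a tiny test set."""
    features, truth = cohort_feature_table(seed=seed, effect="none")
    split = split_by_participant(truth, seed=seed)
    spec = knn(1, "cityblock")
    return {
        comparison: evaluate(features, split, spec, comparison).participant_accuracy["test"]
        for comparison in ALL_COMPARISONS
    }
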