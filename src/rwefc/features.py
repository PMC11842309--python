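"""Assembly of the 113-feature epoch descriptor and the feature table.

Ordering contract (stable; feature ranking depends on it):

* f001-f056: RWE functional connectivity, row-major over the canonical
  channel order F7, T7, CP3, P5, F8, T8, CP4, P6, skipping the diagonal.
* f057-f068: graph metrics -- CC per electrode (canonical order), CPL, CPE,
  CD, SW.
* f069-f113: energy ratios -- whole-EEG (delta..gamma), then five per
  electrode in canonical order.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import GRAPH_FEATURE_NAMES, graph_features
from .recording import CANONICAL_CHANNELS, Epoch
from .spectral import (
    BAND_NAMES,
    assemble_feature_vector,
    band_energies,
    fc_features,
    relative_energies,
    rwe_matrix,
)

N_FEATURES = 113


def _build_feature_names() -> tuple[str, ...]:
    names = [
        f"rwe_{a}_{b}" for a in CANONICAL_CHANNELS for b in CANONICAL_CHANNELS if a != b
    ]
    names.extend(GRAPH_FEATURE_NAMES)
    names.extend(f"energy_all_{band}" for band in BAND_NAMES)
    names.extend(f"energy_{ch}_{band}" for ch in CANONICAL_CHANNELS for band in BAND_NAMES)
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _build_feature_names()
FEATURE_COLUMNS: tuple[str, ...] = tuple(f"f{i + 1:03d}" for i in range(N_FEATURES))


def feature_name_map() -> dict[str, str]:
    """Machine-readable column-id -> feature-name map."""
    return dict(zip(FEATURE_COLUMNS, FEATURE_NAMES))


def sw_seed_for(seed: int, participant_id: str, epoch_index: int) -> int:
    """Stable per-epoch seed for the small-world null ensemble."""
    return zlib.crc32(f"{seed}:{participant_id}:{epoch_index}".encode()) & 0x7FFFFFFF


def epoch_feature_vector(
    epoch: Epoch,
    rate: float = 500.0,
    backend: str = "wavelet",
    epsilon: float = 1e-12,
    tau: float | None = None,
    n_random: int = 20,
    sw_seed: int = 0,
) -> np.ndarray:
    """The ordered 113-element descriptor of one 8-channel epoch.

    Band energies are computed once and shared by the connectivity and
    energy-ratio blocks, which keeps the composite numerically identical to
    the standalone operations.
    """
    if epoch.data.shape[0] != 8:
        raise ValueError(f"feature extraction expects 8 channels, got {epoch.data.shape[0]}")
    energies = band_energies(epoch.data, rate, backend=backend)
    totals = energies.sum(axis=-1)
    if np.any(totals <= 0):
        bad = CANONICAL_CHANNELS[int(np.argmax(totals <= 0))]
        raise ValueError(f"channel {bad} has zero band energy")
    P = energies / totals[:, None]
    W = rwe_matrix(P, epsilon=epsilon)
    fc = fc_features(W)
    graph = graph_features(W, tau=tau, n_random=n_random, seed=sw_seed).values
    energy = np.concatenate([relative_energies(energies.sum(axis=0)), P.ravel()])
    return assemble_feature_vector(fc, graph, energy)


def extract_features(
    epochs: list[Epoch],
    rate: float = 500.0,
    backend: str = "wavelet",
    tau: float | None = None,
    n_random: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature table: one row per epoch with participant_id, group,
    epoch_index and columns f001..f113."""
    rows = []
    for ep in epochs:
        vec = epoch_feature_vector(
            ep,
            rate=rate,
            backend=backend,
            tau=tau,
            n_random=n_random,
            sw_seed=sw_seed_for(seed, ep.participant_id, ep.index),
        )
        row = {"participant_id": ep.participant_id, "group": ep.group, "epoch_index": ep.index}
        row.update(zip(FEATURE_COLUMNS, vec))
        rows.append(row)
    return pd.DataFrame(rows)


def save_features(features: pd.DataFrame, path: str | Path) -> Path:
    """Write the feature CSV plus the column-name map JSON next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(path, index=False)
    path.with_name("feature_map.json").write_text(json.dumps(feature_name_map(), indent=2))
    return path
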