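"""Containers and file I/O for multichannel resting-state EEG recordings.

A recording is a channel x sample matrix in microvolts plus the metadata
needed downstream: sampling rate, ordered channel labels, powerline frequency
of the recording site, participant id and diagnostic group.  Recordings are
read either from EDF files (via :mod:`mne`, optional dependency) or from a
plain delimited numeric matrix with a JSON metadata sidecar.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

GROUPS = ("HC", "MCI", "PPA")

#: The eight 10-10 electrodes shared by both source montages, in the fixed
#: order every downstream feature block depends on.
CANONICAL_CHANNELS = ("F7", "T7", "CP3", "P5", "F8", "T8", "CP4", "P6")
LEFT_CHANNELS = CANONICAL_CHANNELS[:4]
RIGHT_CHANNELS = CANONICAL_CHANNELS[4:]

EPOCH_SECONDS = 8.192

_CANONICAL_BY_UPPER = {name.upper(): name for name in CANONICAL_CHANNELS}


def epoch_samples(rate: float, epoch_s: float = EPOCH_SECONDS) -> int:
    """Number of samples in one epoch (4096 at 500 Hz)."""
    return int(round(rate * epoch_s))


def canonicalize_label(label: str) -> str:
    """Map a raw channel label onto its canonical 10-10 name if it is one of
    the eight channels used here; unknown labels are preserved verbatim."""
    stripped = str(label).strip()
    return _CANONICAL_BY_UPPER.get(stripped.upper(), stripped)


@dataclass
class RawRecording:
    """One participant's continuous multichannel EEG plus metadata."""

    participant_id: str
    group: str
    data: np.ndarray  # channel x sample, microvolts
    rate: float = 500.0
    channel_labels: tuple[str, ...] = CANONICAL_CHANNELS
    powerline_hz: float = 50.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("data must be a channel x sample matrix with >=1 channel")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.powerline_hz not in (50, 60):
            raise ValueError("powerline_hz must be 50 or 60")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def with_data(self, data: np.ndarray) -> "RawRecording":
        """Copy of this recording with replaced sample data (same metadata)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class Epoch:
    """One 8.192 s channel x sample segment; the unit of feature extraction."""

    participant_id: str
    group: str
    index: int
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.index < 0:
            raise ValueError("epoch index must be >= 0")


def _load_matrix(path: Path) -> np.ndarray:
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    return np.atleast_2d(np.loadtxt(path, delimiter=delimiter))


def read_recording(path: str | Path, metadata: dict | None = None) -> RawRecording:
    """Read a recording from an EDF file or a delimited matrix + JSON sidecar.

    ``metadata`` overrides/supplies the sidecar fields ``participant_id``,
    ``group``, ``rate``, ``labels`` and ``powerline_hz``.  Channel labels are
    mapped onto canonical 10-10 names where recognized.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError("reading EDF files requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        meta["rate"] = float(raw.info["sfreq"])
        meta["labels"] = list(raw.ch_names)
        meta["data"] = data
    else:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta.update(json.loads(sidecar.read_text()))
        meta["data"] = _load_matrix(path)
    if metadata:
        meta.update(metadata)
    if "rate" not in meta:
        raise ValueError(f"no sampling rate available for {path}")
    data = meta["data"]
    labels = meta.get("labels", [f"ch{i}" for i in range(data.shape[0])])
    if len(labels) != data.shape[0]:
        raise ValueError(f"{len(labels)} labels for {data.shape[0]} data rows in {path}")
    return RawRecording(
        participant_id=str(meta.get("participant_id", path.stem)),
        group=meta.get("group", "HC"),
        data=data,
        rate=float(meta["rate"]),
        channel_labels=tuple(canonicalize_label(c) for c in labels),
        powerline_hz=float(meta.get("powerline_hz", 50)),
    )


def write_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording as a tab-delimited matrix with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.8g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "rate": rec.rate,
                "labels": list(rec.channel_labels),
                "powerline_hz": rec.powerline_hz,
            },
            indent=2,
        )
    )
    return path


def write_epochs(epochs: list[Epoch], directory: str | Path) -> Path:
    """Write epochs as one matrix file each plus a CSV index manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "group", "epoch_index", "file"])
        for ep in epochs:
            name = f"{ep.participant_id}_epoch{ep.index:03d}.tsv"
            np.savetxt(directory / name, ep.data, delimiter="\t", fmt="%.8g")
            writer.writerow([ep.participant_id, ep.group, ep.index, name])
    return manifest


def read_epochs(directory: str | Path) -> list[Epoch]:
    """Read an epoch store written by :func:`write_epochs`."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(manifest)
    epochs = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            data = np.atleast_2d(np.loadtxt(directory / row["file"], delimiter="\t"))
            epochs.append(
                Epoch(row["participant_id"], row["group"], int(row["epoch_index"]), data)
            )
    return epochs
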