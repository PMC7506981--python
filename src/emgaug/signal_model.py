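"""Core domain types for multichannel sEMG recordings and labelled datasets.

A recording is a ``time x channel`` matrix with a sampling rate; a dataset
is a list of recordings with gesture / repetition / subject metadata.
Train-validation-test partitioning is repetition-based: every window cut
from a given gesture repetition lands in exactly one split, which prevents
overlapping windows of the same physical signal from leaking between
training and evaluation sets.

Datasets round-trip through a plain-text container: one CSV per recording
(one row per sample, one column per channel) plus a JSON manifest with the
sampling rate and per-record metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DatasetIOError

__all__ = [
    "MultichannelSignal",
    "RecordingMeta",
    "LabeledDataset",
    "split_by_repetition",
    "balance_classes",
    "read_dataset",
    "write_dataset",
]

REAL = "real"
AUGMENTED = "augmented"


@dataclass(frozen=True)
class MultichannelSignal:
    """A ``(n_samples, n_channels)`` signal matrix with its sampling rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        if samples.ndim != 2 or samples.shape[0] < 1 or samples.shape[1] < 1:
            raise ValueError("samples must be a non-empty (time, channel) matrix")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def channel_count(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "MultichannelSignal":
        """Same sampling rate, new sample matrix."""
        return MultichannelSignal(samples, self.fs)


@dataclass(frozen=True)
class RecordingMeta:
    """Who / what / which take, plus augmentation provenance."""

    subject_id: str
    gesture_label: int
    repetition: int
    origin: str = REAL
    lineage: tuple[str, ...] = ()

    def __post_init__(self):
        if self.gesture_label < 0:
            raise ValueError("gesture_label must be >= 0")
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")
        if self.origin not in (REAL, AUGMENTED):
            raise ValueError(f"origin must be 'real' or 'augmented', got {self.origin!r}")
        object.__setattr__(self, "lineage", tuple(self.lineage))
        if (self.origin == REAL) != (len(self.lineage) == 0):
            raise ValueError("origin='real' iff lineage is empty")

    def derived(self, lineage: Sequence[str]) -> "RecordingMeta":
        """Metadata for an augmented copy of this record."""
        return replace(
            self,
            origin=AUGMENTED,
            lineage=self.lineage + tuple(lineage),
        )


@dataclass
class LabeledDataset:
    """A list of ``(signal, meta)`` pairs sharing fs and channel count."""

    records: list[tuple[MultichannelSignal, RecordingMeta]] = field(default_factory=list)

    def __post_init__(self):
        if self.records:
            fs0 = self.records[0][0].fs
            c0 = self.records[0][0].channel_count
            for sig, _ in self.records:
                if sig.fs != fs0:
                    raise DatasetIOError(
                        f"mixed sampling rates in dataset: {fs0} Hz vs {sig.fs} Hz"
                    )
                if sig.channel_count != c0:
                    raise DatasetIOError(
                        f"ragged channel counts in dataset: {c0} vs {sig.channel_count}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[MultichannelSignal, RecordingMeta]]:
        return iter(self.records)

    @property
    def fs(self) -> float:
        if not self.records:
            raise ValueError("empty dataset has no sampling rate")
        return self.records[0][0].fs

    @property
    def channel_count(self) -> int:
        if not self.records:
            raise ValueError("empty dataset has no channel count")
        return self.records[0][0].channel_count

    def repetitions(self) -> set[int]:
        return {meta.repetition for _, meta in self.records}

    def gesture_labels(self) -> set[int]:
        return {meta.gesture_label for _, meta in self.records}


DEFAULT_TEST_REPS = frozenset({5})
DEFAULT_VAL_REPS = frozenset({4})


def split_by_repetition(
    ds: LabeledDataset,
    train_reps: Iterable[int],
    val_reps: Iterable[int],
    test_reps: Iterable[int],
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Partition a dataset by gesture repetition index.

    Every repetition present in ``ds`` must belong to exactly one of the
    three sets; augmented records follow the split of their source
    repetition (they carry it in their metadata).  The default convention
    used elsewhere in the package reserves repetition 5 for testing and
    repetition 4 for validation.
    """
    train, val, test = set(train_reps), set(val_reps), set(test_reps)
    overlap = (train & val) | (train & test) | (val & test)
    if overlap:
        raise ConfigurationError(
            f"split sets overlap on repetitions {sorted(overlap)}"
        )
    covered = train | val | test
    missing = sorted(ds.repetitions() - covered)
    if missing:
        raise ConfigurationError(
            f"repetitions {missing} present in dataset but assigned to no split"
        )
    buckets: dict[str, list] = {"train": [], "val": [], "test": []}
    for sig, meta in ds:
        if meta.repetition in train:
            buckets["train"].append((sig, meta))
        elif meta.repetition in val:
            buckets["val"].append((sig, meta))
        else:
            buckets["test"].append((sig, meta))
    return (
        LabeledDataset(buckets["train"]),
        LabeledDataset(buckets["val"]),
        LabeledDataset(buckets["test"]),
    )


def balance_classes(segs, rng_seed: int):
    """Equalize per-gesture segment counts by random removal.

    Gesture durations vary, so sliding-window segmentation over-represents
    long gestures; surplus segments of each over-represented label are
    removed uniformly at random (deterministic under ``rng_seed``) until
    every label matches the pre-balance minimum count.  Accepts any
    segment container exposing ``labels`` and ``subset(indices)``
    (see :class:`emgaug.windowing.SegmentSet`).
    """
    labels = np.asarray(segs.labels)
    if labels.size == 0:
        raise ValueError("cannot balance an empty segment set")
    uniq, counts = np.unique(labels, return_counts=True)
    target = int(counts.min())
    rng = np.random.default_rng(rng_seed)
    keep: list[np.ndarray] = []
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        if len(idx) > target:
            idx = rng.choice(idx, size=target, replace=False)
        keep.append(np.sort(idx))
    order = np.sort(np.concatenate(keep))
    return segs.subset(order)


# --------------------------------------------------------------------------
# Manifest I/O


def write_dataset(ds: LabeledDataset, dir_path) -> Path:
    """Write one CSV per record plus ``manifest.json``; returns manifest path.

    Floats are printed with 17 significant digits so the write -> read
    round trip reproduces samples exactly.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (sig, meta) in enumerate(ds):
        rel = f"rec_{i:05d}.csv"
        cols = [f"ch{c}" for c in range(sig.channel_count)]
        pd.DataFrame(sig.samples, columns=cols).to_csv(
            out / rel, index=False, float_format="%.17g"
        )
        entries.append(
            {
                "path": rel,
                "subject": meta.subject_id,
                "gesture": int(meta.gesture_label),
                "repetition": int(meta.repetition),
                "origin": meta.origin,
                "lineage": list(meta.lineage),
            }
        )
    manifest = {"fs_hz": ds.fs if ds.records else None, "records": entries}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_dataset(manifest_path) -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`.

    Raises :class:`DatasetIOError` for a missing record file, a per-record
    ``fs_hz`` that contradicts the manifest rate, or ragged channel counts.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DatasetIOError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    fs = manifest.get("fs_hz")
    root = manifest_path.parent
    records = []
    for entry in manifest.get("records", []):
        rec_fs = entry.get("fs_hz", fs)
        if fs is not None and rec_fs != fs:
            raise DatasetIOError(
                f"sampling-rate mismatch: manifest says {fs} Hz but record "
                f"{entry['path']!r} says {rec_fs} Hz"
            )
        csv_path = root / entry["path"]
        if not csv_path.exists():
            raise DatasetIOError(f"record file not found: {csv_path}")
        samples = pd.read_csv(csv_path, float_precision="round_trip").to_numpy(
            dtype=float
        )
        sig = MultichannelSignal(samples, rec_fs)
        meta = RecordingMeta(
            subject_id=str(entry["subject"]),
            gesture_label=int(entry["gesture"]),
            repetition=int(entry["repetition"]),
            origin=entry.get("origin", REAL),
            lineage=tuple(entry.get("lineage", ())),
        )
        records.append((sig, meta))
    return LabeledDataset(records)
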