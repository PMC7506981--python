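"""Sliding-window segmentation into L x C input images.

A record of length ``n`` yields windows starting at ``0, tau, 2*tau, ...``
while the whole window fits: ``floor((n - L) / tau) + 1`` windows.
Windows never span record boundaries, so repetition-based splits stay
leak-free by construction.  ``tau = L`` tiles the record without overlap;
``tau < L`` produces overlapping windows — the "sliding window" form of
augmentation.  The presets SW(15) and SW(01) are L = 15 with step 15 and
1 respectively, i.e. 150 ms images at the 100 Hz envelope rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .signal_model import LabeledDataset

__all__ = [
    "WindowingConfig",
    "SegmentSet",
    "segment",
    "count_windows",
    "sw_preset",
    "flatten_segments",
    "save_segments",
    "load_segments",
]

logger = logging.getLogger(__name__)

META_COLUMNS = ["record", "start", "subject", "gesture", "repetition", "origin"]


@dataclass(frozen=True)
class WindowingConfig:
    """Window length L and step tau, both in samples, 1 <= tau <= L."""

    L: int
    tau: int

    def __post_init__(self):
        if self.L < 1:
            raise ParameterError("window length L must be >= 1")
        if not 1 <= self.tau <= self.L:
            raise ParameterError(
                f"step tau must lie in [1, L]=[1, {self.L}], got {self.tau}"
            )


def sw_preset(name: str) -> WindowingConfig:
    """The named baselines: ``'SW(15)'`` -> (15, 15), ``'SW(01)'`` -> (15, 1)."""
    presets = {"SW(15)": WindowingConfig(15, 15), "SW(01)": WindowingConfig(15, 1)}
    try:
        return presets[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None


def count_windows(n_samples: int, L: int, tau: int) -> int:
    """Closed-form window count: ``floor((n - L) / tau) + 1``, or 0 if n < L."""
    if L < 1 or not 1 <= tau <= L:
        raise ParameterError(f"invalid windowing (L={L}, tau={tau})")
    if n_samples < L:
        return 0
    return (n_samples - L) // tau + 1


@dataclass
class SegmentSet:
    """A stack of L x C images with per-image provenance.

    ``images`` has shape ``(n_segments, L, C)``; ``meta`` is a DataFrame
    with columns record / start / subject / gesture / repetition /
    origin, one row per image.
    """

    images: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, L, C) array")
        if len(self.meta) != len(self.images):
            raise ValueError("meta rows must match image count")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["gesture"].to_numpy()

    @property
    def window_shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def subset(self, indices) -> "SegmentSet":
        indices = np.asarray(indices, dtype=int)
        return SegmentSet(self.images[indices], self.meta.iloc[indices])

    def label_counts(self) -> dict[int, int]:
        counts = self.meta["gesture"].value_counts()
        return {int(k): int(v) for k, v in counts.items()}


def segment(ds: LabeledDataset, cfg: WindowingConfig) -> SegmentSet:
    """Cut every record into L x C windows with step tau.

    Records shorter than L yield no windows (a warning is logged);
    trailing samples that do not fill a window are dropped rather than
    padded, because padding would fabricate signal.
    """
    images = []
    rows = []
    for rec_idx, (sig, meta) in enumerate(ds):
        n = sig.n_samples
        k = count_windows(n, cfg.L, cfg.tau)
        if k == 0:
            logger.warning(
                "record %d (len %d) shorter than window L=%d; skipped",
                rec_idx, n, cfg.L,
            )
            continue
        for w in range(k):
            start = w * cfg.tau
            images.append(sig.samples[start : start + cfg.L])
            rows.append(
                (rec_idx, start, meta.subject_id, meta.gesture_label,
                 meta.repetition, meta.origin)
            )
    if images:
        stack = np.stack(images)
    else:
        c = ds.channel_count if len(ds) else 0
        stack = np.empty((0, cfg.L, c))
    meta_df = pd.DataFrame(rows, columns=META_COLUMNS)
    return SegmentSet(stack, meta_df)


def flatten_segments(segs: SegmentSet) -> tuple[np.ndarray, np.ndarray]:
    """Flatten each L x C image to a feature vector; returns (X, labels)."""
    n = len(segs)
    return segs.images.reshape(n, -1), segs.labels.copy()


def save_segments(segs: SegmentSet, path, fmt: str = "csv"):
    """Serialize a segment set.

    ``fmt='csv'`` writes a directory with ``meta.csv``, ``images.csv``
    (one flattened L*C row per image, 17 significant digits) and a small
    ``shape.json``; ``fmt='hdf5'`` writes a single ``.h5`` file with an
    ``images`` dataset and a metadata table.
    """
    import json
    from pathlib import Path

    path = Path(path)
    L, C = (segs.images.shape[1], segs.images.shape[2])
    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        segs.meta.to_csv(path / "meta.csv", index=False)
        flat = segs.images.reshape(len(segs), -1)
        pd.DataFrame(flat).to_csv(path / "images.csv", index=False,
                                  float_format="%.17g")
        (path / "shape.json").write_text(json.dumps({"L": L, "C": C}))
        return path
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=segs.images)
            grp = f.create_group("meta")
            for col in META_COLUMNS:
                vals = segs.meta[col].to_numpy()
                if vals.dtype.kind in "OU":
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)
        return path
    raise ParameterError(f"unknown segment format {fmt!r}")


def load_segments(path, fmt: str = "csv") -> SegmentSet:
    """Inverse of :func:`save_segments`."""
    import json
    from pathlib import Path

    path = Path(path)
    if fmt == "csv":
        meta = pd.read_csv(path / "meta.csv")
        shape = json.loads((path / "shape.json").read_text())
        flat = pd.read_csv(path / "images.csv",
                           float_precision="round_trip").to_numpy(dtype=float)
        images = flat.reshape(len(meta), shape["L"], shape["C"])
        return SegmentSet(images, meta)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            images = f["images"][...]
            cols = {}
            for col in META_COLUMNS:
                vals = f["meta"][col][...]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
        return SegmentSet(images, pd.DataFrame(cols))
    raise ParameterError(f"unknown segment format {fmt!r}")
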