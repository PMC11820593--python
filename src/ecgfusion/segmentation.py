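"""Slice ECG records into labeled 5-second windows and build splits.

A window covers the half-open sample interval ``[start, start + W)``
with ``W = window_s * fs`` (1800 points at 360 Hz) and inherits the
AAMI labels of every beat annotated inside it. One label per slice is
then decided by four rules:

1. all beats normal -> N;
2. exactly one abnormal type present -> that type;
3. several abnormal types -> the most frequent abnormal type;
4. tie in counts -> the abnormal type occurring first in the slice.

This avoids any R-peak detection: beat positions come from the
annotation stream only. Overlap between neighbouring slices (default
50%) multiplies the number of usable samples.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .balance import SMOTEConfig, smote_oversample
from .io_wfdb import ECGRecord

__all__ = [
    "EmptySliceError",
    "LabeledSegment",
    "SegmentSet",
    "SliceConfig",
    "label_slice",
    "make_segments",
    "partition",
    "slice_record",
    "validation_split",
]

AAMI_CLASSES = ("N", "S", "V", "F", "Q")


class EmptySliceError(ValueError):
    """Raised when a slice contains no beats to label."""


@dataclass(frozen=True)
class SliceConfig:
    """Window geometry: 5 s windows at 360 Hz with 50% overlap."""

    window_s: float = 5.0
    overlap_fraction: float = 0.5
    fs: float = 360.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        w = self.window_s * self.fs
        if abs(w - round(w)) > 1e-9 or w <= 0:
            raise ValueError("window_s * fs must be a positive whole number")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def stride(self) -> int:
        stride = int(round(self.window_samples * (1.0 - self.overlap_fraction)))
        return max(stride, 1)


@dataclass
class LabeledSegment:
    """A fixed-length 1-D slice with a single AAMI class label."""

    samples: np.ndarray
    label: str
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.label not in AAMI_CLASSES:
            raise ValueError(f"label must be one of {AAMI_CLASSES}, got {self.label!r}")


def slice_record(
    record: ECGRecord, cfg: SliceConfig | None = None, lead: int = 0
) -> list[tuple[np.ndarray, list[str], int]]:
    """Cut one lead into overlapping windows.

    Returns ``(window_samples, beat_labels, start_index)`` triples where
    ``beat_labels`` are the AAMI classes of the beats inside the
    half-open window, in order of occurrence. The trailing partial
    window is dropped.
    """
    cfg = cfg or SliceConfig(fs=record.fs)
    w, stride = cfg.window_samples, cfg.stride
    sig = record.lead(lead)
    if sig.size < w:
        raise ValueError(f"record of {sig.size} samples shorter than one {w} window")
    beats = record.aami_labels()
    idx = np.array([i for i, _ in beats], dtype=int)
    labels = [s for _, s in beats]
    out = []
    for start in range(0, sig.size - w + 1, stride):
        inside = np.where((idx >= start) & (idx < start + w))[0]
        out.append((sig[start : start + w], [labels[j] for j in inside], start))
    return out


def label_slice(beat_labels: Sequence[str]) -> str:
    """Assign one AAMI label to a slice from its beat labels (rules 1-4)."""
    if len(beat_labels) == 0:
        raise EmptySliceError("no beats in slice")
    abnormal = [b for b in beat_labels if b != "N"]
    if not abnormal:
        return "N"
    counts = Counter(abnormal)
    best = max(counts.values())
    tied = {c for c, n in counts.items() if n == best}
    if len(tied) == 1:
        return next(iter(tied))
    for b in abnormal:  # tie: first-occurring abnormal type wins
        if b in tied:
            return b
    raise AssertionError("unreachable")


def make_segments(
    record: ECGRecord, cfg: SliceConfig | None = None, lead: int = 0
) -> list[LabeledSegment]:
    """Slice and label a record; windows without beats are skipped."""
    out = []
    for samples, labels, start in slice_record(record, cfg, lead):
        if not labels:
            continue
        out.append(
            LabeledSegment(samples, label_slice(labels), f"{record.name}@{start}")
        )
    return out


@dataclass
class SegmentSet:
    """Array-backed collection of segments for model consumption.

    ``synthetic`` flags SMOTE-generated rows so evaluation can exclude
    them.
    """

    X: np.ndarray
    y: np.ndarray
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.y), dtype=bool)
        if not (len(self.X) == len(self.y) == len(self.synthetic)):
            raise ValueError("X, y and synthetic must have equal length")

    @classmethod
    def from_segments(cls, segments: Iterable[LabeledSegment]) -> "SegmentSet":
        segments = list(segments)
        if not segments:
            raise ValueError("no segments")
        X = np.stack([s.samples for s in segments])
        y = np.array([s.label for s in segments])
        return cls(X=X, y=y)

    def __len__(self) -> int:
        return len(self.y)

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def validation_split(
    data: SegmentSet, val_fraction: float = 0.3, seed: int = 0
) -> tuple[SegmentSet, SegmentSet]:
    """Stratified validation/training split of an (already balanced) set.

    The validation side receives ``ceil(val_fraction * n)`` samples, so
    a fractional share rounds toward validation.
    """
    idx = np.arange(len(data))
    train_idx, val_idx = train_test_split(
        idx, test_size=val_fraction, stratify=data.y, random_state=seed % (2**31)
    )
    pick = lambda i: SegmentSet(data.X[i], data.y[i], data.synthetic[i])  # noqa: E731
    return pick(train_idx), pick(val_idx)


def partition(
    segments: Iterable[LabeledSegment] | SegmentSet,
    test_fraction: float = 0.2,
    val_fraction: float = 0.3,
    seed: int = 0,
    smote: SMOTEConfig | None = None,
) -> tuple[SegmentSet, SegmentSet, SegmentSet]:
    """Split into (train, val, test) with SMOTE balancing.

    ``test_fraction`` of the segments is held out first (stratified by
    label) and never participates in SMOTE neighbour search; the
    remainder is SMOTE-balanced and then split ``val_fraction`` /
    ``1 - val_fraction`` into validation and training.
    """
    data = (
        segments
        if isinstance(segments, SegmentSet)
        else SegmentSet.from_segments(segments)
    )
    counts = data.class_counts()
    if any(c < 2 for c in counts.values()):
        small = [k for k, c in counts.items() if c < 2]
        raise ValueError(f"classes with < 2 members cannot be stratified: {small}")
    idx = np.arange(len(data))
    rest_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=data.y, random_state=seed % (2**31)
    )
    test = SegmentSet(data.X[test_idx], data.y[test_idx])
    rest = SegmentSet(data.X[rest_idx], data.y[rest_idx])
    balanced = smote_oversample(rest, smote or SMOTEConfig(seed=seed))
    train, val = validation_split(balanced, val_fraction, seed=seed + 1)
    return train, val, test
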