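"""Beat-level preprocessing: R-peak detection, windowing, standardization,
class balancing and dataset splitting.

R peaks are located with the classic Pan-Tompkins chain: 5-15 Hz band-pass,
differentiation, squaring, 150 ms moving-window integration, then dual
adaptive thresholds with RR-based search-back; each detection is refined to
the local maximum of the band-passed signal. Beats are cut into 360-sample
windows with the R peak at offset 179 (179 samples of context before the
peak, 180 after), Z-scored per segment, balanced by random over/under
sampling, and split into train/validation/test parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks
from scipy.stats import zscore as _scipy_zscore
from sklearn.model_selection import train_test_split

from .io import CLASS_LABELS, ECGRecord

logger = logging.getLogger(__name__)

#: Standard window geometry at 360 Hz: one second per beat, R at offset 179.
SEGMENT_LENGTH = 360
R_OFFSET = 179


class RecordTooShortError(ValueError):
    """Record shorter than the detector needs for threshold adaptation."""


class ZeroVarianceError(ValueError):
    """A constant segment cannot be Z-scored."""


class MissingClassError(KeyError):
    """A class requested for balancing is absent from the dataset."""


@dataclass(frozen=True)
class RPeakSet:
    """Detected (or ground-truth) R-peak sample positions."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("R-peak indices must be non-negative")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class Segment:
    """One fixed-length heartbeat window.

    ``r_offset`` is the position of the R peak inside ``samples`` (179 for
    the standard one-second window at 360 Hz). ``standardized`` records
    whether the window has been Z-scored (``None`` = unknown provenance,
    e.g. read back from CSV).
    """

    samples: np.ndarray
    r_offset: int = R_OFFSET
    label: str | None = None
    standardized: bool | None = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("segment samples must be a 1-D array of length >= 2")
        if not 0 <= self.r_offset < self.samples.size:
            raise ValueError("r_offset must fall inside the segment")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class SegmentDataset:
    """A bag of segments with bookkeeping for reproducibility."""

    segments: list[Segment]
    provenance: dict = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for seg in self.segments:
            if seg.label is not None:
                counts[seg.label] = counts.get(seg.label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------- detection

def _pan_tompkins_stages(record: ECGRecord):
    """Band-pass, derivative, squaring and integration stages."""
    fs = record.fs
    nyq = fs / 2.0
    b, a = butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    bandpassed = filtfilt(b, a, record.samples)
    # five-point derivative (1/8)[-1 -2 0 2 1], sign-symmetric before squaring
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bandpassed, kernel, mode="same")
    squared = deriv * deriv
    win = max(int(round(0.150 * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")
    return bandpassed, integrated


def detect_rpeaks(record: ECGRecord) -> RPeakSet:
    """Pan-Tompkins QRS detection with adaptive thresholds and search-back.

    Returns R indices refined to the local maximum of the band-passed
    signal within ±75 ms of each integrated-signal detection.

    Raises
    ------
    RecordTooShortError
        If the record is shorter than 2 s (threshold learning phase).
    """
    fs = record.fs
    if len(record) < int(2.0 * fs):
        raise RecordTooShortError(
            f"need >= 2 s of signal at {fs:g} Hz, got {len(record)} samples")
    bandpassed, integrated = _pan_tompkins_stages(record)

    refractory = int(round(0.200 * fs))
    peaks, _ = find_peaks(integrated, distance=refractory)
    peaks = peaks[integrated[peaks] > 1e-12]     # all-zero signals yield nothing
    if peaks.size == 0:
        return RPeakSet(indices=np.array([], dtype=np.int64), fs=fs)

    # learning phase: initialize signal/noise running estimates from 2 s
    learn = integrated[: int(2.0 * fs)]
    spki = 0.25 * float(learn.max())
    npki = 0.5 * float(learn.mean())

    detections: list[int] = []
    rr_history: list[float] = []
    last_missed: int | None = None
    for p in peaks:
        level = integrated[p]
        threshold1 = npki + 0.25 * (spki - npki)
        if level > threshold1:
            if detections:
                rr_history.append(p - detections[-1])
                rr_history = rr_history[-8:]
            detections.append(int(p))
            spki = 0.125 * level + 0.875 * spki
            last_missed = None
        else:
            # search-back: if the expected beat never arrived, accept the
            # best sub-threshold candidate above half the threshold
            if (
                detections
                and rr_history
                and last_missed is not None
                and p - detections[-1] > 1.66 * np.mean(rr_history)
                and integrated[last_missed] > 0.5 * threshold1
            ):
                detections.append(int(last_missed))
                spki = 0.25 * integrated[last_missed] + 0.75 * spki
                detections.sort()
                last_missed = None
            if last_missed is None or integrated[p] > integrated[last_missed]:
                last_missed = int(p)
            npki = 0.125 * level + 0.875 * npki

    # refine each detection to the band-passed local maximum
    half = int(round(0.075 * fs))
    refined = []
    for d in detections:
        lo, hi = max(d - half, 0), min(d + half + 1, len(record))
        refined.append(lo + int(np.argmax(bandpassed[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    return RPeakSet(indices=refined, fs=fs)


# -------------------------------------------------------------- segmentation

def segment_beats(
    record: ECGRecord,
    rpeaks: RPeakSet,
    labels: list[str] | None = None,
    length: int = SEGMENT_LENGTH,
    r_offset: int = R_OFFSET,
) -> list[Segment]:
    """Cut one window per R peak: ``samples[k - r_offset .. k - r_offset + length)``.

    Peaks too close to either record boundary to supply full context are
    dropped (and the drop count logged). ``labels``, if given, must align
    with ``rpeaks.indices``.
    """
    if labels is not None and len(labels) != len(rpeaks):
        raise ValueError("labels must align one-to-one with rpeaks")
    segments: list[Segment] = []
    dropped = 0
    for i, k in enumerate(rpeaks.indices):
        start = int(k) - r_offset
        if start < 0 or start + length > len(record):
            dropped += 1
            continue
        segments.append(Segment(
            samples=record.samples[start : start + length].copy(),
            r_offset=r_offset,
            label=labels[i] if labels is not None else None,
            standardized=False,
        ))
    if dropped:
        logger.info("segment_beats: dropped %d boundary beats", dropped)
    return segments


def zscore_segment(segment: Segment) -> Segment:
    """Standardize a segment to zero mean and unit (population) deviation."""
    sd = float(np.std(segment.samples))
    if sd == 0.0:
        raise ZeroVarianceError("cannot Z-score a constant segment")
    return Segment(
        samples=_scipy_zscore(segment.samples, ddof=0),
        r_offset=segment.r_offset,
        label=segment.label,
        standardized=True,
    )


# ----------------------------------------------------------------- balancing

def balance_classes(
    dataset: SegmentDataset, per_class_target: int, seed: int = 0
) -> SegmentDataset:
    """Equalize class sizes by random under/over-sampling.

    Classes above the target are uniformly undersampled without
    replacement; classes below it keep all their members and are topped up
    by duplicating uniformly drawn existing members. Segment values are
    never altered or synthesized.
    """
    if per_class_target < 1:
        raise ValueError("per_class_target must be >= 1")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[Segment]] = {}
    for seg in dataset.segments:
        if seg.label is None:
            raise ValueError("balance_classes requires labeled segments")
        by_class.setdefault(seg.label, []).append(seg)
    for label in by_class:
        if not by_class[label]:
            raise MissingClassError(label)
    out: list[Segment] = []
    for label in sorted(by_class):
        members = by_class[label]
        n = len(members)
        if n >= per_class_target:
            chosen = rng.choice(n, size=per_class_target, replace=False)
        else:
            chosen = np.concatenate(
                [np.arange(n), rng.integers(0, n, size=per_class_target - n)])
        out.extend(members[int(i)] for i in chosen)
    provenance = dict(dataset.provenance)
    provenance.update({"balanced_to": per_class_target, "balance_seed": seed})
    return SegmentDataset(segments=out, provenance=provenance)


# ------------------------------------------------------------------ splitting

def split_dataset(
    dataset: SegmentDataset,
    train_frac: float = 0.7,
    val_frac_of_train: float = 0.1,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[SegmentDataset, SegmentDataset, SegmentDataset]:
    """Random disjoint, exhaustive train/validation/test partition.

    ``train_frac`` of the data goes to training and the rest to test;
    ``val_frac_of_train`` is then carved out of the training share as a
    validation set. With ``stratified`` the per-class proportions are
    preserved within rounding in every part.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if not 0.0 <= val_frac_of_train < 1.0:
        raise ValueError("val_frac_of_train must lie in [0, 1)")
    idx = np.arange(len(dataset.segments))
    y = [seg.label for seg in dataset.segments]
    strat = y if stratified else None
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, random_state=seed, stratify=strat)
    if val_frac_of_train > 0:
        y_train = [y[i] for i in train_idx] if stratified else None
        train_idx, val_idx = train_test_split(
            train_idx, test_size=val_frac_of_train, random_state=seed,
            stratify=y_train)
    else:
        val_idx = np.array([], dtype=np.int64)

    def subset(indices: np.ndarray, part: str) -> SegmentDataset:
        prov = dict(dataset.provenance)
        prov.update({"split": part, "split_seed": seed, "train_frac": train_frac,
                     "val_frac_of_train": val_frac_of_train})
        return SegmentDataset(
            segments=[dataset.segments[int(i)] for i in np.sort(indices)],
            provenance=prov,
        )

    return subset(train_idx, "train"), subset(val_idx, "val"), subset(test_idx, "test")
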