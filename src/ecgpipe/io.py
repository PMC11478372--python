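"""Reading and writing the formats the pipeline touches.

Two on-disk formats are supported:

* WFDB record triplets (``.hea`` header, ``.dat`` signal, ``.atr`` beat
  annotations) in the MIT-BIH arrhythmia database layout — signal formats
  16 (little-endian int16) and 212 (packed 12-bit pairs) are readable,
  and format 16 is writable so that synthetic fixtures can round-trip.
* CSV segment tables: one row per fixed-length heartbeat segment, columns
  ``s0..s{L-1}`` plus a trailing ``label`` column.

Annotation symbols use the standard MIT-BIH single-character beat codes;
only the five classes N, A, V, L, R are kept by the symbol mapper.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five admissible heartbeat class labels: normal, atrial premature,
#: ventricular premature, left and right bundle branch block.
CLASS_LABELS: tuple[str, ...] = ("N", "A", "V", "L", "R")


class WFDBFormatError(ValueError):
    """Malformed WFDB header or signal data."""


class MissingWFDBFileError(FileNotFoundError):
    """A required member of the .hea/.dat/.atr triplet is absent."""


class LeadNotFoundError(KeyError):
    """The requested lead name is not present in the record header."""


class CorruptAnnotationError(ValueError):
    """The MIT annotation byte stream is truncated or inconsistent."""


class RaggedSegmentsError(ValueError):
    """Segments of differing lengths were passed to the CSV writer."""


class MalformedSegmentCSVError(ValueError):
    """A CSV segment table has inconsistent row width or a bad header."""


@dataclass
class ECGRecord:
    """A single-lead voltage series.

    Parameters
    ----------
    samples:
        Voltage values in millivolt, one per sample.
    fs:
        Sampling frequency in Hz.
    lead:
        Lead name, e.g. ``"MLII"``.
    source_id:
        Identifier of the originating record.
    """

    samples: np.ndarray
    fs: float
    lead: str = "MLII"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("record must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record contains non-finite samples")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class BeatAnnotation:
    """One expert beat label: a sample position and a single-character symbol."""

    sample_index: int
    symbol: str


# MIT annotation codes <-> display symbols (subset relevant to beat typing).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f", 39: "(",
    40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise WFDBFormatError(f"empty header: {hea_path}")
    head = lines[0].split()
    if len(head) < 3:
        raise WFDBFormatError(f"bad record line in {hea_path}: {lines[0]!r}")
    name = head[0].split("/")[0]
    nsig = int(head[1])
    fs = float(head[2].split("/")[0])
    nsamp = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + nsig]:
        tok = ln.split()
        if len(tok) < 2:
            raise WFDBFormatError(f"bad signal line in {hea_path}: {ln!r}")
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, None
        if len(tok) > 2:
            gspec = tok[2].split("/")[0]
            if "(" in gspec:
                gpart, bpart = gspec.split("(")
                gain = float(gpart) if gpart else 200.0
                baseline = int(bpart.rstrip(")"))
            elif gspec:
                gain = float(gspec)
        if gain == 0:
            gain = 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(
            {"file": tok[0], "fmt": fmt, "gain": gain, "baseline": baseline,
             "desc": desc}
        )
    return name, nsig, fs, nsamp, signals


def _read_dat(dat_path: Path, fmt: int, nsig: int) -> np.ndarray:
    """Return digital samples with shape (nsamples, nsig)."""
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        n = (data.size // nsig) * nsig
        return data[:n].reshape(-1, nsig).astype(np.int32)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        n_triplets = b.size // 3
        b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
        s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        flat = np.empty(2 * n_triplets, dtype=np.int32)
        flat[0::2], flat[1::2] = s1, s2
        flat[flat > 2047] -= 4096  # 12-bit two's complement
        n = (flat.size // nsig) * nsig
        return flat[:n].reshape(-1, nsig)
    raise WFDBFormatError(f"unsupported WFDB signal format {fmt}")


def read_wfdb_record(
    path: str | Path,
    lead: str = "MLII",
    annotator: str = "atr",
    fs_override: float | None = None,
) -> tuple[ECGRecord, list[BeatAnnotation]]:
    """Read one lead of a WFDB record together with its beat annotations.

    Parameters
    ----------
    path:
        Record path without extension (e.g. ``data/100`` for
        ``100.hea``/``100.dat``/``100.atr``).
    lead:
        Lead name to extract; must match a signal description in the header.
    annotator:
        Annotation file extension; if the file is absent an empty
        annotation list is returned.
    fs_override:
        Use this sampling frequency instead of the header's (for fixtures
        recorded at a nominal rate other than their true one).

    Raises
    ------
    MissingWFDBFileError
        If the header or signal file is missing.
    LeadNotFoundError
        If ``lead`` is not among the record's signal descriptions.
    CorruptAnnotationError
        If the annotation byte stream is truncated.
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise MissingWFDBFileError(f"header not found: {hea}")
    name, nsig, fs, nsamp, signals = _parse_header(hea)
    descs = [s["desc"] for s in signals]
    if lead not in descs:
        raise LeadNotFoundError(f"lead {lead!r} not in record {name} (has {descs})")
    idx = descs.index(lead)
    sig = signals[idx]
    dat = hea.parent / sig["file"]
    if not dat.exists():
        raise MissingWFDBFileError(f"signal file not found: {dat}")
    digital = _read_dat(dat, sig["fmt"], nsig)
    if nsamp:
        digital = digital[:nsamp]
    physical = (digital[:, idx] - sig["baseline"]) / sig["gain"]
    record = ECGRecord(samples=physical, fs=fs_override or fs, lead=lead,
                       source_id=name)
    atr = base.with_suffix("." + annotator)
    annotations = read_annotations(atr, len(record)) if atr.exists() else []
    return record, annotations


def read_annotations(atr_path: str | Path, nsamples: int | None = None) -> list[BeatAnnotation]:
    """Decode a MIT-format annotation file into beat annotations."""
    raw = Path(atr_path).read_bytes()
    if len(raw) % 2:
        raise CorruptAnnotationError(f"odd byte count in {atr_path}")
    out: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if code == 0 and interval == 0:
            return out
        if code == _SKIP and interval == 0:
            if i + 3 >= len(raw):
                raise CorruptAnnotationError(f"truncated SKIP in {atr_path}")
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            t += struct.unpack("<i", struct.pack("<I", ((hi << 16) | lo) & 0xFFFFFFFF))[0]
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        t += interval
        symbol = _CODE_TO_SYMBOL.get(code)
        if symbol is None:
            continue
        if nsamples is not None and not (0 <= t < nsamples):
            raise CorruptAnnotationError(
                f"annotation at sample {t} outside record of {nsamples} samples"
            )
        out.append(BeatAnnotation(sample_index=t, symbol=symbol))
    raise CorruptAnnotationError(f"missing end-of-stream marker in {atr_path}")


def write_wfdb_record(
    record: ECGRecord,
    path: str | Path,
    annotations: Sequence[BeatAnnotation] = (),
    gain: float = 200.0,
    annotator: str = "atr",
) -> ECGRecord:
    """Write a record (and annotations) as a format-16 WFDB triplet.

    Voltages are quantized to the ADC grid (``round(mV * gain)``); the
    returned :class:`ECGRecord` holds the values as stored, so reading the
    files back reproduces it bit-for-bit.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    digital = np.clip(np.round(record.samples * gain), -32768, 32767).astype(np.int16)
    name = base.name
    header = (
        f"{name} 1 {record.fs:g} {digital.size}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(digital[0])} 0 0 {record.lead}\n"
    )
    base.with_suffix(".hea").write_text(header)
    base.with_suffix(".dat").write_bytes(digital.astype("<i2").tobytes())
    if annotations:
        write_annotations(annotations, base.with_suffix("." + annotator))
    return ECGRecord(
        samples=digital.astype(np.float64) / gain,
        fs=record.fs,
        lead=record.lead,
        source_id=name,
    )


def write_annotations(annotations: Sequence[BeatAnnotation], atr_path: str | Path) -> None:
    """Encode beat annotations in the MIT annotation format."""
    ordered = sorted(annotations, key=lambda a: a.sample_index)
    buf = bytearray()
    t_prev = 0
    for ann in ordered:
        code = _SYMBOL_TO_CODE.get(ann.symbol)
        if code is None:
            raise ValueError(f"no MIT code for annotation symbol {ann.symbol!r}")
        dt = ann.sample_index - t_prev
        if dt < 0:
            raise ValueError("annotation indices must be non-decreasing")
        if dt >= 1024:
            buf += struct.pack("<H", _SKIP << 10)
            udt = dt & 0xFFFFFFFF
            buf += struct.pack("<HH", (udt >> 16) & 0xFFFF, udt & 0xFFFF)
            dt = 0
        buf += struct.pack("<H", (code << 10) | dt)
        t_prev = ann.sample_index
    buf += struct.pack("<H", 0)
    Path(atr_path).write_bytes(bytes(buf))


def map_annotation_symbols(
    annotations: Iterable[BeatAnnotation],
) -> list[tuple[int, str]]:
    """Keep the five-class beat symbols, dropping (and counting) the rest.

    Returns ``(sample_index, label)`` pairs where the label is one of
    :data:`CLASS_LABELS`. Symbols outside that set — paced beats, fusion
    beats, rhythm change markers, noise flags — are filtered out; the
    number dropped is logged.
    """
    kept: list[tuple[int, str]] = []
    dropped = 0
    for ann in annotations:
        if ann.symbol in CLASS_LABELS:
            kept.append((ann.sample_index, ann.symbol))
        else:
            dropped += 1
    if dropped:
        logger.info("map_annotation_symbols: dropped %d non-{N,A,V,L,R} symbols", dropped)
    return kept


def write_segments_csv(segments: Sequence, path: str | Path) -> None:
    """Write segments as a CSV table: columns ``s0..s{L-1}`` then ``label``."""
    lengths = {len(s.samples) for s in segments}
    if len(lengths) > 1:
        raise RaggedSegmentsError(f"mixed segment lengths: {sorted(lengths)}")
    length = lengths.pop() if lengths else 360
    columns = [f"s{i}" for i in range(length)] + ["label"]
    rows = [list(np.asarray(s.samples, dtype=np.float64)) + [s.label] for s in segments]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_segments_csv(path: str | Path):
    """Read a CSV segment table written by :func:`write_segments_csv`."""
    from .preprocess import Segment  # local import: io is lower in the stack

    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[-1] != "label" or not all(
        c == f"s{i}" for i, c in enumerate(df.columns[:-1])
    ):
        raise MalformedSegmentCSVError(f"unexpected column layout in {path}")
    values = df.iloc[:, :-1].to_numpy(dtype=np.float64)
    labels = df["label"].astype(str).tolist()
    return [
        Segment(samples=values[i], label=labels[i], standardized=None)
        for i in range(len(df))
    ]
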