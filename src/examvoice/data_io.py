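"""On-disk artifacts: WAV audio, test segmentations, diagnosis timelines, manifests.

All time coordinates are seconds from recording start; test intervals are
half-open ``[start_s, end_s)``. Dates are ISO-8601 strings parsed to
:class:`datetime.date`; date arithmetic is in whole days. Audio is kept
internally as mono float64 in ``[-1, 1]`` at 8 kHz (multi-channel input is
mixed to mono by arithmetic mean before anti-aliased resampling).

File dialects (documented in the README):

* segmentation: TSV with header ``test_name  start_s  end_s``
* timelines: CSV with header ``participant_id,diagnosis_date,status``
* manifest: CSV with header
  ``recording_id,participant_id,recording_date,audio_path,duration_s``
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

DEFAULT_RATE = 8000
VALID_STATUSES = ("NC", "MCI", "DE")


class SegmentationError(ValueError):
    """Raised for overlapping, inverted, or malformed test intervals."""


class TimelineError(ValueError):
    """Raised for malformed diagnosis timelines (bad status, duplicate dates)."""


@dataclass
class Waveform:
    """Mono audio samples in [-1, 1] with their sampling rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if self.samples.size < 1:
            raise ValueError("Waveform must contain at least one sample")
        if self.rate <= 0:
            raise ValueError(f"Sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class RecordingRecord:
    recording_id: str
    participant_id: str
    recording_date: _dt.date
    audio_path: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(
                f"Recording {self.recording_id}: duration must be positive"
            )


@dataclass
class TestSegmentation:
    """Non-overlapping labeled intervals mapping recording seconds to tests.

    Intervals are sorted by start; the union need not cover the whole
    recording (un-annotated gaps are allowed).
    """

    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        rows = [(str(t), float(a), float(b)) for t, a, b in self.intervals]
        for name, start, end in rows:
            if not (math.isfinite(start) and math.isfinite(end)):
                raise SegmentationError(f"{name}: non-finite interval bounds")
            if start < 0:
                raise SegmentationError(f"{name}: start {start} < 0")
            if not start < end:
                raise SegmentationError(
                    f"{name}: inverted or empty interval [{start}, {end})"
                )
        rows.sort(key=lambda r: (r[1], r[2]))
        bad = [
            (rows[i], rows[i + 1])
            for i in range(len(rows) - 1)
            if rows[i + 1][1] < rows[i][2]
        ]
        if bad:
            desc = "; ".join(f"{a} overlaps {b}" for a, b in bad)
            raise SegmentationError(f"Overlapping test intervals: {desc}")
        self.intervals = rows

    @property
    def test_names(self) -> list[str]:
        return [name for name, _, _ in self.intervals]

    @property
    def end_s(self) -> float:
        return max((end for _, _, end in self.intervals), default=0.0)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class DiagnosisTimeline:
    """Date-sorted cognitive-status history for one participant."""

    participant_id: str
    entries: list[tuple[_dt.date, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        entries = []
        for date, status in self.entries:
            if isinstance(date, str):
                date = _dt.date.fromisoformat(date)
            if status not in VALID_STATUSES:
                raise TimelineError(
                    f"{self.participant_id}: unknown status {status!r} "
                    f"(expected one of {VALID_STATUSES})"
                )
            entries.append((date, status))
        entries.sort(key=lambda e: e[0])
        dates = [d for d, _ in entries]
        if len(set(dates)) != len(dates):
            dup = sorted({d for d in dates if dates.count(d) > 1})
            raise TimelineError(
                f"{self.participant_id}: duplicate diagnosis dates {dup}"
            )
        self.entries = entries


def read_wav(path: str | Path, target_rate: int = DEFAULT_RATE) -> Waveform:
    """Read a PCM WAV file, mix to mono, and resample to ``target_rate``.

    Channels are averaged before anti-aliased polyphase resampling. Integer
    PCM is rescaled to [-1, 1] by its type's full scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"Audio file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises bare ValueError on corruption
        raise IOError(f"Could not read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"Zero-length audio in {path}")
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        x = resample_poly(x, target_rate // g, rate // g)
    return Waveform(samples=np.clip(x, -1.0, 1.0), rate=target_rate)


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    pcm = np.clip(np.round(w.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), w.rate, pcm)


def read_segmentation(path: str | Path) -> TestSegmentation:
    """Read a test-interval TSV (``test_name  start_s  end_s``)."""
    df = pd.read_csv(Path(path), sep="\t")
    required = {"test_name", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise SegmentationError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    for col in ("start_s", "end_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            rows = df.index[vals.isna()].tolist()
            raise SegmentationError(f"{path}: non-numeric {col} in rows {rows}")
        df[col] = vals
    return TestSegmentation(
        intervals=list(zip(df["test_name"], df["start_s"], df["end_s"]))
    )


def write_segmentation(path: str | Path, seg: TestSegmentation) -> None:
    pd.DataFrame(seg.intervals, columns=["test_name", "start_s", "end_s"]).to_csv(
        Path(path), sep="\t", index=False
    )


def read_timelines(path: str | Path) -> dict[str, DiagnosisTimeline]:
    """Read diagnosis timelines CSV into one timeline per participant."""
    try:
        df = pd.read_csv(Path(path), dtype={"participant_id": str, "status": str})
    except pd.errors.EmptyDataError:
        return {}
    required = {"participant_id", "diagnosis_date", "status"}
    if not df.empty and not required.issubset(df.columns):
        raise TimelineError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, DiagnosisTimeline] = {}
    if df.empty:
        return out
    bad = sorted(set(df["status"]) - set(VALID_STATUSES))
    if bad:
        raise TimelineError(f"{path}: unknown status tokens {bad}")
    for pid, grp in df.groupby("participant_id", sort=True):
        out[str(pid)] = DiagnosisTimeline(
            participant_id=str(pid),
            entries=list(zip(grp["diagnosis_date"], grp["status"])),
        )
    return out


def write_timelines(
    path: str | Path, timelines: Mapping[str, DiagnosisTimeline]
) -> None:
    rows = [
        (tl.participant_id, d.isoformat(), s)
        for tl in timelines.values()
        for d, s in tl.entries
    ]
    pd.DataFrame(
        rows, columns=["participant_id", "diagnosis_date", "status"]
    ).to_csv(Path(path), index=False)


def read_manifest(path: str | Path) -> list[RecordingRecord]:
    df = pd.read_csv(Path(path), dtype={"recording_id": str, "participant_id": str})
    return [
        RecordingRecord(
            recording_id=row.recording_id,
            participant_id=row.participant_id,
            recording_date=_dt.date.fromisoformat(str(row.recording_date)),
            audio_path=str(row.audio_path),
            duration_s=float(row.duration_s),
        )
        for row in df.itertuples()
    ]


def write_manifest(path: str | Path, records: Iterable[RecordingRecord]) -> None:
    pd.DataFrame(
        [
            (r.recording_id, r.participant_id, r.recording_date.isoformat(),
             r.audio_path, r.duration_s)
            for r in records
        ],
        columns=["recording_id", "participant_id", "recording_date",
                 "audio_path", "duration_s"],
    ).to_csv(Path(path), index=False)


def write_metrics_report(path: str | Path, report: Mapping) -> None:
    """Write an evaluation report as JSON (numpy scalars coerced to floats)."""

    def _coerce(obj):
        if isinstance(obj, Mapping):
            return {k: _coerce(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_coerce(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    Path(path).write_text(json.dumps(_coerce(report), indent=2))
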