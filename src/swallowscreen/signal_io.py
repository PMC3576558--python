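"""Data model and file I/O for dual-axis swallowing-accelerometry data.

A recording is a two-channel acceleration time series measured at the neck
surface: ``ap`` is the anterior-posterior axis (anterior positive) and ``si``
the superior-inferior axis (superior positive), in arbitrary device units.
Signals are stored as CSV (columns ``time_s, ap, si``) with a JSON metadata
sidecar carrying the sampling rate and acquisition parameters.  Swallow
segmentation boundaries and Penetration-Aspiration Scale (PAS) ratings are
plain CSV tables keyed by (participant, task, bolus, subswallow).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("swallowscreen")

DEFAULT_FS_HZ = 10_000.0

SEGMENT_COLUMNS = [
    "participant_id",
    "task_id",
    "bolus_id",
    "subswallow_index",
    "start_s",
    "end_s",
]
PAS_COLUMNS = [
    "participant_id",
    "task_id",
    "bolus_id",
    "subswallow_index",
    "pas",
]

TASK_IDS = ("teaspoon1", "teaspoon2", "teaspoon3", "cup")


@dataclass
class RecordingMeta:
    """Acquisition metadata carried alongside a recording.

    Defaults describe the hardware chain the signals are modeled after:
    analog bandpass 0.1 Hz - 3 kHz, 10x amplification, 10 kHz sampling.
    """

    participant_id: str = ""
    bandpass_low_hz: float = 0.1
    bandpass_high_hz: float = 3000.0
    amplification: float = 10.0
    notes: str = ""
    processing: list[str] = field(default_factory=list)


@dataclass
class Recording:
    """Two-channel acceleration series with sampling-rate metadata."""

    ap: np.ndarray
    si: np.ndarray
    fs: float
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.ap = np.asarray(self.ap, dtype=float)
        self.si = np.asarray(self.si, dtype=float)
        if self.ap.ndim != 1 or self.si.ndim != 1:
            raise ValueError("ap and si must be one-dimensional")
        if len(self.ap) != len(self.si):
            raise ValueError(
                f"axis length mismatch: ap has {len(self.ap)}, si has {len(self.si)}"
            )
        if len(self.ap) < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return len(self.ap)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SegmentBoundary:
    """One subswallow's time window within a participant/task recording."""

    participant_id: str
    task_id: str
    bolus_id: str
    subswallow_index: int
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(
                f"invalid interval [{self.start_s}, {self.end_s}) for "
                f"{self.key}"
            )
        if self.subswallow_index < 1:
            raise ValueError("subswallow_index is 1-based")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.participant_id, self.task_id, self.bolus_id, self.subswallow_index)


@dataclass(frozen=True)
class PasRating:
    """8-point Penetration-Aspiration Scale score for one subswallow."""

    participant_id: str
    task_id: str
    bolus_id: str
    subswallow_index: int
    score: int

    def __post_init__(self) -> None:
        if not 1 <= self.score <= 8:
            raise ValueError(f"PAS score must be in 1..8, got {self.score}")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.participant_id, self.task_id, self.bolus_id, self.subswallow_index)


# ---------------------------------------------------------------------------
# sample-index convention
# ---------------------------------------------------------------------------

def time_to_index(t_s: float, fs: float) -> int:
    """Convert a boundary time to a sample index: floor(t*fs).

    Intervals are half-open [start, end) in index space so contiguous
    subswallows partition their samples without duplication.  The product
    is rounded to 1 microsample before flooring so that values that are
    integers up to binary floating-point error (2.3*10 = 22.999999999999996)
    land on the intended sample.
    """
    return int(math.floor(round(t_s * fs, 6)))


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def _repair_nonfinite(x: np.ndarray, axis_name: str, max_run: int = 10) -> np.ndarray:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    # locate runs of consecutive non-finite samples
    idx = np.flatnonzero(bad)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    longest = max(len(r) for r in runs)
    if longest > max_run:
        raise ValueError(
            f"{axis_name}: non-finite run of {longest} samples exceeds "
            f"repairable limit of {max_run}"
        )
    if bad[0] or bad[-1]:
        raise ValueError(f"{axis_name}: non-finite samples at series edge cannot be interpolated")
    good = ~bad
    out = x.copy()
    out[bad] = np.interp(idx, np.flatnonzero(good), x[good])
    logger.warning(
        "%s: linearly interpolated %d non-finite samples in %d run(s)",
        axis_name, int(bad.sum()), len(runs),
    )
    return out


def read_recording(
    signal_path: str | Path,
    sidecar_path: str | Path,
    *,
    repair_nonfinite: bool = False,
) -> Recording:
    """Load a recording from a CSV signal file plus JSON sidecar.

    The sidecar's declared ``fs_hz`` must agree with the median time step of
    the ``time_s`` column within 1%.  Non-finite samples are rejected unless
    ``repair_nonfinite`` permits linear interpolation of runs of at most 10
    samples (logged).
    """
    df = pd.read_csv(signal_path, float_precision="round_trip")
    missing = {"time_s", "ap", "si"} - set(df.columns)
    if missing:
        raise ValueError(f"{signal_path}: missing columns {sorted(missing)}")

    with open(sidecar_path) as fh:
        side = json.load(fh)
    if "fs_hz" not in side:
        raise ValueError(f"{sidecar_path}: sidecar missing key 'fs_hz'")
    fs = float(side["fs_hz"])

    if len(df) >= 2:
        step = float(np.median(np.diff(df["time_s"].to_numpy())))
        if step <= 0:
            raise ValueError(f"{signal_path}: time column is not increasing")
        fs_from_time = 1.0 / step
        if abs(fs_from_time - fs) > 0.01 * fs:
            raise ValueError(
                f"fs mismatch: sidecar declares {fs} Hz but median time step "
                f"{step:.6g} s implies {fs_from_time:.6g} Hz"
            )

    ap = df["ap"].to_numpy(dtype=float)
    si = df["si"].to_numpy(dtype=float)
    if repair_nonfinite:
        ap = _repair_nonfinite(ap, "ap")
        si = _repair_nonfinite(si, "si")
    elif not (np.isfinite(ap).all() and np.isfinite(si).all()):
        raise ValueError(f"{signal_path}: non-finite samples present")

    meta = RecordingMeta(
        participant_id=str(side.get("participant_id", "")),
        bandpass_low_hz=float(side.get("bandpass_low_hz", 0.1)),
        bandpass_high_hz=float(side.get("bandpass_high_hz", 3000.0)),
        amplification=float(side.get("amplification", 10.0)),
        notes=str(side.get("notes", "")),
        processing=list(side.get("processing", [])),
    )
    return Recording(ap=ap, si=si, fs=fs, meta=meta)


def write_recording(rec: Recording, signal_path: str | Path, sidecar_path: str | Path) -> None:
    """Write a recording as CSV + JSON sidecar (inverse of :func:`read_recording`)."""
    n = rec.n_samples
    df = pd.DataFrame(
        {
            "time_s": np.arange(n) / rec.fs,
            "ap": rec.ap,
            "si": rec.si,
        }
    )
    # %.17g guarantees float64 round-trips bit-identically through the CSV
    df.to_csv(signal_path, index=False, float_format="%.17g")
    side = {
        "fs_hz": rec.fs,
        "bandpass_low_hz": rec.meta.bandpass_low_hz,
        "bandpass_high_hz": rec.meta.bandpass_high_hz,
        "amplification": rec.meta.amplification,
        "participant_id": rec.meta.participant_id,
        "notes": rec.meta.notes,
        "processing": rec.meta.processing,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(side, fh, indent=1)


# ---------------------------------------------------------------------------
# segment table I/O
# ---------------------------------------------------------------------------

def read_segments(path: str | Path) -> list[SegmentBoundary]:
    """Load and validate a segment-boundary table.

    Rows are validated (positive half-open intervals; within each bolus the
    subswallow intervals must be ordered by index, non-overlapping, and
    unique) and returned sorted by (participant, task, bolus, subswallow).
    Consecutive subswallows may share a boundary instant.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        logger.warning("%s: empty segment table", path)
        return []
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = [
        SegmentBoundary(
            participant_id=str(r.participant_id),
            task_id=str(r.task_id),
            bolus_id=str(r.bolus_id),
            subswallow_index=int(r.subswallow_index),
            start_s=float(r.start_s),
            end_s=float(r.end_s),
        )
        for r in df.itertuples()
    ]
    rows.sort(key=lambda b: b.key)
    _validate_segments(rows)
    return rows


def _validate_segments(rows: list[SegmentBoundary]) -> None:
    by_bolus: dict[tuple[str, str, str], list[SegmentBoundary]] = {}
    for b in rows:
        by_bolus.setdefault((b.participant_id, b.task_id, b.bolus_id), []).append(b)
    for key, group in by_bolus.items():
        seen = set()
        for b in group:
            if b.subswallow_index in seen:
                raise ValueError(f"duplicate subswallow_index {b.subswallow_index} in bolus {key}")
            seen.add(b.subswallow_index)
        group = sorted(group, key=lambda b: b.subswallow_index)
        for prev, nxt in zip(group, group[1:]):
            if nxt.start_s < prev.end_s:
                raise ValueError(
                    f"overlapping subswallows in bolus {key}: "
                    f"[{prev.start_s},{prev.end_s}) and [{nxt.start_s},{nxt.end_s})"
                )


def write_segments(rows: list[SegmentBoundary], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": b.participant_id,
                "task_id": b.task_id,
                "bolus_id": b.bolus_id,
                "subswallow_index": b.subswallow_index,
                "start_s": b.start_s,
                "end_s": b.end_s,
            }
            for b in rows
        ],
        columns=SEGMENT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# PAS table I/O
# ---------------------------------------------------------------------------

def read_pas(path: str | Path) -> list[PasRating]:
    """Load a PAS rating table; every score must lie in 1..8, one per key."""
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty PAS table", path)
        return []
    missing = set(PAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = [
        PasRating(
            participant_id=str(r.participant_id),
            task_id=str(r.task_id),
            bolus_id=str(r.bolus_id),
            subswallow_index=int(r.subswallow_index),
            score=int(r.pas),
        )
        for r in df.itertuples()
    ]
    keys = [r.key for r in out]
    if len(set(keys)) != len(keys):
        raise ValueError(f"{path}: duplicate (participant, task, bolus, subswallow) keys")
    out.sort(key=lambda r: r.key)
    return out


def write_pas(rows: list[PasRating], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "task_id": r.task_id,
                "bolus_id": r.bolus_id,
                "subswallow_index": r.subswallow_index,
                "pas": r.score,
            }
            for r in rows
        ],
        columns=PAS_COLUMNS,
    )
    df.to_csv(path, index=False)
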