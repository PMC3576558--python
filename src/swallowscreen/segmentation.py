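"""Carve preprocessed recordings into per-subswallow clips.

Segmentation boundaries come from an external table (in the clinical
workflow they are read off concurrent videofluoroscopy: bolus-head arrival
at the mandibular ramus to lowest hyoid position); there is no automatic
swallow detector.  Windows are half-open in sample space, so contiguous
subswallows partition their samples exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import Recording, SegmentBoundary, time_to_index


@dataclass(frozen=True)
class SwallowClip:
    """One segmented subswallow: dual-axis samples plus cohort identifiers."""

    participant_id: str
    task_id: str
    bolus_id: str
    subswallow_index: int
    ap: np.ndarray
    si: np.ndarray
    fs: float
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if len(self.ap) != len(self.si):
            raise ValueError("clip axes differ in length")
        if len(self.ap) < 1:
            raise ValueError("empty clip window after rounding")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.participant_id, self.task_id, self.bolus_id, self.subswallow_index)

    @property
    def n_samples(self) -> int:
        return len(self.ap)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def extract_clip(rec: Recording, b: SegmentBoundary) -> SwallowClip:
    """Cut one half-open window [floor(start*fs), floor(end*fs)) from a recording."""
    i0 = time_to_index(b.start_s, rec.fs)
    i1 = time_to_index(b.end_s, rec.fs)
    if i1 > rec.n_samples:
        raise ValueError(
            f"boundary end {b.end_s}s (sample {i1}) exceeds recording of "
            f"{rec.n_samples} samples ({rec.duration_s:.3g}s) for {b.key}"
        )
    if i1 <= i0:
        raise ValueError(f"empty window after rounding for {b.key}")
    return SwallowClip(
        participant_id=b.participant_id,
        task_id=b.task_id,
        bolus_id=b.bolus_id,
        subswallow_index=b.subswallow_index,
        ap=rec.ap[i0:i1].copy(),
        si=rec.si[i0:i1].copy(),
        fs=rec.fs,
        start_s=b.start_s,
        end_s=b.end_s,
    )


def extract_clips(
    rec: Recording, boundaries: list[SegmentBoundary]
) -> list[SwallowClip]:
    """One clip per boundary, in boundary order."""
    return [extract_clip(rec, b) for b in boundaries]
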