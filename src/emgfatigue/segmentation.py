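"""Overlapping rectangular-window segmentation (default 3 s windows, 1.5 s overlap).

Windows are half-open sample ranges ``[start, start + N)`` with start indices
computed as ``round(i * hop * fs)``, so no sample changes segments by a rounding
accident.  A trailing stretch shorter than one full window is dropped: every
downstream feature normalises by the fixed window length N.  "Rectangular"
means literal: no taper is applied before any spectral analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .record import EMGRecord

WINDOW_S = 3.0
OVERLAP_S = 1.5


@dataclass
class Segment:
    """One rectangular window of a record.

    ``index`` is 0-based internally (reports print it 1-based); ``t_start`` is
    the window start time in seconds.
    """

    samples: np.ndarray
    index: int
    t_start: float
    fs: float

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "Segment":
        return Segment(samples=samples, index=self.index, t_start=self.t_start, fs=self.fs)


def segment(
    record: EMGRecord, window_s: float = WINDOW_S, overlap_s: float = OVERLAP_S
) -> list[Segment]:
    """Split a record into overlapping rectangular windows.

    With hop = window_s - overlap_s, the number of segments is
    ``floor((duration - window_s)/hop) + 1``; consecutive segments share exactly
    ``round(overlap_s * fs)`` samples.
    """
    if not (0 <= overlap_s < window_s):
        raise ValueError(
            f"need 0 <= overlap ({overlap_s}) < window ({window_s}) seconds"
        )
    n_win = round(window_s * record.fs)
    if n_win < 1 or len(record) < n_win:
        raise ValueError(
            f"record of {record.duration_s:.3f} s is shorter than one "
            f"{window_s} s window"
        )
    hop = window_s - overlap_s
    segments: list[Segment] = []
    i = 0
    while True:
        start = round(i * hop * record.fs)
        if start + n_win > len(record):
            break
        segments.append(
            Segment(
                samples=record.samples[start : start + n_win],
                index=i,
                t_start=i * hop,
                fs=record.fs,
            )
        )
        i += 1
    return segments
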