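"""The double-step binary fatigue classifier.

Step 1 gates each segment on muscle activity: the segment's integrated EMG must
strictly exceed the first segment's (the session baseline).  The gate is
evaluated independently per segment — it does not latch — and the first segment
is therefore non-fatigue by construction.  Step 2 band-splits the gated segment
into a low-frequency sub-signal (LFSS, 25-79 Hz) and a high-frequency
sub-signal (HFSS, 80-350 Hz) with fourth-order Butterworth band-pass filters,
computes the instantaneous mean amplitude (IMA) of each — the mean magnitude of
the segment's full two-sided DFT divided by the segment length — and declares
fatigue when

    fatigue_index = IMA(LFSS) - IMA(HFSS) >= 0.

As fatigue progresses, spectral mass migrates from the high band into the low
band, so the index crosses from negative to non-negative.  The fatigue report
counter records the per-segment labels, gate states and indices for a session,
plus the onset time (start of the first fatigue-labelled segment).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .record import EMGRecord
from . import preprocessing as pre
from .preprocessing import FilterSpec, preprocess
from .segmentation import Segment, segment, WINDOW_S, OVERLAP_S
from .features import iemg

LABEL_FATIGUE = "fatigue"
LABEL_NON_FATIGUE = "non-fatigue"

LFC_LOW_HZ = 25.0
LFC_HIGH_HZ = 79.0
HFC_LOW_HZ = 80.0
HFC_HIGH_HZ = 350.0
SUBBAND_ORDER = 4


@dataclass(frozen=True)
class ClassifierConfig:
    """Cutoffs, orders and windowing for the full pipeline.

    The defaults are the reference configuration for middle-deltoid sEMG at
    fs = 2000 Hz: conditioning band-pass 25-350 Hz (order 2) with a 47-53 Hz
    power-line band-stop (order 2), sub-bands 25-79 / 80-350 Hz (order 4),
    3 s windows with 1.5 s overlap, zero-phase filtering throughout.
    """

    lfc_low: float = LFC_LOW_HZ
    lfc_high: float = LFC_HIGH_HZ
    hfc_low: float = HFC_LOW_HZ
    hfc_high: float = HFC_HIGH_HZ
    subband_order: int = SUBBAND_ORDER
    zero_phase: bool = True
    window_s: float = WINDOW_S
    overlap_s: float = OVERLAP_S
    bandpass_low: float = pre.BANDPASS_LOW_HZ
    bandpass_high: float = pre.BANDPASS_HIGH_HZ
    bandpass_order: int = pre.BANDPASS_ORDER
    bandstop_low: float = pre.BANDSTOP_LOW_HZ
    bandstop_high: float = pre.BANDSTOP_HIGH_HZ
    bandstop_order: int = pre.BANDSTOP_ORDER

    def __post_init__(self) -> None:
        if not (self.lfc_low < self.lfc_high < self.hfc_low < self.hfc_high):
            raise ValueError("sub-band cutoffs must be ordered low < high per band")


@dataclass
class SubBandAnalysis:
    """Per-segment low/high-band IMA values and their difference."""

    ima_lfss: float
    ima_hfss: float

    @property
    def fatigue_index(self) -> float:
        return self.ima_lfss - self.ima_hfss


@dataclass
class SegmentClassification:
    """Outcome of the double-step decision for one segment."""

    index: int
    t_start: float
    iemg: float
    gate_passed: bool
    subband: Optional[SubBandAnalysis]
    label: str

    @property
    def fatigue_index(self) -> Optional[float]:
        return None if self.subband is None else self.subband.fatigue_index


@dataclass
class FatigueReport:
    """The fatigue report counter for a session."""

    segments: list[SegmentClassification]
    iemg_initial: float

    @property
    def onset_time(self) -> Optional[float]:
        """Start time of the first fatigue-labelled segment, or None."""
        for s in self.segments:
            if s.label == LABEL_FATIGUE:
                return s.t_start
        return None

    @property
    def n_fatigue(self) -> int:
        return sum(1 for s in self.segments if s.label == LABEL_FATIGUE)

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def summary(self) -> dict:
        return {
            "n_segments": len(self.segments),
            "n_fatigue": self.n_fatigue,
            "iemg_initial": self.iemg_initial,
            "onset_time_s": self.onset_time,
        }


def label_from_index(fatigue_index: float) -> str:
    """Decision rule on an (activity-gated) fatigue index: fatigue iff >= 0."""
    return LABEL_FATIGUE if fatigue_index >= 0 else LABEL_NON_FATIGUE


def extract_subband(
    seg: Segment, low: float, high: float, order: int = SUBBAND_ORDER,
    zero_phase: bool = True,
) -> Segment:
    """Band-limit a segment with a Butterworth band-pass (LFSS or HFSS)."""
    spec = FilterSpec("band-pass", order, low, high, zero_phase)
    rec = EMGRecord(seg.samples, fs=seg.fs)
    return seg.with_samples(pre.apply_filter(rec, spec).samples)


def ima(seg: Segment) -> float:
    """Instantaneous mean amplitude: mean |X_n| of the full two-sided DFT.

    Equals (1/N) * sum_{n=0}^{N-1} |X_n| where X is the length-N DFT of the
    segment samples.
    """
    x = np.asarray(seg.samples, dtype=float)
    if x.size == 0:
        raise ValueError("segment must be non-empty")
    return float(np.abs(np.fft.fft(x)).mean())


def fatigue_index(seg: Segment, cfg: ClassifierConfig = ClassifierConfig()) -> SubBandAnalysis:
    """Sub-band decomposition and IMA difference for one (preprocessed) segment."""
    lfss = extract_subband(seg, cfg.lfc_low, cfg.lfc_high, cfg.subband_order, cfg.zero_phase)
    hfss = extract_subband(seg, cfg.hfc_low, cfg.hfc_high, cfg.subband_order, cfg.zero_phase)
    return SubBandAnalysis(ima_lfss=ima(lfss), ima_hfss=ima(hfss))


def classify_segment(
    seg: Segment,
    iemg_initial: float,
    cfg: ClassifierConfig = ClassifierConfig(),
    use_gate: bool = True,
) -> SegmentClassification:
    """Double-step decision for one segment.

    The gate requires the segment IEMG to strictly exceed ``iemg_initial``.
    When the gate fails, the label is non-fatigue and no sub-band analysis is
    performed.  ``use_gate=False`` runs step 2 unconditionally (the gate state
    is still recorded) — used to demonstrate why the gate is necessary on
    relaxed-muscle recordings.
    """
    if iemg_initial < 0:
        raise ValueError("iemg_initial must be nonnegative")
    iemg_val = iemg(seg)
    gate_passed = iemg_val > iemg_initial
    if use_gate and not gate_passed:
        return SegmentClassification(
            index=seg.index, t_start=seg.t_start, iemg=iemg_val,
            gate_passed=False, subband=None, label=LABEL_NON_FATIGUE,
        )
    sub = fatigue_index(seg, cfg)
    return SegmentClassification(
        index=seg.index, t_start=seg.t_start, iemg=iemg_val,
        gate_passed=gate_passed, subband=sub,
        label=label_from_index(sub.fatigue_index),
    )


def run_classifier(
    record: EMGRecord,
    cfg: ClassifierConfig = ClassifierConfig(),
    use_gate: bool = True,
    preprocessed: bool = False,
) -> FatigueReport:
    """Full pipeline: preprocess, segment, gate and classify every segment.

    The IEMG baseline is fixed to the first segment for the whole session, so
    the first segment is always labelled non-fatigue (it cannot strictly
    exceed itself).
    """
    rec = record if preprocessed else preprocess(
        record,
        bandpass_low=cfg.bandpass_low, bandpass_high=cfg.bandpass_high,
        bandpass_order=cfg.bandpass_order,
        bandstop_low=cfg.bandstop_low, bandstop_high=cfg.bandstop_high,
        bandstop_order=cfg.bandstop_order, zero_phase=cfg.zero_phase,
    )
    segs = segment(rec, cfg.window_s, cfg.overlap_s)
    if len(segs) < 2:
        raise ValueError(
            f"record yields only {len(segs)} segment(s); need at least 2 "
            "(the first defines the IEMG baseline)"
        )
    iemg_initial = iemg(segs[0])
    classified = [classify_segment(s, iemg_initial, cfg, use_gate=use_gate) for s in segs]
    return FatigueReport(segments=classified, iemg_initial=iemg_initial)
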