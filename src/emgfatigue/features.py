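"""Per-segment features: integrated EMG, power spectrum, mean and median frequency.

The spectral estimator is the raw single-window periodogram of the untapered
segment (P_k = |X_k|^2 from the DFT, one-sided bins 0..floor(N/2)).  No taper
or averaging is applied, consistent with rectangular windowing upstream.  The
DC bin is excluded from MNF/MDF sums: the DC offset is removed during
preprocessing and the frequency-weighted sums start at the first nonzero bin.

MNF is the power-weighted mean frequency.  MDF is defined here with an explicit
tie-break, since exact equal-power splitting rarely holds on discrete bins: it
is the smallest bin frequency at which the cumulative power reaches half of the
total.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .segmentation import Segment

ArrayOrSegment = Union[Segment, np.ndarray, list]


def _samples(x: ArrayOrSegment) -> np.ndarray:
    if isinstance(x, Segment):
        return np.asarray(x.samples, dtype=float)
    return np.asarray(x, dtype=float)


@dataclass
class PowerSpectrum:
    """One-sided periodogram: frequencies f_k (Hz) and powers P_k = |X_k|^2."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def total_power(self) -> float:
        return float(self.power.sum())

    @property
    def is_degenerate(self) -> bool:
        """True for an all-zero spectrum (zero input signal)."""
        return self.total_power == 0.0


@dataclass
class SegmentFeatures:
    """IEMG (unitless amplitude sum), MNF and MDF (Hz) of one segment."""

    iemg: float
    mnf: float
    mdf: float


def iemg(seg: ArrayOrSegment) -> float:
    """Integrated EMG: the sum of absolute sample amplitudes over the segment."""
    x = _samples(seg)
    if x.size == 0:
        raise ValueError("segment must be non-empty")
    return float(np.abs(x).sum())


def power_spectrum(seg: Segment) -> PowerSpectrum:
    """One-sided periodogram of the untapered segment."""
    x = _samples(seg)
    if x.size == 0:
        raise ValueError("segment must be non-empty")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / seg.fs)
    return PowerSpectrum(freqs=freqs, power=np.abs(spec) ** 2)


def _nonzero_bins(ps: PowerSpectrum) -> tuple[np.ndarray, np.ndarray]:
    if ps.is_degenerate:
        raise ValueError("degenerate all-zero spectrum: MNF/MDF undefined")
    # drop the DC bin when present
    if ps.freqs[0] == 0.0:
        return ps.freqs[1:], ps.power[1:]
    return ps.freqs, ps.power


def mnf(ps: PowerSpectrum) -> float:
    """Mean frequency: power-weighted mean of the bin frequencies."""
    f, p = _nonzero_bins(ps)
    total = p.sum()
    if total == 0:
        raise ValueError("degenerate spectrum: no power above DC")
    return float((f * p).sum() / total)


def mdf(ps: PowerSpectrum) -> float:
    """Median frequency: smallest bin frequency where cumulative power >= half total."""
    f, p = _nonzero_bins(ps)
    total = p.sum()
    if total == 0:
        raise ValueError("degenerate spectrum: no power above DC")
    cum = np.cumsum(p)
    m = int(np.searchsorted(cum, total / 2.0))
    return float(f[m])


def segment_features(seg: Segment) -> SegmentFeatures:
    """IEMG, MNF and MDF of a segment in one pass."""
    ps = power_spectrum(seg)
    return SegmentFeatures(iemg=iemg(seg), mnf=mnf(ps), mdf=mdf(ps))
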