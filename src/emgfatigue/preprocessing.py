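"""Signal conditioning: DC removal, 25-350 Hz band-pass, 47-53 Hz power-line band-stop.

All filters are Butterworth IIR designs.  The stated ``order`` is the prototype
design order; zero-phase (forward-backward) application effectively doubles it.
Zero-phase filtering is the default because it preserves envelope timing across
sub-bands, which matters when low- and high-band amplitudes are later compared
segment by segment; a causal single-pass mode is available via ``zero_phase=False``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .record import EMGRecord

BANDPASS_LOW_HZ = 25.0
BANDPASS_HIGH_HZ = 350.0
BANDPASS_ORDER = 2
BANDSTOP_LOW_HZ = 47.0
BANDSTOP_HIGH_HZ = 53.0
BANDSTOP_ORDER = 2


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth band filter specification.

    ``kind`` is ``"band-pass"`` or ``"band-stop"``; ``order`` is the prototype
    design order (>= 1); cutoffs are in Hz and must satisfy
    ``0 < low_hz < high_hz < fs/2`` at application time.
    """

    kind: str
    order: int
    low_hz: float
    high_hz: float
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("band-pass", "band-stop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"cutoffs must satisfy 0 < low < high, got {self.low_hz}, {self.high_hz}"
            )

    def design(self, fs: float) -> np.ndarray:
        """Second-order-section coefficients for this spec at sampling rate ``fs``."""
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"upper cutoff {self.high_hz} Hz must be below Nyquist ({fs / 2} Hz)"
            )
        btype = "bandpass" if self.kind == "band-pass" else "bandstop"
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype=btype, fs=fs, output="sos"
        )


def magnitude_response(spec: FilterSpec, fs: float, freqs) -> np.ndarray:
    """Designed single-pass magnitude response |H(f)| at the given frequencies."""
    sos = spec.design(fs)
    _, h = sps.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs, dtype=float)), fs=fs)
    return np.abs(h)


def remove_dc(record: EMGRecord) -> EMGRecord:
    """Subtract the arithmetic mean so the output is zero-mean."""
    return record.with_samples(record.samples - record.samples.mean())


def _startup_length(sos: np.ndarray) -> int:
    # mirrors scipy's default sosfiltfilt padlen
    n_sections = sos.shape[0]
    ntaps = 2 * n_sections + 1
    ntaps -= min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum())
    return 3 * ntaps


def apply_filter(record: EMGRecord, spec: FilterSpec) -> EMGRecord:
    """Apply a Butterworth band filter to a record.

    Zero-phase specs run forward-backward (``sosfiltfilt`` with its standard
    even-reflection padding); otherwise a causal single pass is used.
    """
    sos = spec.design(record.fs)
    padlen = _startup_length(sos)
    if len(record) <= padlen:
        raise ValueError(
            f"record of {len(record)} samples is shorter than 3x the filter "
            f"startup length ({padlen} samples)"
        )
    if spec.zero_phase:
        out = sps.sosfiltfilt(sos, record.samples)
    else:
        out = sps.sosfilt(sos, record.samples)
    return record.with_samples(out)


def preprocess(
    record: EMGRecord,
    *,
    bandpass_low: float = BANDPASS_LOW_HZ,
    bandpass_high: float = BANDPASS_HIGH_HZ,
    bandpass_order: int = BANDPASS_ORDER,
    bandstop_low: float = BANDSTOP_LOW_HZ,
    bandstop_high: float = BANDSTOP_HIGH_HZ,
    bandstop_order: int = BANDSTOP_ORDER,
    zero_phase: bool = True,
) -> EMGRecord:
    """Full conditioning chain: DC removal -> band-pass -> power-line band-stop."""
    if record.fs <= 2 * bandpass_high:
        raise ValueError(
            f"sampling rate {record.fs} Hz too low for a {bandpass_high} Hz cutoff"
        )
    bp = FilterSpec("band-pass", bandpass_order, bandpass_low, bandpass_high, zero_phase)
    bs = FilterSpec("band-stop", bandstop_order, bandstop_low, bandstop_high, zero_phase)
    return apply_filter(apply_filter(remove_dc(record), bp), bs)
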