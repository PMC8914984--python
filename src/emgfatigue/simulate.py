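"""Synthetic sEMG generator with controllable fatigue structure.

The surrogate signal is a weighted mixture of two band-limited carriers — a
low-band carrier confined to 25-79 Hz and a high-band carrier confined to
80-350 Hz — plus a broadband noise floor:

    x(t) = amp(t) * [ w_h(t) * c_H(t) + w_l(t) * c_L(t) ] + noise_floor * n_0(t)

with amp(t) = amp0 * (1 + amp_growth * t).  In fatigue mode the band weights
follow linear trajectories that cross at ``crossover_s`` (the designed fatigue
onset: the instant low-band content matches high-band content); in non-fatigue
mode the weights are constant with the high band dominant.

The default carriers are dense random-phase multisines on a 1/3-Hz grid.  On
that grid every 3-s analysis window contains an integer number of cycles of
each tone, so the per-window DFT magnitudes — and hence the measured sub-band
IMA values — are essentially deterministic given the band weights, while the
time-domain waveform remains Gaussian-like by the central limit theorem.
Band-limited Gaussian noise carriers (``carrier="gaussian"``) are available,
but their per-window IMA fluctuates with relative SD ~0.52/sqrt(bins-in-band)
(~4% for the 54-Hz low band), which smears the detected onset by 1-2 s.

The carriers are calibrated through the classifier's own measurement chain
(conditioning filters, segmentation, sub-band extraction, IMA) so that one
unit of band weight contributes one unit of measured sub-band IMA *after*
accounting for cross-band leakage.  A final balance step equalises the two
measured sub-band IMAs on a static mixture at the crossover operating point
(equal weights, session amplitude at the crossover, noise floor included):
the broadband noise floor inflates the high-band IMA more than the low-band
one (it spans five times as many bins), and without this step the index zero
would land 1-2 s after the designed crossover.  With it, the weight-crossover
time is the expected zero crossing of the fatigue index as measured.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .record import EMGRecord
from .preprocessing import preprocess, FilterSpec, apply_filter
from .segmentation import segment
from .classifier import ClassifierConfig, extract_subband, ima

#: calibration slice length in seconds (three analysis windows)
_CALIBRATION_S = 9.0
#: multisine tone grid period in seconds.  Half the 3-s analysis window (and
#: equal to the hop), so every analysis window starts on a period boundary and
#: sees the identical carrier waveform; the tones (spacing 2/3 Hz) stay exactly
#: bin-centred for the window DFT.
_CARRIER_PERIOD_S = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a middle-deltoid fatigue session: 80 s at 2000 Hz with
    the designed onset at 50 s, amplitude growing 0.5% per second (a ~40%
    rise over the session, driving the rising IEMG trend), and the high band
    initially dominant (w_h0 > w_l0).  ``crossover_s=None`` selects
    non-fatigue mode (stationary weights, flat amplitude unless overridden).
    """

    fs: float = 2000.0
    duration_s: float = 80.0
    seed: int = 0
    amp0: float = 1.0
    amp_growth: float = 0.005
    w_h0: float = 1.0
    w_l0: float = 0.3
    crossover_s: Optional[float] = 50.0
    noise_floor: float = 0.02
    carrier: str = "multisine"

    def __post_init__(self) -> None:
        if self.fs < 800:
            raise ValueError("fs must be >= 800 Hz (surface EMG extends to ~400 Hz)")
        if self.duration_s < 2 * _CARRIER_PERIOD_S:
            raise ValueError("duration must cover at least two analysis windows")
        if self.w_h0 < 0 or self.w_l0 < 0:
            raise ValueError("band weights must be nonnegative")
        if self.crossover_s is not None:
            if self.crossover_s <= 0:
                raise ValueError("crossover_s must be positive")
            if not self.w_h0 > self.w_l0:
                raise ValueError("fatigue mode needs w_h0 > w_l0")
        if self.amp0 <= 0:
            raise ValueError("amp0 must be positive")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be nonnegative")
        if self.carrier not in ("multisine", "gaussian"):
            raise ValueError(f"unknown carrier {self.carrier!r}")


@dataclass
class SimulationTruth:
    """Designed ground truth: per-time band weights and the crossover."""

    times: np.ndarray
    w_low: np.ndarray
    w_high: np.ndarray
    amp: np.ndarray
    crossover_s: Optional[float]

    def as_dict(self) -> dict:
        return {
            "crossover_s": self.crossover_s,
            "times_s": self.times.tolist(),
            "w_low": self.w_low.tolist(),
            "w_high": self.w_high.tolist(),
            "amp": self.amp.tolist(),
        }


def _multisine_band(rng: np.random.Generator, fs: float, low: float, high: float,
                    n_samples: int) -> np.ndarray:
    """Random-phase multisine with tones on the 1/period grid inside [low, high]."""
    n_per = round(_CARRIER_PERIOD_S * fs)
    k_lo = int(np.ceil(low * _CARRIER_PERIOD_S))
    k_hi = int(np.floor(high * _CARRIER_PERIOD_S))
    spec = np.zeros(n_per // 2 + 1, dtype=complex)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k_hi - k_lo + 1)
    spec[k_lo : k_hi + 1] = np.exp(1j * phases)
    period = np.fft.irfft(spec, n=n_per)
    reps = int(np.ceil(n_samples / n_per))
    return np.tile(period, reps)[:n_samples]


def _gaussian_band(rng: np.random.Generator, fs: float, low: float, high: float,
                   n_samples: int) -> np.ndarray:
    """White Gaussian noise band-limited with a 4th-order zero-phase Butterworth."""
    white = rng.standard_normal(n_samples)
    spec = FilterSpec("band-pass", 4, low, high, zero_phase=True)
    return apply_filter(EMGRecord(white, fs=fs), spec).samples


def _make_carriers(rng: np.random.Generator, cfg: SimulationConfig,
                   n: int, clf: ClassifierConfig) -> tuple[np.ndarray, np.ndarray]:
    maker = _multisine_band if cfg.carrier == "multisine" else _gaussian_band
    c_low = maker(rng, cfg.fs, clf.lfc_low, clf.lfc_high, n)
    c_high = maker(rng, cfg.fs, clf.hfc_low, clf.hfc_high, n)
    s_low, s_high = _calibration_scales(c_low, c_high, cfg.fs, clf)
    return c_low * s_low, c_high * s_high


def _chain_ima(x: np.ndarray, fs: float, clf: ClassifierConfig) -> tuple[float, float]:
    """Mean per-segment (IMA_LFSS, IMA_HFSS) of a signal through the full chain."""
    rec = preprocess(EMGRecord(x, fs=fs), zero_phase=clf.zero_phase)
    segs = segment(rec, clf.window_s, clf.overlap_s)
    lo = np.mean([ima(extract_subband(s, clf.lfc_low, clf.lfc_high,
                                      clf.subband_order, clf.zero_phase)) for s in segs])
    hi = np.mean([ima(extract_subband(s, clf.hfc_low, clf.hfc_high,
                                      clf.subband_order, clf.zero_phase)) for s in segs])
    return float(lo), float(hi)


def _calibration_scales(c_low: np.ndarray, c_high: np.ndarray, fs: float,
                        clf: ClassifierConfig) -> tuple[float, float]:
    """Scales making one unit of band weight one unit of net measured IMA.

    With g_XY the IMA in sub-band X of unit carrier Y, choosing
    s_L = 1/(g_LL - g_HL) and s_H = 1/(g_HH - g_LH) makes the measured
    fatigue index equal w_l - w_h in expectation, leakage included.
    """
    n_cal = min(len(c_low), round(_CALIBRATION_S * fs))
    g_ll, g_hl = _chain_ima(c_low[:n_cal], fs, clf)
    g_lh, g_hh = _chain_ima(c_high[:n_cal], fs, clf)
    d_low = g_ll - g_hl
    d_high = g_hh - g_lh
    if d_low <= 0 or d_high <= 0:
        raise RuntimeError("carrier calibration failed: non-positive net band gain")
    return 1.0 / d_low, 1.0 / d_high


def _weights(cfg: SimulationConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if cfg.crossover_s is None:
        return np.full_like(t, cfg.w_l0), np.full_like(t, cfg.w_h0)
    rate = (cfg.w_h0 - cfg.w_l0) / (2.0 * cfg.crossover_s)
    w_l = cfg.w_l0 + rate * t
    w_h = np.maximum(cfg.w_h0 - rate * t, 0.0)
    return w_l, w_h


def simulate(cfg: SimulationConfig = SimulationConfig()) -> tuple[EMGRecord, SimulationTruth]:
    """Generate a synthetic sEMG record plus its designed ground truth.

    Deterministic for a fixed seed: repeated calls return bit-identical
    samples.
    """
    clf = ClassifierConfig()
    rng = np.random.default_rng(cfg.seed)
    n = round(cfg.duration_s * cfg.fs)
    t = np.arange(n) / cfg.fs
    c_low, c_high = _make_carriers(rng, cfg, n, clf)

    # Balance the bands at the operating point: on a static equal-weight
    # mixture at the crossover-time amplitude, with the noise floor present,
    # the two measured sub-band IMAs must coincide (that coincidence *is* the
    # designed onset).  Corrects the noise-floor Rice bias, which otherwise
    # favours the wider high band.
    w_bar = 0.5 * (cfg.w_l0 + cfg.w_h0)
    t_star = cfg.crossover_s if cfg.crossover_s is not None else 0.0
    a_star = cfg.amp0 * (1.0 + cfg.amp_growth * t_star)
    n_cal = min(n, round(_CALIBRATION_S * cfg.fs))
    mix = w_bar * a_star * (c_low[:n_cal] + c_high[:n_cal])
    if cfg.noise_floor > 0:
        mix = mix + cfg.noise_floor * rng.standard_normal(n_cal)
    ima_lo, ima_hi = _chain_ima(mix, cfg.fs, clf)
    c_low = c_low * (ima_hi / ima_lo)

    w_l, w_h = _weights(cfg, t)
    amp = cfg.amp0 * (1.0 + cfg.amp_growth * t)
    x = amp * (w_h * c_high + w_l * c_low)
    if cfg.noise_floor > 0:
        x = x + cfg.noise_floor * rng.standard_normal(n)
    coarse = np.arange(0.0, cfg.duration_s + 1e-9, 0.5)
    wl_c, wh_c = _weights(cfg, coarse)
    truth = SimulationTruth(
        times=coarse, w_low=wl_c, w_high=wh_c,
        amp=cfg.amp0 * (1.0 + cfg.amp_growth * coarse),
        crossover_s=cfg.crossover_s,
    )
    mode = "fatigue" if cfg.crossover_s is not None else "non-fatigue"
    return EMGRecord(x, fs=cfg.fs, label=f"synthetic {mode}"), truth


#: relaxed-muscle amplitude as a fraction of amp0
_RELAXED_AMP_FRAC = 0.05
#: settling-transient boost and time constant (seconds)
_SETTLE_BOOST = 0.8
_SETTLE_TAU_S = 1.5
#: band-balance modulation: depth and low-pass corner (Hz)
_BALANCE_DEPTH = 0.6
_BALANCE_CORNER_HZ = 0.25


def relaxed_muscle(cfg: SimulationConfig = SimulationConfig()) -> EMGRecord:
    """Synthetic near-silent recording of a relaxed muscle.

    Low-amplitude (5% of ``amp0``) mixture of the two band carriers with equal
    mean weights whose balance drifts slowly and symmetrically, so the
    sub-band IMA difference fluctuates in sign, as real quiescent recordings
    do.  A brief settling transient (residual activation while the limb drops
    into the relaxed posture) elevates the opening amplitude; after it decays
    the signal is stationary.  Total power is held constant across the balance
    drift so the activity gate sees a flat IEMG trend after the transient.
    """
    clf = ClassifierConfig()
    rng = np.random.default_rng(cfg.seed)
    n = round(cfg.duration_s * cfg.fs)
    t = np.arange(n) / cfg.fs
    c_low, c_high = _make_carriers(rng, cfg, n, clf)

    # slow symmetric band-balance drift around equal weights
    z = rng.standard_normal(n)
    sos = sps.butter(2, _BALANCE_CORNER_HZ, btype="lowpass", fs=cfg.fs, output="sos")
    m = sps.sosfiltfilt(sos, z)
    m = np.clip(_BALANCE_DEPTH * m / m.std(), -0.95, 0.95)
    w_l = 0.5 * (1.0 + m)
    w_h = 0.5 * (1.0 - m)

    # constant-power mixing: the balance drift must not modulate the IEMG
    rms_low, rms_high = c_low.std(), c_high.std()
    norm = 1.0 / np.sqrt((w_l * rms_low) ** 2 + (w_h * rms_high) ** 2)

    envelope = 1.0 + _SETTLE_BOOST * np.exp(-t / _SETTLE_TAU_S)
    # 5% of the RMS an active-muscle mixture would have at these settings
    active_rms = cfg.amp0 * np.sqrt((cfg.w_l0 * rms_low) ** 2
                                    + (cfg.w_h0 * rms_high) ** 2)
    amp = _RELAXED_AMP_FRAC * active_rms
    x = amp * envelope * norm * (w_l * c_low + w_h * c_high)
    x = x + 0.02 * amp * rng.standard_normal(n)
    return EMGRecord(x, fs=cfg.fs, label="synthetic relaxed")
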