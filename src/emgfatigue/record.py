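"""The single-channel sEMG record that every pipeline stage transforms."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default sampling rate in Hz for the supported acquisition chain.
DEFAULT_FS = 2000.0


@dataclass
class EMGRecord:
    """A uniformly sampled single-channel sEMG amplitude sequence.

    Parameters
    ----------
    samples : array_like
        Amplitude values in volts or arbitrary sensor units.
    fs : float
        Sampling rate in Hz (must be positive).
    label : str
        Free-text channel / muscle identifier.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("all samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "EMGRecord":
        """A copy of this record carrying new sample values."""
        return EMGRecord(samples=samples, fs=self.fs, label=self.label)
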