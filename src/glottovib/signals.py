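"""Calibrated 1-D signal containers and shared signal helpers.

Pressure is carried in kPa (bronchial pressure transducer units), sound in
Pa (calibrated microphone). Both know their sampling rate and an alignment
offset ``t0`` relative to the video trigger, so that multimodal trials can
be sliced onto a common clock.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InvalidParameterError


@dataclass
class _Trace:
    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("trace samples must be 1-D")
        if not self.fs > 0:
            raise InvalidParameterError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def slice_time(self, t_start: float, t_end: float):
        """Return the sub-trace covering [t_start, t_end)."""
        i0 = max(0, int(np.ceil((t_start - self.t0) * self.fs - 1e-9)))
        i1 = min(self.n, int(np.ceil((t_end - self.t0) * self.fs - 1e-9)))
        if i1 <= i0:
            raise InvalidParameterError(
                f"empty time slice [{t_start}, {t_end}) of trace spanning "
                f"[{self.t0}, {self.t0 + self.duration})"
            )
        return replace(self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs)


@dataclass
class PressureTrace(_Trace):
    """Bronchial pressure in kPa sampled at ``fs`` Hz."""


@dataclass
class SoundTrace(_Trace):
    """Calibrated sound pressure in Pa sampled at ``fs`` Hz."""

    mic_distance_mm: float = 0.0


def running_rms(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Running root-mean-square amplitude over a centred window.

    Edge samples use a shrunken effective window (nearest-mode padding),
    which slightly biases the first/last ``window_s / 2`` seconds.
    """
    size = max(1, int(round(window_s * fs)))
    power = uniform_filter1d(np.asarray(x, dtype=float) ** 2, size=size, mode="nearest")
    return np.sqrt(np.maximum(power, 0.0))
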