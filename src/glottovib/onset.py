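"""Phonation threshold pressure (PTP) and pressure-rate at onset (S_ptp).

The phonation threshold pressure is the minimal bronchial pressure at which
self-sustained tissue oscillation — and hence sound — begins. It is read off
the (zero-phase low-pass filtered) bronchial pressure at the instant the
radiated sound amplitude first crosses a fixed criterion of 0.2 mPa. The
pressure *speed* at that instant, S_ptp, is the first difference of the
filtered pressure scaled by the acquisition rate.

Filtering is forward-backward (zero phase): a causal single-pass filter
would delay the pressure trace relative to the sound and bias PTP upward on
rising ramps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import InvalidParameterError
from .signals import PressureTrace, SoundTrace, running_rms

#: Sound-amplitude criterion for phonation onset, Pa (0.2 mPa).
ONSET_SOUND_THRESHOLD_PA = 2e-4


@dataclass
class OnsetResult:
    """Phonation onset measurement for one trial."""

    detected: bool
    onset_time: float | None = None
    ptp: float | None = None
    s_ptp: float | None = None
    threshold_used: float = ONSET_SOUND_THRESHOLD_PA

    def to_dict(self) -> dict:
        return {
            "detected": bool(self.detected),
            "onset_s": self.onset_time,
            "ptp_kPa": self.ptp,
            "s_ptp_kPa_s": self.s_ptp,
            "sound_threshold_Pa": self.threshold_used,
        }


def lowpass_pressure(trace: PressureTrace, cutoff_hz: float = 500.0,
                     order: int = 6) -> PressureTrace:
    """Zero-phase Butterworth low-pass of the bronchial pressure.

    6th order at 500 Hz by default, applied forward and backward
    (squared magnitude response, zero phase shift, unit DC gain).
    """
    if trace.fs <= 2 * cutoff_hz:
        raise InvalidParameterError(
            f"sampling rate {trace.fs} Hz too low for {cutoff_hz} Hz low-pass"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=trace.fs, output="sos")
    filtered = sosfiltfilt(sos, trace.samples)
    return PressureTrace(filtered, fs=trace.fs, t0=trace.t0)


def pressure_speed(filtered: PressureTrace) -> tuple[np.ndarray, np.ndarray]:
    """Rate of pressure change in kPa/s.

    First difference multiplied by the acquisition rate; the n-1 values are
    timestamped at the midpoints between samples.
    """
    speed = np.diff(filtered.samples) * filtered.fs
    mid_times = filtered.t0 + (np.arange(speed.size) + 0.5) / filtered.fs
    return mid_times, speed


def detect_sound_onset(sound: SoundTrace,
                       threshold: float = ONSET_SOUND_THRESHOLD_PA,
                       power_window: float = 1e-3,
                       hold_time: float = 2e-3) -> float | None:
    """First time the running RMS amplitude crosses ``threshold`` and stays
    above it for at least ``hold_time`` (debounce against isolated clicks).

    Returns None when the criterion is never met.
    """
    if threshold <= 0 or power_window <= 0:
        raise InvalidParameterError("threshold and power_window must be positive")
    rms = running_rms(sound.samples, sound.fs, power_window)
    above = rms >= threshold
    hold = max(1, int(round(hold_time * sound.fs)))
    if hold > 1:
        # sliding all-true test: window sum of the boolean mask equals hold
        csum = np.concatenate(([0], np.cumsum(above)))
        wsum = csum[hold:] - csum[:-hold]
        idx = np.flatnonzero(wsum == hold)
    else:
        idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    return sound.t0 + idx[0] / sound.fs


def compute_ptp(pressure: PressureTrace, sound: SoundTrace,
                threshold: float = ONSET_SOUND_THRESHOLD_PA,
                power_window: float = 1e-3,
                hold_time: float = 2e-3,
                cutoff_hz: float = 500.0) -> OnsetResult:
    """PTP and S_ptp of one trial from synchronized pressure and sound.

    PTP is the filtered pressure at the sound-onset time; S_ptp is the
    pressure speed at the nearest difference midpoint.
    """
    if pressure.fs != sound.fs:
        raise InvalidParameterError(
            f"pressure fs {pressure.fs} != sound fs {sound.fs}"
        )
    if pressure.n != sound.n or pressure.t0 != sound.t0:
        raise InvalidParameterError("pressure and sound traces are misaligned")

    onset = detect_sound_onset(sound, threshold=threshold,
                               power_window=power_window, hold_time=hold_time)
    if onset is None:
        return OnsetResult(detected=False, threshold_used=threshold)

    filtered = lowpass_pressure(pressure, cutoff_hz=cutoff_hz)
    idx = int(round((onset - filtered.t0) * filtered.fs))
    idx = min(max(idx, 0), filtered.n - 1)
    ptp = float(filtered.samples[idx])
    _, speed = pressure_speed(filtered)
    s_idx = min(max(idx, 0), speed.size - 1)
    return OnsetResult(detected=True, onset_time=float(onset), ptp=ptp,
                       s_ptp=float(speed[s_idx]), threshold_used=threshold)
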