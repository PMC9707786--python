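"""Cross-modal synchronization, identity regression and f_o summaries.

Sound and pressure are resampled to the video frame rate so that every
modality shares one clock; the vibration-causes-sound check is an ordinary
least-squares regression of sound f_o on vibration f_o, whose slope should
sit on the identity line when the filmed structure generates the sound.
f_o ranges per structure or call type are summarised as
min/quartiles/max (boxplots whose whiskers are the full range).
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly
from scipy.stats import linregress

from .errors import InsufficientDataError, InvalidParameterError
from .fo import FoTrack, yin_f0
from .signals import SoundTrace, running_rms


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "n": self.n,
                "residual_sd": self.residual_sd}


@dataclass
class RangeSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n: int

    def to_dict(self) -> dict:
        return {"min_hz": self.minimum, "q1_hz": self.q1,
                "median_hz": self.median, "q3_hz": self.q3,
                "max_hz": self.maximum, "n": self.n}


def resample_to_framerate(signal: np.ndarray, fs: float, fps: float) -> np.ndarray:
    """Anti-aliased polyphase resampling from ``fs`` to the video rate.

    Output length is ``ceil(n * fps / fs)``; the first output sample keeps
    the timestamp of the first input sample.
    """
    x = np.asarray(signal, dtype=float)
    if fps > fs:
        raise InvalidParameterError(f"cannot resample up from {fs} to {fps} Hz")
    if fps == fs:
        return x.copy()
    frac = Fraction(fps / fs).limit_denominator(10_000)
    return resample_poly(x, frac.numerator, frac.denominator)


def identity_regression(f0_vibration: FoTrack, f0_sound: FoTrack,
                        max_dt: float | None = None) -> RegressionResult:
    """OLS of sound f_o on vibration f_o over hops valid in both tracks.

    Tracks must share hop times (``max_dt`` tolerance, default half a
    hop); the fit includes an intercept — identity corresponds to slope 1,
    intercept 0.
    """
    tv, ts = f0_vibration.times, f0_sound.times
    n = min(tv.size, ts.size)
    if n == 0:
        raise InsufficientDataError("empty f_o tracks")
    if max_dt is None:
        max_dt = 0.5 * np.median(np.diff(tv)) if tv.size > 1 else np.inf
    aligned = np.abs(tv[:n] - ts[:n]) <= max_dt
    both = aligned & f0_vibration.valid[:n] & f0_sound.valid[:n]
    if both.sum() < 3:
        raise InsufficientDataError(
            f"only {int(both.sum())} shared valid hops; need >= 3"
        )
    x = f0_vibration.f0[:n][both]
    y = f0_sound.f0[:n][both]
    if np.ptp(x) == 0:
        # degenerate perfectly-constant vibration: fit through the cloud
        slope, intercept, r = 1.0, float(np.mean(y - x)), np.nan
        resid = y - (x + intercept)
        r2 = 1.0 if np.allclose(resid, 0) else 0.0
    else:
        fit = linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue ** 2)
        resid = y - (slope * x + intercept)
    ddof = min(2, x.size - 1)
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / max(x.size - ddof, 1)))
    return RegressionResult(slope, intercept, r2, int(x.size), residual_sd)


def fo_range_summary(f0_values) -> RangeSummary:
    """Five-number summary of an f_o collection (Hz).

    Quartiles use linear interpolation between closest order statistics;
    whiskers are the raw minimum and maximum with no outlier trimming.
    """
    vals = np.asarray(list(f0_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InsufficientDataError("no f_o values to summarise")
    q = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0], method="linear")
    return RangeSummary(*(float(v) for v in q), n=int(vals.size))


def segment_calls(sound: SoundTrace, min_gap: float = 0.01,
                  floor: float = 5e-4, rms_window: float = 5e-4) -> list:
    """Intervals (t_start, t_end) where the running RMS exceeds ``floor``,
    merged across gaps shorter than ``min_gap`` — the call-selection step
    for in-vivo recordings. Feed each interval to yin for its f_o
    distribution."""
    rms = running_rms(sound.samples, sound.fs, rms_window)
    above = rms > floor
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1]) / sound.fs < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(sound.t0 + s / sound.fs, sound.t0 + e / sound.fs) for s, e in merged]


def call_f0_distribution(sound: SoundTrace, intervals, f0_min: float = 1000.0,
                         hop: int = 256, ap_threshold: float = 0.1) -> np.ndarray:
    """Pooled valid yin f_o estimates over a list of call intervals."""
    out = []
    for t0, t1 in intervals:
        seg = sound.slice_time(t0, t1)
        window = int(np.ceil(2 * sound.fs / f0_min))
        if seg.n < window:
            continue
        track = yin_f0(seg.samples, seg.fs, window=window,
                       hop=min(hop, max(1, seg.n - window)),
                       ap_threshold=ap_threshold, t0=seg.t0)
        out.append(track.f0[track.valid])
    return np.concatenate(out) if out else np.array([])
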