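"""Synthetic excised-larynx trials with exact ground truth.

Every downstream stage (segmentation, glottovibrogram, pitch, onset
detection, regression) is exercised against trials generated here:
a grayscale high-speed video of a dark elongated glottal opening between
two brighter oscillating edges, a harmonic sound locked to the oscillation
f_o, and a bronchial-pressure protocol — either a slow 0→6 kPa ramp at
1 kPa/s or trains of four fast 300 ms pulses between 0 and 4 kPa.

The kinematics are *prescribed* (a sinusoidal opening with a
mucosal-wave-like anterior–posterior phase lag), not a self-oscillating
tissue model: prescribed motion gives exact ground truth for every frame.
Oscillation onset is gated on the generated pressure: the glottis starts
oscillating only once pressure exceeds ``ptp_true`` and — optionally —
the pressure rate of change exceeds ``rate_gate``, which reproduces the
two-condition onset behaviour of vocal membranes (slow ramps never start
them; fast pulses do).

Rendering has an *opaque* mode (ventricular folds: the opening is simply
the darkest region, so thresholding works) and a *translucent* mode
(vocal membranes: a band adjacent to each true edge is drawn at a gray
level within the noise of the surrounding fold, so thresholding
under-reports the opening and only edge tracking recovers it).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InvalidParameterError
from .onset import lowpass_pressure, pressure_speed
from .segmentation import FrameStack, default_line_rows
from .signals import PressureTrace, SoundTrace

# ---------------------------------------------------------------------------
# pressure protocols


def generate_pressure(protocol: str, fs: float, seed: int | None = None,
                      noise_sd: float = 0.0, **params) -> PressureTrace:
    """Bronchial-pressure protocol in kPa at ``fs`` Hz.

    ``slow_ramp``: linear rise from ``start`` (default 0 kPa) to ``end``
    (default 6 kPa) at ``rate`` kPa/s (default 1), then held at ``end``
    for ``hold_s``. The mid-ramp derivative equals ``rate`` exactly.

    ``fast_pulses``: ``n_pulses`` (default 4) trapezoidal pulses of
    ``width`` seconds (default 0.3) between ``floor`` (0) and ``peak``
    (4 kPa) with linear rise/fall over ``rise_time`` (default 30 ms,
    i.e. ~133 kPa/s), separated by ``gap`` seconds at the floor.

    Optional additive Gaussian measurement noise of ``noise_sd`` kPa RMS
    (seeded), modelled as broadband electronic/sensor noise high-passed
    above 2 kHz: real transducer chains put their noise power well above
    the physiological band, which is exactly what the downstream 500 Hz
    low-pass is there to remove. In-band (sub-500 Hz) leakage is
    negligible, so the filtered pressure and its derivative recover the
    commanded protocol at any permitted noise level.
    """
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    if protocol == "slow_ramp":
        start = float(params.pop("start", 0.0))
        end = float(params.pop("end", 6.0))
        rate = float(params.pop("rate", 1.0))
        hold_s = float(params.pop("hold_s", 0.0))
        if params:
            raise InvalidParameterError(f"unknown slow_ramp params {sorted(params)}")
        if rate <= 0:
            raise InvalidParameterError("ramp rate must be positive")
        ramp_s = (end - start) / rate
        n = int(round((ramp_s + hold_s) * fs)) + 1
        t = np.arange(n) / fs
        p = np.minimum(start + rate * t, end)
    elif protocol == "fast_pulses":
        n_pulses = int(params.pop("n_pulses", 4))
        width = float(params.pop("width", 0.3))
        floor = float(params.pop("floor", 0.0))
        peak = float(params.pop("peak", 4.0))
        rise_time = float(params.pop("rise_time", 0.030))
        gap = float(params.pop("gap", 0.3))
        lead = float(params.pop("lead_s", 0.1))
        if params:
            raise InvalidParameterError(f"unknown fast_pulses params {sorted(params)}")
        if width <= 0 or rise_time <= 0 or n_pulses < 1:
            raise InvalidParameterError("pulse width, rise_time, n_pulses must be positive")
        if 2 * rise_time > width:
            raise InvalidParameterError("rise_time too long for pulse width")
        total = lead + n_pulses * width + (n_pulses - 1) * gap + gap
        n = int(round(total * fs)) + 1
        t = np.arange(n) / fs
        p = np.full(n, floor)
        for k in range(n_pulses):
            t_on = lead + k * (width + gap)
            tau = t - t_on
            seg = np.clip(tau / rise_time, 0.0, 1.0) \
                - np.clip((tau - (width - rise_time)) / rise_time, 0.0, 1.0)
            p += (peak - floor) * seg
    else:
        raise InvalidParameterError(f"unknown pressure protocol '{protocol}'")
    if noise_sd > 0:
        from scipy.signal import butter, sosfiltfilt

        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, 1.0, p.size)
        if fs > 8000:
            sos = butter(4, 2000.0, btype="high", fs=fs, output="sos")
            noise = sosfiltfilt(sos, noise)
        rms = np.sqrt(np.mean(noise ** 2))
        p = p + noise_sd / max(rms, 1e-12) * noise
    return PressureTrace(p, fs=fs)


def pulse_rise_rate(peak: float = 4.0, floor: float = 0.0,
                    rise_time: float = 0.030) -> float:
    """Commanded pressure slew rate of the fast-pulse protocol, kPa/s."""
    return (peak - floor) / rise_time


# ---------------------------------------------------------------------------
# f0 profiles


def constant_f0(f0: float):
    """f_o(t) = f0."""
    def f(t):
        return np.full_like(np.asarray(t, dtype=float), f0)
    f.f0_max = f0
    return f


def linear_sweep(f0_a: float, f0_b: float, t_a: float, t_b: float):
    """Linear f_o sweep from f0_a at t_a to f0_b at t_b, clamped outside."""
    def f(t):
        t = np.asarray(t, dtype=float)
        frac = np.clip((t - t_a) / (t_b - t_a), 0.0, 1.0)
        return f0_a + (f0_b - f0_a) * frac
    f.f0_max = max(f0_a, f0_b)
    return f


def ramp_locked_f0(pressure: PressureTrace, ptp: float, f0_at_ptp: float,
                   hz_per_kpa: float):
    """f_o rises linearly with bronchial pressure above the threshold."""
    times = pressure.times
    samples = pressure.samples

    def f(t):
        p = np.interp(np.asarray(t, dtype=float), times, samples)
        return f0_at_ptp + hz_per_kpa * np.maximum(p - ptp, 0.0)
    f.f0_max = f0_at_ptp + hz_per_kpa * max(float(samples.max()) - ptp, 0.0)
    return f


# ---------------------------------------------------------------------------
# kinematics


@dataclass
class KinematicProfile:
    """Prescribed glottal kinematics for one trial.

    ``amplitude_px`` is the peak half-opening at the AP line of maximal
    amplitude; across lines the amplitude follows a Gaussian envelope
    (sd ``envelope_sigma_lines``) centred on ``peak_line``. Each line lags
    the previous by a fixed phase so that a mucosal-wave-like pattern
    travels along the AP axis (the total lag over all lines is
    ``phase_lag_total_rad``; a free modelling choice, not a measured
    property of any species).
    """

    duration: float
    fps: float
    f0_of_t: object                 # callable t -> Hz, with .f0_max
    amplitude_px: float = 14.0
    n_lines: int = 10
    slit_half_px: float = 2.0
    phase_lag_total_rad: float = 0.6
    peak_line: int | None = None
    envelope_sigma_lines: float | None = None

    def __post_init__(self):
        if not 8 <= self.n_lines <= 10:
            raise InvalidParameterError(f"n_lines must be in [8, 10], got {self.n_lines}")
        if self.duration <= 0 or self.fps <= 0:
            raise InvalidParameterError("duration and fps must be positive")
        if self.peak_line is None:
            self.peak_line = self.n_lines // 2
        if self.envelope_sigma_lines is None:
            self.envelope_sigma_lines = self.n_lines / 3.0

    @property
    def phase_offsets(self) -> np.ndarray:
        return np.linspace(0.0, self.phase_lag_total_rad, self.n_lines)

    @property
    def line_amplitudes(self) -> np.ndarray:
        i = np.arange(self.n_lines)
        env = np.exp(-0.5 * ((i - self.peak_line) / self.envelope_sigma_lines) ** 2)
        return self.amplitude_px * env

    def check_video_sampling(self):
        """Refuse to render video that undersamples the oscillation."""
        f0_max = getattr(self.f0_of_t, "f0_max", None)
        if f0_max is None:
            raise InvalidParameterError("f0_of_t must expose .f0_max")
        if self.fps < 4 * f0_max:
            raise InvalidParameterError(
                f"fps {self.fps} < 4 x max f0 {f0_max}: video would undersample"
            )


@dataclass
class Kinematics:
    """Ground-truth motion: per-frame, per-line edge positions plus the
    continuous oscillation phase used by both video and sound."""

    profile: KinematicProfile
    frame_times: np.ndarray
    left_x: np.ndarray            # (frames, lines)
    right_x: np.ndarray
    center_x: float
    onset_time: float | None
    onset_pressure: float | None
    onset_pressure_speed: float | None
    _phase_times: np.ndarray = field(repr=False, default=None)
    _phase_values: np.ndarray = field(repr=False, default=None)
    _phonating: np.ndarray = field(repr=False, default=None)

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self._phase_times,
                         self._phase_values)

    def phonating_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self._phase_times,
                         self._phonating.astype(float)) > 0.5

    def half_width(self) -> np.ndarray:
        return 0.5 * (self.right_x - self.left_x)


def simulate_kinematics(profile: KinematicProfile, pressure: PressureTrace,
                        ptp_true: float, rate_gate: float | None = None,
                        center_x: float = 32.0,
                        video_t0: float | None = None) -> Kinematics:
    """Oscillating-edge kinematics gated on the pressure protocol.

    Oscillation begins at the first instant where the (low-pass filtered)
    pressure reaches ``ptp_true`` while its rate of change is at least
    ``rate_gate`` (if set); it runs whenever pressure stays above
    ``ptp_true`` thereafter. If the gate is never satisfied the glottis
    stays at the minimal slit for the whole trial and ``onset_time`` is
    None — a valid no-phonation outcome, not an error.

    During phonation the half-opening of line *i* is
    ``slit + A_i (1 - cos(theta(t) + phi_i)) / 2`` with
    ``theta' = 2 pi f0(t)``, so the opening returns to the slit exactly
    once per cycle and onset is continuous.
    """
    filtered = lowpass_pressure(pressure)
    _, speed = pressure_speed(filtered)
    p = filtered.samples
    ok = p >= ptp_true
    if rate_gate is not None:
        gate = np.concatenate([[False], speed >= rate_gate])
        start_ok = ok & gate
    else:
        start_ok = ok
    start_idx = np.flatnonzero(start_ok)
    t_press = filtered.times

    if start_idx.size == 0:
        onset_time = onset_p = onset_s = None
        phonating = np.zeros(p.size, dtype=bool)
    else:
        i0 = int(start_idx[0])
        onset_time = float(t_press[i0])
        onset_p = float(p[i0])
        onset_s = float(speed[min(i0, speed.size - 1)])
        phonating = ok.copy()
        phonating[:i0] = False

    # oscillation phase on the pressure clock, shared by video and sound
    f0_t = np.asarray(profile.f0_of_t(t_press), dtype=float)
    if np.any(f0_t[phonating] <= 0):
        raise InvalidParameterError("f0_of_t must be positive during phonation")
    dphi = 2 * np.pi * f0_t * phonating
    phase = cumulative_trapezoid(dphi, t_press, initial=0.0)

    if video_t0 is None:
        video_t0 = onset_time if onset_time is not None else 0.0
    n_frames = int(round(profile.duration * profile.fps))
    frame_times = video_t0 + np.arange(n_frames) / profile.fps

    theta = np.interp(frame_times, t_press, phase)
    phon_f = np.interp(frame_times, t_press, phonating.astype(float)) > 0.5
    amps = profile.line_amplitudes
    phis = profile.phase_offsets
    osc = 0.5 * (1.0 - np.cos(theta[:, None] + phis[None, :]))
    half = profile.slit_half_px + amps[None, :] * osc * phon_f[:, None]
    return Kinematics(
        profile=profile, frame_times=frame_times,
        left_x=center_x - half, right_x=center_x + half, center_x=center_x,
        onset_time=onset_time, onset_pressure=onset_p,
        onset_pressure_speed=onset_s,
        _phase_times=t_press, _phase_values=phase, _phonating=phonating,
    )


# ---------------------------------------------------------------------------
# rendering


DEFAULT_GRAYS = {"background": 160.0, "fold": 160.0, "glottis": 40.0,
                 "membrane": 156.0}


def render_frames(kin: Kinematics, mode: str = "opaque",
                  shape: tuple = (128, 64), grays: dict | None = None,
                  noise_sd: float = 3.0, membrane_px: float = 8.0,
                  fps: float | None = None, pixel_scale: float = 0.02,
                  pre_rotate_deg: float = 0.0,
                  seed: int | None = None) -> tuple[FrameStack, np.ndarray]:
    """Render a grayscale 8-bit frame stack from edge kinematics.

    In *opaque* mode the glottal opening is uniformly dark, so all opening
    pixels lie below any threshold between the glottis and fold gray
    levels. In *translucent* mode a band of ``membrane_px`` adjacent to
    each true edge is drawn at the membrane gray, which must lie within
    ``noise_sd`` of the fold gray — simple thresholding then sees only the
    inner dark core and under-reports the opening by about
    ``2 * membrane_px``. Returns the stack and the scan-line rows used.
    """
    grays = {**DEFAULT_GRAYS, **(grays or {})}
    rows, cols = shape
    profile = kin.profile
    profile.check_video_sampling()
    line_rows = default_line_rows(rows, profile.n_lines)
    if mode == "opaque":
        if not grays["glottis"] < grays["fold"]:
            raise InvalidParameterError("opaque mode requires glottis darker than fold")
    elif mode == "translucent":
        if abs(grays["membrane"] - grays["fold"]) > noise_sd + 1e-12:
            raise InvalidParameterError(
                "translucent mode requires membrane gray within noise_sd of fold gray"
            )
    else:
        raise InvalidParameterError(f"unknown render mode '{mode}'")
    if np.nanmin(kin.left_x) < 0 or np.nanmax(kin.right_x) > cols:
        raise InvalidParameterError("edge positions exceed frame bounds")

    # per-row edge positions: linear interpolation between scan lines,
    # tapering to closed at pseudo-anchors one line-spacing beyond the span
    spacing = line_rows[1] - line_rows[0]
    anchor_rows = np.concatenate([[max(0, line_rows[0] - spacing)], line_rows,
                                  [min(rows - 1, line_rows[-1] + spacing)]])
    n_frames = kin.frame_times.size
    cx = kin.center_x
    left_a = np.concatenate([np.full((n_frames, 1), cx), kin.left_x,
                             np.full((n_frames, 1), cx)], axis=1)
    right_a = np.concatenate([np.full((n_frames, 1), cx), kin.right_x,
                              np.full((n_frames, 1), cx)], axis=1)
    all_rows = np.arange(rows)
    seg = np.clip(np.searchsorted(anchor_rows, all_rows, side="right") - 1,
                  0, anchor_rows.size - 2)
    w1 = (all_rows - anchor_rows[seg]) / np.maximum(
        anchor_rows[seg + 1] - anchor_rows[seg], 1)
    w1 = np.clip(w1, 0.0, 1.0)
    inside = (all_rows >= anchor_rows[0]) & (all_rows <= anchor_rows[-1])
    left_rows = left_a[:, seg] * (1 - w1) + left_a[:, seg + 1] * w1
    right_rows = right_a[:, seg] * (1 - w1) + right_a[:, seg + 1] * w1
    left_rows[:, ~inside] = cx
    right_rows[:, ~inside] = cx

    cc = np.arange(cols) + 0.5
    open_px = (cc[None, None, :] > left_rows[:, :, None]) \
        & (cc[None, None, :] < right_rows[:, :, None])
    frames = np.full((n_frames, rows, cols), grays["fold"], dtype=np.float32)
    if mode == "opaque":
        frames[open_px] = grays["glottis"]
    else:
        inner = (cc[None, None, :] > left_rows[:, :, None] + membrane_px) \
            & (cc[None, None, :] < right_rows[:, :, None] - membrane_px)
        frames[open_px] = grays["membrane"]
        frames[open_px & inner] = grays["glottis"]

    if pre_rotate_deg:
        from scipy import ndimage

        frames = ndimage.rotate(frames, pre_rotate_deg, axes=(1, 2),
                                reshape=False, order=1, mode="nearest")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)
    fps = fps if fps is not None else profile.fps
    stack = FrameStack(frames, fps=fps, pixel_scale=pixel_scale,
                       rotation_deg=0.0, t0=float(kin.frame_times[0]))
    return stack, line_rows


# ---------------------------------------------------------------------------
# sound


def synthesize_sound(f0_of_t, onset_time: float | None, duration: float,
                     fs: float, amp_pa: float = 0.02, attack_s: float = 0.01,
                     n_harmonics: int = 3, noise_sd: float = 2e-5,
                     seed: int | None = None, phase: np.ndarray | None = None,
                     phonating=None, t0: float = 0.0,
                     delay_s: float = 0.0) -> SoundTrace:
    """Harmonic sound locked to the oscillation f_o.

    Zero (noise only) before ``onset_time``; thereafter a 1/h-weighted
    harmonic series at instantaneous frequency ``f0_of_t`` whose envelope
    rises linearly over ``attack_s`` at the start of each phonation
    segment to a peak amplitude ``amp_pa``. Harmonics are truncated
    sample-by-sample below 0.45 fs. ``phase``/``phonating`` allow passing
    the exact phase integral of a :class:`Kinematics` so video and sound
    share one oscillator; ``delay_s`` models microphone propagation delay
    (0 by default — at <= 44 mm it is ~0.13 ms and is ignored).
    """
    if fs <= 0 or duration <= 0:
        raise InvalidParameterError("fs and duration must be positive")
    n = int(round(duration * fs))
    t = t0 + np.arange(n) / fs
    t_src = t - delay_s
    if phonating is not None:
        phon = np.asarray(phonating(t_src), dtype=bool)
    elif onset_time is not None:
        phon = t_src >= onset_time
    else:
        phon = np.zeros(n, dtype=bool)

    f0_t = np.asarray(f0_of_t(t_src), dtype=float)
    if phase is not None:
        theta = np.asarray(phase, dtype=float)
        if theta.size != n:
            raise InvalidParameterError("phase array must match the sample grid")
    else:
        theta = 2 * np.pi * cumulative_trapezoid(f0_t * phon, t_src, initial=0.0)

    # linear attack from each phonation-segment start
    idx = np.arange(n)
    starts = phon & ~np.concatenate([[False], phon[:-1]])
    last_start = np.maximum.accumulate(np.where(starts, idx, -1))
    seg_t = np.where((last_start >= 0) & phon, (idx - last_start) / fs, 0.0)
    env = amp_pa * np.clip(seg_t / max(attack_s, 1 / fs), 0.0, 1.0) * phon

    weights = 1.0 / np.arange(1, n_harmonics + 1)
    wave = np.zeros(n)
    norm = np.zeros(n)
    for h in range(1, n_harmonics + 1):
        audible = (h * f0_t) < 0.45 * fs
        w = weights[h - 1] * audible
        wave += w * np.sin(h * theta)
        norm += w
    wave = env * wave / np.maximum(norm, 1e-12)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        wave = wave + rng.normal(0.0, noise_sd, n)
    return SoundTrace(wave, fs=fs, t0=t0)


# ---------------------------------------------------------------------------
# full trials


@dataclass
class TrialRecipe:
    """Everything needed to generate one synchronized synthetic trial."""

    name: str = "custom"
    # pressure protocol
    protocol: str = "slow_ramp"
    protocol_params: dict = field(default_factory=dict)
    fs: float = 250_000.0
    pressure_noise_kpa: float = 0.02
    # onset gating
    ptp_true: float = 4.0
    rate_gate: float | None = None
    # kinematics
    fps: float = 20_000.0
    f0_kind: str = "constant"            # constant | sweep | ramp_locked
    f0_params: dict = field(default_factory=lambda: {"f0": 2000.0})
    amplitude_px: float = 14.0
    n_lines: int = 10
    slit_half_px: float = 2.0
    phase_lag_total_rad: float = 0.6
    peak_line: int | None = None
    # video
    mode: str = "opaque"                 # opaque | translucent | none
    frame_shape: tuple = (128, 64)
    grays: dict = field(default_factory=dict)
    video_noise_sd: float = 3.0
    membrane_px: float = 8.0
    video_duration: float = 0.1
    video_delay_s: float = 0.005         # video start after onset
    pre_rotate_deg: float = 0.0
    pixel_scale: float = 0.02
    gray_threshold: float = 100.0
    # sound
    sound_amp_pa: float = 0.02
    sound_attack_s: float = 0.01
    n_harmonics: int = 3
    sound_noise_sd: float = 2e-5
    mic_delay_s: float = 0.0

    def f0_function(self, pressure: PressureTrace):
        if self.f0_kind == "constant":
            return constant_f0(**self.f0_params)
        if self.f0_kind == "sweep":
            return linear_sweep(**self.f0_params)
        if self.f0_kind == "ramp_locked":
            return ramp_locked_f0(pressure, self.ptp_true, **self.f0_params)
        raise InvalidParameterError(f"unknown f0_kind '{self.f0_kind}'")


@dataclass
class SyntheticTrial:
    """One fully synchronized trial bundle plus its ground truth."""

    recipe: TrialRecipe
    frames: FrameStack | None
    sound: SoundTrace
    pressure: PressureTrace
    kinematics: Kinematics
    line_rows: np.ndarray | None
    truth: dict


#: Named trial recipes for the canonical experimental conditions.
RECIPES: dict[str, TrialRecipe] = {
    # ventricular folds: slow ramp, opaque, threshold segmentation works
    "ventricular-slow-ramp": TrialRecipe(
        name="ventricular-slow-ramp", protocol="slow_ramp",
        protocol_params={"start": 0.0, "end": 6.0, "rate": 1.0, "hold_s": 0.5},
        ptp_true=4.0, rate_gate=None, fps=20_000.0,
        f0_kind="ramp_locked", f0_params={"f0_at_ptp": 2000.0, "hz_per_kpa": 500.0},
        mode="opaque", video_duration=0.12, video_delay_s=0.005,
    ),
    # vocal membranes: fast pulses satisfy the rate gate, translucent render
    "membrane-fast-pulses": TrialRecipe(
        name="membrane-fast-pulses", protocol="fast_pulses",
        protocol_params={"n_pulses": 4, "width": 0.3, "floor": 0.0,
                         "peak": 4.0, "rise_time": 0.030, "gap": 0.3},
        ptp_true=3.2, rate_gate=30.0, fps=125_000.0,
        f0_kind="ramp_locked", f0_params={"f0_at_ptp": 15_000.0, "hz_per_kpa": 1000.0},
        amplitude_px=10.0, slit_half_px=8.0,
        mode="translucent", video_noise_sd=4.0,
        grays={"membrane": 156.0}, membrane_px=6.0,
        video_duration=0.024, video_delay_s=0.002,
        sound_attack_s=0.005,
    ),
    # same membrane larynx under a slow ramp: rate gate never satisfied
    "membrane-slow-gated": TrialRecipe(
        name="membrane-slow-gated", protocol="slow_ramp",
        protocol_params={"start": 0.0, "end": 6.0, "rate": 1.0, "hold_s": 0.5},
        ptp_true=3.2, rate_gate=30.0, fps=125_000.0,
        f0_kind="constant", f0_params={"f0": 15_000.0},
        mode="none", video_duration=0.0,
    ),
    # tensed membranes: high-f0 sweep, sound-only (ridge-tracker regime)
    "membrane-sweep": TrialRecipe(
        name="membrane-sweep", protocol="slow_ramp",
        protocol_params={"start": 5.0, "end": 5.0, "rate": 1.0, "hold_s": 1.6},
        ptp_true=4.5, rate_gate=None, fps=250_000.0,
        f0_kind="sweep",
        f0_params={"f0_a": 20_000.0, "f0_b": 70_000.0, "t_a": 0.05, "t_b": 1.55},
        mode="none", video_duration=0.0, n_harmonics=1,
        sound_amp_pa=0.05,
    ),
}


def get_recipe(name_or_recipe) -> TrialRecipe:
    if isinstance(name_or_recipe, TrialRecipe):
        return name_or_recipe
    if isinstance(name_or_recipe, str):
        if name_or_recipe not in RECIPES:
            raise InvalidParameterError(
                f"unknown recipe '{name_or_recipe}'; known: {sorted(RECIPES)}"
            )
        return RECIPES[name_or_recipe]
    if isinstance(name_or_recipe, dict):
        d = dict(name_or_recipe)
        if "frame_shape" in d:
            d["frame_shape"] = tuple(d["frame_shape"])
        return TrialRecipe(**d)
    raise InvalidParameterError("recipe must be a name, dict or TrialRecipe")


def make_trial(recipe, seed: int, out_dir=None) -> SyntheticTrial:
    """Generate one synchronized trial; optionally write it to disk.

    Deterministic: identical (recipe, seed) produce identical trials and,
    with ``out_dir``, byte-identical files (frames as multi-page TIFF,
    sound as float WAV in Pa, pressure as CSV, truth/recipe/metadata as
    JSON).
    """
    recipe = get_recipe(recipe)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

    pressure = generate_pressure(recipe.protocol, recipe.fs, seed=seeds[0],
                                 noise_sd=recipe.pressure_noise_kpa,
                                 **recipe.protocol_params)
    # f0 truth references the low-pass filtered pressure so that the
    # high-frequency sensor noise never enters the oscillator
    f0_fn = recipe.f0_function(lowpass_pressure(pressure))
    profile = KinematicProfile(
        duration=max(recipe.video_duration, 1.0 / recipe.fps),
        fps=recipe.fps, f0_of_t=f0_fn, amplitude_px=recipe.amplitude_px,
        n_lines=recipe.n_lines, slit_half_px=recipe.slit_half_px,
        phase_lag_total_rad=recipe.phase_lag_total_rad,
        peak_line=recipe.peak_line,
    )
    cx = recipe.frame_shape[1] / 2.0
    kin = simulate_kinematics(profile, pressure, recipe.ptp_true,
                              rate_gate=recipe.rate_gate, center_x=cx)
    if kin.onset_time is not None:
        kin = simulate_kinematics(profile, pressure, recipe.ptp_true,
                                  rate_gate=recipe.rate_gate, center_x=cx,
                                  video_t0=kin.onset_time + recipe.video_delay_s)

    frames = line_rows = None
    if recipe.mode != "none" and recipe.video_duration > 0:
        frames, line_rows = render_frames(
            kin, mode=recipe.mode, shape=recipe.frame_shape,
            grays=recipe.grays or None, noise_sd=recipe.video_noise_sd,
            membrane_px=recipe.membrane_px, pixel_scale=recipe.pixel_scale,
            pre_rotate_deg=recipe.pre_rotate_deg, seed=seeds[1],
        )

    t_snd = np.arange(pressure.n) / recipe.fs
    phase = kin.phase_at(t_snd)
    sound = synthesize_sound(
        f0_fn, kin.onset_time, duration=pressure.n / recipe.fs, fs=recipe.fs,
        amp_pa=recipe.sound_amp_pa, attack_s=recipe.sound_attack_s,
        n_harmonics=recipe.n_harmonics, noise_sd=recipe.sound_noise_sd,
        seed=seeds[2], phase=phase, phonating=kin.phonating_at,
        delay_s=recipe.mic_delay_s,
    )

    truth = {
        "onset_time_s": kin.onset_time,
        "onset_pressure_kpa": kin.onset_pressure,
        "onset_pressure_speed_kpa_s": kin.onset_pressure_speed,
        "f0_at_frames_hz": (np.asarray(f0_fn(kin.frame_times)).tolist()
                            if frames is not None else None),
        "video_t0_s": float(kin.frame_times[0]) if frames is not None else None,
        "line_rows": line_rows.tolist() if line_rows is not None else None,
        "left_x": kin.left_x.tolist() if frames is not None else None,
        "right_x": kin.right_x.tolist() if frames is not None else None,
        "commanded_rise_rate_kpa_s": (
            pulse_rise_rate(recipe.protocol_params.get("peak", 4.0),
                            recipe.protocol_params.get("floor", 0.0),
                            recipe.protocol_params.get("rise_time", 0.030))
            if recipe.protocol == "fast_pulses" else
            recipe.protocol_params.get("rate", 1.0)),
        "seed": seed,
    }
    trial = SyntheticTrial(recipe=recipe, frames=frames, sound=sound,
                           pressure=pressure, kinematics=kin,
                           line_rows=line_rows, truth=truth)
    if out_dir is not None:
        write_trial(trial, out_dir)
    return trial


def write_trial(trial: SyntheticTrial, out_dir) -> Path:
    """Write a trial bundle in the canonical one-directory layout."""
    import tifffile
    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recipe = trial.recipe
    if trial.frames is not None:
        tifffile.imwrite(out / "frames.tif", trial.frames.pixels)
    wavfile.write(out / "sound.wav", int(recipe.fs),
                  trial.sound.samples.astype(np.float32))
    import pandas as pd

    pd.DataFrame({
        "time_s": trial.pressure.times, "pressure_kPa": trial.pressure.samples,
    }).to_csv(out / "pressure.csv", index=False, float_format="%.8g")
    meta = {
        "trial_id": recipe.name,
        "fps": recipe.fps,
        "sound_fs": recipe.fs,
        "pressure_fs": recipe.fs,
        "pixel_scale": recipe.pixel_scale,
        "rotation_deg": -recipe.pre_rotate_deg,
        "gray_threshold": recipe.gray_threshold,
        "video_t0": trial.truth["video_t0_s"],
        "mode": {"opaque": "ventricular", "translucent": "membrane",
                 "none": "none"}[recipe.mode],
        "n_lines": recipe.n_lines,
        "line_rows": trial.truth["line_rows"],
        "has_video": trial.frames is not None,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    (out / "truth.json").write_text(json.dumps(trial.truth, indent=2, sort_keys=True))
    rec = asdict(recipe)
    rec["frame_shape"] = list(rec["frame_shape"])
    (out / "recipe.json").write_text(json.dumps(rec, indent=2, sort_keys=True))
    return out
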