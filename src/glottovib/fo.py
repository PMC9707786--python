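"""Fundamental-frequency estimation.

Two engines cover the full vocal range of the larynx preparations:

* :func:`yin_f0` — the yin autocorrelation-family estimator (difference
  function, cumulative-mean-normalised difference (CMND), absolute
  threshold, parabolic lag refinement). Reliable for f_o below a quarter
  of the sampling rate; used for glottal opening waveforms and for sound
  after resampling to the video frame rate.
* :func:`ridge_f0` — time-frequency ridge tracking on a Hamming-window
  spectrogram (nfft 2048, 50 % overlap) by dynamic programming with a
  linear frequency-jump penalty; used for high f_o (tens of kHz) where
  yin fails.

:func:`select_engine` encodes the fs/4 rule that decides between them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import spectrogram

from .errors import InvalidParameterError

DEFAULT_AP_THRESHOLD = 0.1
DEFAULT_NFFT = 2048
DEFAULT_RIDGE_PENALTY = 1.0  # log-magnitude units per bin of jump


@dataclass
class FoTrack:
    """Time series of f_o estimates with quality gates.

    ``aperiodicity`` is the CMND value at the chosen lag for yin, or a
    spectral-concentration complement for the ridge engine; both lie in
    [0, 1] with 0 meaning perfectly periodic / concentrated.
    """

    times: np.ndarray
    f0: np.ndarray
    aperiodicity: np.ndarray
    power: np.ndarray
    valid: np.ndarray
    engine: str = "yin"
    fs: float = 0.0

    def __post_init__(self):
        for name in ("times", "f0", "aperiodicity", "power"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.times, "f0_hz": self.f0,
            "aperiodicity": self.aperiodicity, "power": self.power,
            "valid": self.valid, "engine": self.engine,
        })


def _cmnd_frames(frames: np.ndarray, tau_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Difference function and its cumulative-mean normalisation per frame.

    ``frames`` has shape (n_frames, window) with window >= 2 * tau_max.
    Both outputs have shape (n_frames, tau_max + 1); CMND column 0 is
    defined as 1. The integration window is fixed at ``tau_max`` terms
    for every lag so all lags average the same number of squared
    differences.
    """
    n, window = frames.shape
    w_int = window - tau_max  # same integration length for every lag
    diff = np.empty((n, tau_max + 1))
    diff[:, 0] = 0.0
    base = frames[:, :w_int]
    for tau in range(1, tau_max + 1):
        d = base - frames[:, tau:tau + w_int]
        diff[:, tau] = np.einsum("ij,ij->i", d, d)
    cum = np.cumsum(diff[:, 1:], axis=1)
    cmnd = np.ones_like(diff)
    taus = np.arange(1, tau_max + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cmnd[:, 1:] = diff[:, 1:] * taus / cum
    cmnd[~np.isfinite(cmnd)] = 1.0
    return diff, cmnd


def _parabolic_min(y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through (i-1, i, i+1); clamped at the edges."""
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom <= 0:
        return float(i), float(y1)
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    return i + shift, float(y1 - 0.25 * (y0 - y2) * shift)


def yin_f0(signal: np.ndarray, fs: float, window: int | None = None,
           hop: int = 10, f0_min: float | None = None,
           ap_threshold: float = DEFAULT_AP_THRESHOLD,
           power_floor: float = 0.0, t0: float = 0.0) -> FoTrack:
    """Yin f_o track of a 1-D signal.

    Parameters
    ----------
    window : analysis span in samples; defaults to ``ceil(2 * fs / f0_min)``.
        Must satisfy window >= 2 * fs / f0_min so the longest candidate
        period fits twice. A window longer than the minimum keeps the lag
        range anchored at ``fs / f0_min`` and spends the extra samples on
        a longer difference integration, which suppresses window-edge
        bias; it also keeps period multiples of in-range f0 out of the
        candidate set (subharmonic protection).
    hop : samples between successive estimates. The default of 10 matches
        the convention of one estimate per 10 video frames when the signal
        is a frame-rate opening waveform; pass an explicit hop (e.g. 256)
        for raw audio.
    ap_threshold : absolute CMND threshold; the first dip below it selects
        the period candidate, and it doubles as the validity gate.
    power_floor : minimal AC power (variance) of an analysis frame for the
        estimate to be flagged valid.

    The estimate per frame is the first CMND local minimum below
    ``ap_threshold``, refined by parabolic interpolation over the raw
    difference function (which, unlike the CMND, is symmetric about the
    true period, so the vertex is unbiased); without any sub-threshold
    dip the global CMND minimum is reported and the aperiodicity gate
    marks the frame invalid. Validity additionally requires f0 <= fs/4,
    above which yin is unreliable.
    """
    x = np.asarray(signal, dtype=float)
    if f0_min is None:
        f0_min = 25.0 if window is None else 2 * fs / window
    if window is None:
        window = int(np.ceil(2 * fs / f0_min))
    if window > x.size:
        raise InvalidParameterError(
            f"window {window} longer than signal ({x.size} samples)"
        )
    if hop < 1:
        raise InvalidParameterError("hop must be >= 1")
    tau_max = min(window // 2, int(np.ceil(fs / f0_min)))
    if tau_max < 2:
        raise InvalidParameterError("window too short for any candidate period")

    starts = np.arange(0, x.size - window + 1, hop)
    idx = starts[:, None] + np.arange(window)[None, :]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)
    power = frames.var(axis=1)

    diff, cmnd = _cmnd_frames(frames, tau_max)

    n = starts.size
    f0 = np.zeros(n)
    ap = np.ones(n)
    for i in range(n):
        row = cmnd[i]
        # subharmonic guard: a dip at the true period that narrowly misses
        # the absolute threshold must still beat a slightly deeper dip at
        # a period multiple, so the bar adapts to the global minimum
        bar = max(ap_threshold, float(row[1:].min()) + 0.05)
        below = np.flatnonzero(row[1:] < bar) + 1
        if below.size:
            tau = below[0]
            while tau + 1 <= tau_max and row[tau + 1] < row[tau]:
                tau += 1
        else:
            tau = int(np.argmin(row[1:]) + 1)
        tau_ref, _ = _parabolic_min(diff[i], tau)
        if tau_ref > 0:
            f0[i] = fs / tau_ref
        ap[i] = min(max(row[tau], 0.0), 1.0)

    times = t0 + (starts + window / 2) / fs
    valid = (power >= power_floor) & (ap <= ap_threshold) \
        & (f0 > 0) & (f0 <= fs / 4)
    return FoTrack(times, f0, ap, power, valid, engine="yin", fs=fs)


def _ridge_dp(log_mag: np.ndarray, penalty: float) -> np.ndarray:
    """Maximum-score frequency path through a (bins x columns) log-magnitude
    spectrogram with cost ``penalty`` per bin of jump between columns.

    The accumulation uses the linear-penalty distance-transform trick, so
    the whole pass is O(bins x columns).
    """
    nb, nc = log_mag.shape
    accs = np.empty((nb, nc))
    accs[:, 0] = log_mag[:, 0]
    for j in range(1, nc):
        accs[:, j] = _linear_penalty_max(accs[:, j - 1], penalty) + log_mag[:, j]
    ridge = np.empty(nc, dtype=int)
    ridge[-1] = int(np.argmax(accs[:, -1]))
    bins = np.arange(nb)
    for j in range(nc - 2, -1, -1):
        ridge[j] = int(np.argmax(accs[:, j] - penalty * np.abs(bins - ridge[j + 1])))
    return ridge


def _linear_penalty_max(v: np.ndarray, penalty: float) -> np.ndarray:
    """out[f] = max_g (v[g] - penalty * |f - g|) in two linear passes."""
    out = v.copy()
    for i in range(1, out.size):
        out[i] = max(out[i], out[i - 1] - penalty)
    for i in range(out.size - 2, -1, -1):
        out[i] = max(out[i], out[i + 1] - penalty)
    return out


def ridge_f0(signal: np.ndarray, fs: float, nfft: int = DEFAULT_NFFT,
             overlap: float = 0.5, penalty_per_bin: float = DEFAULT_RIDGE_PENALTY,
             fmin: float = 0.0, fmax: float | None = None,
             power_floor: float = 0.0, t0: float = 0.0) -> FoTrack:
    """f_o track by spectrogram ridge detection.

    Hamming-window spectrogram (nfft, 50 % overlap by default); the ridge
    is the frequency path maximising the summed log magnitude subject to a
    per-column jump penalty of ``penalty_per_bin`` log units per bin,
    found by dynamic programming. Per column the ridge frequency is
    refined by a parabolic fit over the log magnitude of the three bins
    around the path.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < nfft:
        raise InvalidParameterError(
            f"signal ({x.size} samples) shorter than nfft {nfft}"
        )
    noverlap = int(round(nfft * overlap))
    freqs, times, sxx = spectrogram(
        x, fs=fs, window="hamming", nperseg=nfft, noverlap=noverlap,
        nfft=nfft, mode="magnitude", detrend=False,
    )
    band = (freqs >= fmin) & (freqs <= (fmax if fmax is not None else fs / 2))
    if band.sum() < 3:
        raise InvalidParameterError("frequency band too narrow for ridge tracking")
    freqs_b = freqs[band]
    log_mag = np.log(sxx[band] + 1e-30)

    ridge = _ridge_dp(log_mag, penalty_per_bin)

    df = freqs_b[1] - freqs_b[0]
    n = times.size
    f0 = np.empty(n)
    power = np.empty(n)
    ap = np.empty(n)
    for j in range(n):
        i = ridge[j]
        bin_ref, _ = _parabolic_max(log_mag[:, j], i)
        f0[j] = freqs_b[0] + bin_ref * df
        power[j] = sxx[band][i, j] ** 2
        col = sxx[band][:, j] ** 2
        lo, hi = max(0, i - 2), min(col.size, i + 3)
        conc = col[lo:hi].sum() / max(col.sum(), 1e-300)
        ap[j] = float(np.clip(1.0 - conc, 0.0, 1.0))
    valid = (power >= power_floor) & (f0 > 0)
    return FoTrack(t0 + times, f0, ap, power, valid, engine="ridge", fs=fs)


def _parabolic_max(y: np.ndarray, i: int) -> tuple[float, float]:
    neg_pos, neg_val = _parabolic_min(-y, i)
    return neg_pos, -neg_val


def select_engine(f0_expected_range: tuple[float, float], fs: float) -> str:
    """Engine choice: yin up to and including fs/4, ridge above."""
    f_max = max(f0_expected_range)
    return "yin" if f_max <= fs / 4 else "ridge"
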