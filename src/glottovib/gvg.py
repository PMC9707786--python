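"""Glottovibrogram (GVG) assembly and opening-waveform extraction.

The GVG is the glottal opening width as a function of time and
anterior–posterior (AP) position — the central kymographic summary of a
high-speed recording. Vibration f_o is read from the opening waveform at
the AP position of maximal mean opening.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError
from .segmentation import EdgeTracks

#: longest edge-track dropout (frames) that is silently bridged by linear
#: interpolation; longer gaps abort GVG assembly so that pitch halving from
#: fabricated data cannot occur.
MAX_INTERP_GAP = 3


@dataclass
class Glottovibrogram:
    """Opening width (mm) on a (time x AP position) grid."""

    width: np.ndarray          # (frames, positions), mm, >= 0
    times: np.ndarray          # s, strictly increasing, 1/fps spacing
    ap_positions: np.ndarray   # mm from the anterior end
    source: str                # "threshold" | "edges"
    fps: float
    interpolated: np.ndarray | None = None   # boolean mask of filled gaps

    def __post_init__(self):
        self.width = np.asarray(self.width, dtype=float)
        if self.width.ndim != 2:
            raise InvalidParameterError("width must be (frames, positions)")
        if np.any(self.width < 0):
            raise InvalidParameterError("opening width cannot be negative")

    @property
    def n_interpolated(self) -> int:
        return 0 if self.interpolated is None else int(self.interpolated.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.width, index=pd.Index(self.times, name="time_s"),
                            columns=np.round(self.ap_positions, 6))


def build_gvg(source, *, fps: float | None = None, pixel_scale: float | None = None,
              t0: float = 0.0) -> Glottovibrogram:
    """Assemble a glottovibrogram.

    ``source`` is either a (frames x rows) array of per-frame width
    profiles in mm (threshold path; pass ``fps`` and ``pixel_scale``) or
    an :class:`EdgeTracks` (edge path; width per line = right - left,
    scaled by ``pixel_scale``). Edge-track dropouts up to
    ``MAX_INTERP_GAP`` frames are linearly interpolated and flagged;
    longer gaps raise an error listing the offending frames, and a line
    with no detections at all is a degenerate input.
    """
    if isinstance(source, EdgeTracks):
        if pixel_scale is None:
            raise InvalidParameterError("pixel_scale required for edge tracks")
        fps = fps if fps is not None else source.fps
        if not fps or fps <= 0:
            raise InvalidParameterError("fps must be positive")
        width_px = source.width_px
        width, interp = _fill_gaps(width_px)
        width = np.clip(width, 0.0, None) * pixel_scale
        ap = source.line_rows * pixel_scale
        gvg_source = "edges"
        t0 = t0 or source.t0
    else:
        width = np.asarray(source, dtype=float)
        if width.ndim != 2:
            raise InvalidParameterError("width profiles must be (frames, positions)")
        if fps is None or fps <= 0 or pixel_scale is None:
            raise InvalidParameterError("fps and pixel_scale required")
        interp = np.zeros(width.shape, dtype=bool)
        ap = np.arange(width.shape[1]) * pixel_scale
        gvg_source = "threshold"
    times = t0 + np.arange(width.shape[0]) / fps
    return Glottovibrogram(width, times, ap, gvg_source, fps, interpolated=interp)


def _fill_gaps(width: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    out = width.copy()
    interp = np.zeros(width.shape, dtype=bool)
    n = width.shape[0]
    for j in range(width.shape[1]):
        col = out[:, j]
        nan = np.isnan(col)
        if nan.all():
            raise DegenerateInputError(f"edge line {j} has no defined detections")
        if not nan.any():
            continue
        # locate runs of NaN and check their lengths
        edges = np.diff(nan.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if nan[0]:
            starts.insert(0, 0)
        if nan[-1]:
            ends.append(n)
        too_long = [(s, e) for s, e in zip(starts, ends) if e - s > MAX_INTERP_GAP]
        if too_long:
            frames = ", ".join(f"{s}..{e - 1}" for s, e in too_long)
            raise DegenerateInputError(
                f"edge line {j}: dropout longer than {MAX_INTERP_GAP} frames at {frames}"
            )
        good = np.flatnonzero(~nan)
        col[nan] = np.interp(np.flatnonzero(nan), good, col[good])
        interp[nan, j] = True
    return out, interp


def max_opening_position(gvg: Glottovibrogram) -> int:
    """AP index where the time-mean opening is maximal.

    Exact ties resolve to the anterior-most (lowest) index.
    """
    mean = gvg.width.mean(axis=0)
    if not np.any(np.isfinite(mean)):
        raise DegenerateInputError("glottovibrogram has no finite columns")
    return int(np.argmax(mean))


def opening_waveform(gvg: Glottovibrogram, ap_index: int,
                     demean: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Opening time series (mm) at one AP position, at the video frame rate.

    A plain slice of the GVG — never exceeds the column it came from.
    With ``demean`` the column mean is removed (for pitch analysis; yin is
    offset-invariant, so this only matters for power gating).
    """
    if not 0 <= ap_index < gvg.width.shape[1]:
        raise InvalidParameterError(f"ap_index {ap_index} out of range")
    w = gvg.width[:, ap_index].copy()
    if demean:
        w -= w.mean()
    return gvg.times.copy(), w
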