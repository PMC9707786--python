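"""Glottal segmentation from high-speed video.

Two extraction paths with one output contract (per-frame opening widths):

* **Threshold path** — for opaque structures (ventricular folds) the
  glottis is simply darker than the surrounding tissue: all pixels below a
  manually set gray threshold, dilated with a 2-pixel line horizontally
  then vertically, hole-filled, largest component kept.
* **Scan-line edge path** — for translucent vocal membranes whose edges
  cross underlying tissue at nearly the same gray value, thresholding
  under-segments. Instead, 8–10 equidistant horizontal scan lines are
  superimposed and the left/right membrane edge position is located on
  each line per frame, with subpixel refinement. Detections are fixed
  vertically to their line rows; only horizontal motion is measured.

Coordinates: row 0 is anterior; continuous x positions are in pixel units
where pixel ``c`` spans [c, c+1) (its centre is c + 0.5).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, InvalidParameterError


@dataclass
class FrameStack:
    """Grayscale high-speed video with acquisition metadata."""

    pixels: np.ndarray          # (frames, rows, cols)
    fps: float
    pixel_scale: float          # mm per pixel
    rotation_deg: float = 0.0   # rotation already applied
    crop_box: tuple | None = None
    t0: float = 0.0             # time of frame 0 relative to trigger

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise InvalidParameterError("pixels must be (frames, rows, cols)")
        if not self.fps > 0:
            raise InvalidParameterError("fps must be positive")
        if not self.pixel_scale > 0:
            raise InvalidParameterError("pixel_scale must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[1:]

    @property
    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.fps


@dataclass
class GlottalMask:
    """Binary glottis mask for one frame."""

    mask: np.ndarray
    threshold_used: float
    closed: bool = False  # no sub-threshold pixels: glottis fully closed


@dataclass
class EdgeTracks:
    """Per-line, per-frame membrane edge positions (subpixel)."""

    line_rows: np.ndarray               # strictly increasing AP rows
    left_x: np.ndarray                  # (frames, lines), NaN = undefined
    right_x: np.ndarray
    confidence: np.ndarray              # in [0, 1]
    fps: float = 0.0
    t0: float = 0.0

    def __post_init__(self):
        self.line_rows = np.asarray(self.line_rows, dtype=int)
        if np.any(np.diff(self.line_rows) <= 0):
            raise InvalidParameterError("line_rows must be strictly increasing")

    @property
    def width_px(self) -> np.ndarray:
        return self.right_x - self.left_x

    def to_frame(self):
        import pandas as pd

        n_f, n_l = self.left_x.shape
        frames = np.repeat(np.arange(n_f), n_l)
        rows = np.tile(self.line_rows, n_f)
        return pd.DataFrame({
            "frame": frames, "line_row": rows,
            "left_x": self.left_x.ravel(), "right_x": self.right_x.ravel(),
            "confidence": self.confidence.ravel(),
        })


def default_line_rows(n_rows: int, n_lines: int) -> np.ndarray:
    """Equidistant scan-line rows leaving a 1/8-height margin at both ends.

    Shared between the synthetic renderer and the tracker so that, absent
    explicit metadata, both refer to the same anatomy lines.
    """
    if not 8 <= n_lines <= 10:
        raise InvalidParameterError(f"n_lines must be in [8, 10], got {n_lines}")
    margin = n_rows // 8
    rows = np.linspace(margin, n_rows - 1 - margin, n_lines)
    rows = np.round(rows).astype(int)
    if np.any(np.diff(rows) <= 0):
        raise InvalidParameterError(f"frame of {n_rows} rows too small for {n_lines} lines")
    return rows


def preprocess(stack: FrameStack, rotation_deg: float = 0.0,
               crop_box: tuple | None = None) -> FrameStack:
    """Rotate the stack so the glottal midline is vertical, then crop.

    Rotation is bilinear about the frame centre (positive =
    counter-clockwise); crop_box = (row0, row1, col0, col1), half-open.
    """
    pixels = stack.pixels.astype(np.float32)
    if rotation_deg != 0.0:
        pixels = ndimage.rotate(pixels, rotation_deg, axes=(1, 2),
                                reshape=False, order=1, mode="nearest")
    if crop_box is not None:
        r0, r1, c0, c1 = crop_box
        rows, cols = pixels.shape[1:]
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise InvalidParameterError(
                f"crop_box {crop_box} invalid for frame shape {(rows, cols)}"
            )
        pixels = pixels[:, r0:r1, c0:c1]
    return replace(stack, pixels=pixels,
                   rotation_deg=stack.rotation_deg + rotation_deg,
                   crop_box=crop_box)


_H_LINE = np.ones((1, 2), dtype=bool)
_V_LINE = np.ones((2, 1), dtype=bool)


def segment_glottis_threshold(frame: np.ndarray, threshold: float) -> GlottalMask:
    """Threshold segmentation of one frame.

    Pipeline: sub-threshold pixels -> horizontal 2-px dilation -> vertical
    2-px dilation -> hole fill -> largest connected component (ties broken
    toward the darker blob). An empty sub-threshold set is a validly
    closed glottis, not an error.
    """
    frame = np.asarray(frame)
    sub = frame < threshold
    if not sub.any():
        return GlottalMask(sub, threshold, closed=True)
    mask = ndimage.binary_dilation(sub, _H_LINE)
    mask = ndimage.binary_dilation(mask, _V_LINE)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(frame, dtype=float), labels,
                                   index=np.arange(1, n + 1))
        best = np.flatnonzero(sizes == sizes.max()) + 1
        if best.size > 1:
            darkness = ndimage.mean(-frame.astype(float), labels, index=best)
            best = best[[int(np.argmax(darkness))]]
        mask = labels == best[0]
    return GlottalMask(mask, threshold, closed=False)


def segment_stack_threshold(stack: FrameStack, threshold: float) -> np.ndarray:
    """Threshold segmentation of every frame, vectorised across the stack.

    Returns a boolean (frames, rows, cols) array; per-frame semantics are
    identical to :func:`segment_glottis_threshold` (structuring elements
    never span frames).
    """
    sub = stack.pixels < threshold
    mask = ndimage.binary_dilation(sub, _H_LINE[None, :, :])
    mask = ndimage.binary_dilation(mask, _V_LINE[None, :, :])
    mask = ndimage.binary_fill_holes(mask, structure=np.ones((1, 3, 3), bool))
    frame_conn = np.zeros((3, 3, 3), bool)
    frame_conn[1] = True  # 8-connectivity within a frame, none across frames
    labels, n = ndimage.label(mask, structure=frame_conn)
    if n:
        # keep, within each frame, only its largest component
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        frame_of = ndimage.labeled_comprehension(
            np.broadcast_to(np.arange(stack.n_frames)[:, None, None], labels.shape),
            labels, np.arange(1, n + 1), np.min, int, -1)
        keep = np.zeros(n + 1, dtype=bool)
        for f in range(stack.n_frames):
            lbls = np.flatnonzero(frame_of == f) + 1
            if lbls.size:
                keep[lbls[np.argmax(counts[lbls])]] = True
        mask = keep[labels]
    return mask


def suggest_threshold(frame: np.ndarray) -> float:
    """Otsu threshold as a starting suggestion; never applied silently —
    the operative threshold always comes from trial metadata."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(frame)))


def glottal_width_profile(mask: np.ndarray, pixel_scale: float,
                          margin_px: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Opening width per AP row from a binary mask.

    Width is the count of mask pixels along each row (the opening
    direction), optionally reduced by a dilation ``margin_px`` measured on
    calibration fixtures (see :func:`measure_dilation_margin`), and scaled
    to mm. Returns ``(width_px, width_mm)`` indexed anterior -> posterior.
    """
    mask = np.asarray(mask, dtype=bool)
    width_px = mask.sum(axis=-1).astype(float)
    corrected = np.where(width_px > 0, np.maximum(width_px - margin_px, 0.0), 0.0)
    return corrected, corrected * pixel_scale


def horizontal_extent_profile(mask: np.ndarray) -> np.ndarray:
    """Alternative width reading: rightmost minus leftmost mask column per
    row (extent rather than pixel count). Zero on empty rows."""
    mask = np.asarray(mask, dtype=bool)
    rows = mask.shape[0]
    out = np.zeros(rows)
    cols = np.arange(mask.shape[1])
    for r in range(rows):
        on = cols[mask[r]]
        if on.size:
            out[r] = on[-1] - on[0] + 1
    return out


def measure_dilation_margin(width_px: int = 20, rows: int = 32, cols: int = 64) -> float:
    """Width bias (px) the dilate-and-fill pipeline adds to a known
    rectangular opening, measured on a noiseless calibration frame."""
    frame = np.full((rows, cols), 200, dtype=np.uint8)
    c0 = (cols - width_px) // 2
    frame[4:-4, c0:c0 + width_px] = 30
    res = segment_glottis_threshold(frame, 100)
    measured, _ = glottal_width_profile(res.mask, 1.0)
    mid = measured[rows // 2]
    return float(mid - width_px)


# ---------------------------------------------------------------------------
# scan-line edge tracking


def track_edges_scanlines(stack: FrameStack, n_lines: int = 10,
                          line_rows: np.ndarray | None = None,
                          band_rows: int = 3, smooth_sigma: float = 1.5,
                          max_search_px: int = 12, split_t_min: float = 2.0,
                          gate_px: float = 6.0, gate_frames: int = 3) -> EdgeTracks:
    """Track left/right glottal edges on equidistant horizontal scan lines.

    Built for translucent membranes whose gray step against the
    surrounding fold is at noise level, where gradient peaks are useless:
    per line and frame the row band (+/- ``band_rows``) is averaged, the
    dark glottal core located from a smoothed copy by its strong
    contrast, and the true edge found by change-point localization — the
    split of the raw profile over the ``max_search_px`` columns outside
    the core that best separates a brighter fold plateau from the
    membrane plateau (Welch-style statistic against a per-line robust
    noise estimate). Plateau-mean splitting localizes a step of height
    comparable to the pixel noise to well under a pixel, which a gradient
    extremum cannot. If no significant split exists (statistic below
    ``split_t_min``, e.g. opaque tissue where the core edge *is* the
    edge), the subpixel crossing of the core mid-level is returned
    instead. Confidence reflects the split statistic (or is capped at
    0.45 for mid-level fallbacks); detections are fixed vertically to
    their line rows.

    When no dark core is visible at all, the previous frame's positions
    are held for up to ``gate_frames`` frames at low confidence, after
    which the detection is undefined (NaN).
    """
    if line_rows is None:
        line_rows = default_line_rows(stack.shape[0], n_lines)
    else:
        line_rows = np.asarray(line_rows, dtype=int)
        if not 8 <= line_rows.size <= 10:
            raise InvalidParameterError("need 8-10 scan lines")
    pixels = stack.pixels.astype(np.float32)
    n_frames, n_rows, n_cols = pixels.shape
    n_l = line_rows.size

    left = np.full((n_frames, n_l), np.nan)
    right = np.full((n_frames, n_l), np.nan)
    conf = np.zeros((n_frames, n_l))

    for li, r in enumerate(line_rows):
        # outermost lines average toward the interior only: beyond the
        # line span the opening tapers shut, which would bias the band
        r0 = r if li == 0 else max(0, r - band_rows)
        r1 = r + 1 if li == n_l - 1 else min(n_rows, r + band_rows + 1)
        prof = pixels[:, r0:r1, :].mean(axis=1)
        sm = ndimage.gaussian_filter1d(prof, smooth_sigma, axis=1, mode="nearest")

        lo = sm.min()
        hi = np.median(sm[:, [0, 1, -2, -1]])
        cut = 0.5 * (lo + hi)

        # per-column noise of the band profile, from the static flanks
        flank = np.concatenate([prof[:, :4], prof[:, -4:]], axis=1)
        resid = flank - flank.mean(axis=0, keepdims=True)
        sigma = 1.4826 * float(np.median(np.abs(resid)))

        below = sm < cut
        has_core = below.any(axis=1)
        il = np.argmax(below, axis=1)
        ir = n_cols - 1 - np.argmax(below[:, ::-1], axis=1)

        xl, cl, tl = _split_edges(prof, sm, il, cut, sigma, max_search_px,
                                  split_t_min, side=-1)
        xr, cr, tr = _split_edges(prof, sm, ir, cut, sigma, max_search_px,
                                  split_t_min, side=+1)

        # a membrane band is a persistent feature of the anatomy, not of
        # single frames: if the line shows no consistent split, individual
        # supra-threshold splits are noise and the core edge is the edge
        if np.median(tl) < split_t_min:
            xl, cl, _ = _split_edges(prof, sm, il, cut, sigma, max_search_px,
                                     np.inf, side=-1)
        if np.median(tr) < split_t_min:
            xr, cr, _ = _split_edges(prof, sm, ir, cut, sigma, max_search_px,
                                     np.inf, side=+1)

        # second pass where a membrane band is consistently present: learn
        # the fold and membrane levels from the whole line's history, then
        # relocate each boundary by maximum likelihood with known levels —
        # far tighter than per-frame plateau splits when the gray step is
        # at noise level.
        if (np.median(tl) >= split_t_min and np.median(tr) >= split_t_min
                and has_core.any()):
            a_level = float(flank.mean())
            b_level = _membrane_level(prof, xl, il, xr, ir, has_core)
            if b_level is not None and a_level - b_level > 0.5 * sigma:
                xl = _ml_edges(prof, il, a_level, b_level, max_search_px,
                               side=-1, x_init=xl)
                xr = _ml_edges(prof, ir, a_level, b_level, max_search_px,
                               side=+1, x_init=xr)

        held = 0
        prev_l = prev_r = np.nan
        for f in range(n_frames):
            if not has_core[f]:
                if not np.isnan(prev_l) and held < gate_frames:
                    left[f, li], right[f, li] = prev_l, prev_r
                    conf[f, li] = 0.05
                    held += 1
                continue
            held = 0
            x0, c0, x1, c1 = xl[f], cl[f], xr[f], cr[f]
            # continuity gate against single-frame flyers
            if not np.isnan(prev_l) and abs(x0 - prev_l) > gate_px and c0 < 1.0:
                x0, c0 = prev_l, 0.2
            if not np.isnan(prev_r) and abs(x1 - prev_r) > gate_px and c1 < 1.0:
                x1, c1 = prev_r, 0.2
            if x0 > x1:  # never report crossed edges
                x0 = x1 = 0.5 * (x0 + x1)
            left[f, li], right[f, li] = x0, x1
            conf[f, li] = float(np.clip(0.5 * (c0 + c1), 0.0, 1.0))
            prev_l, prev_r = x0, x1

    return EdgeTracks(line_rows, left, right, conf, fps=stack.fps, t0=stack.t0)


def _split_edges(prof: np.ndarray, sm: np.ndarray, inner: np.ndarray,
                 cut: float, sigma: float, search: int, t_min: float,
                 side: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised change-point edge localization for one side, all frames.

    For the left edge (side -1) the window is the ``search + 1`` columns
    ending two columns outside the inner core edge; each candidate split
    divides it into an outer (fold) and inner (membrane) plateau and is
    scored by the plateau mean difference over its standard error. The
    returned position is the plateau boundary in continuous pixel
    coordinates. Frames without a significant split fall back to the
    subpixel crossing of the core mid-level ``cut``.
    """
    n_frames, n_cols = prof.shape
    m = search + 1
    if side < 0:
        start = inner - 2 - search
    else:
        start = inner + 2
    start = np.clip(start, 0, n_cols - m)
    idx = start[:, None] + np.arange(m)[None, :]
    win = np.take_along_axis(prof, idx, axis=1)
    if side > 0:
        win = win[:, ::-1]  # orient: outer (fold) first

    csum = np.cumsum(win, axis=1)
    total = csum[:, -1:]
    k = np.arange(1, m)[None, :]
    mean_out = csum[:, :-1] / k
    mean_in = (total - csum[:, :-1]) / (m - k)
    se = sigma * np.sqrt(1.0 / k + 1.0 / (m - k)) + 1e-12
    t = (mean_out - mean_in) / se          # fold brighter than membrane
    k_best = np.argmax(t, axis=1) + 1
    t_best = np.take_along_axis(t, (k_best - 1)[:, None], axis=1)[:, 0]

    if side < 0:
        x_split = start + k_best.astype(float)
    else:
        x_split = start + (m - k_best).astype(float)

    # fallback: subpixel crossing of the mid-level at the core edge
    i0 = np.clip(inner - (1 if side < 0 else 0), 0, n_cols - 2)
    a = np.take_along_axis(sm, i0[:, None], axis=1)[:, 0]
    b = np.take_along_axis(sm, (i0 + 1)[:, None], axis=1)[:, 0]
    frac = np.clip((a - cut) / np.where(np.abs(a - b) < 1e-9, np.inf, a - b),
                   0.0, 1.0)
    x_cross = i0 + frac + 0.5

    use_split = t_best >= t_min
    x = np.where(use_split, x_split, x_cross)
    confidence = np.where(use_split, np.clip(t_best / 6.0, 0.0, 1.0), 0.45)
    return x, confidence, t_best


def _membrane_level(prof: np.ndarray, xl: np.ndarray, il: np.ndarray,
                    xr: np.ndarray, ir: np.ndarray,
                    has_core: np.ndarray) -> float | None:
    """Pooled mean gray of the membrane band interior over all frames,
    i.e. columns strictly between the pass-1 edge and the dark core."""
    n_frames, n_cols = prof.shape
    cols = np.arange(n_cols)[None, :]
    left_band = (cols >= np.ceil(xl)[:, None] + 1) & (cols <= il[:, None] - 3)
    right_band = (cols >= ir[:, None] + 3) & (cols <= np.floor(xr)[:, None] - 1)
    band = (left_band | right_band) & has_core[:, None]
    if band.sum() < 50:
        return None
    return float(prof[band].mean())


def _ml_edges(prof: np.ndarray, inner: np.ndarray, a: float, b: float,
              search: int, side: int, x_init: np.ndarray,
              max_shift: float = 3.0) -> np.ndarray:
    """Boundary relocation with known plateau levels.

    Within the same search window as pass 1, choose the split k that
    minimises sum((v - a)^2) over the outer part plus sum((v - b)^2) over
    the inner part. Falls back to the pass-1 position when the ML answer
    moves more than ``max_shift`` pixels away from it.
    """
    n_frames, n_cols = prof.shape
    m = search + 1
    if side < 0:
        start = inner - 2 - search
    else:
        start = inner + 2
    start = np.clip(start, 0, n_cols - m)
    idx = start[:, None] + np.arange(m)[None, :]
    win = np.take_along_axis(prof, idx, axis=1)
    if side > 0:
        win = win[:, ::-1]

    ca = np.concatenate([np.zeros((n_frames, 1)),
                         np.cumsum((win - a) ** 2, axis=1)], axis=1)
    cb = np.concatenate([np.zeros((n_frames, 1)),
                         np.cumsum((win - b) ** 2, axis=1)], axis=1)
    # cost of boundary at k: outer cols [0,k) match a, inner [k,m) match b
    cost = ca[:, :m + 1] + (cb[:, -1:] - cb[:, :m + 1])
    k_ml = np.argmin(cost, axis=1).astype(float)
    if side < 0:
        x = start + k_ml
    else:
        x = start + (m - k_ml)
    return np.where(np.abs(x - x_init) <= max_shift, x, x_init)


def read_edge_tracks_csv(path, fps: float = 0.0, t0: float = 0.0) -> EdgeTracks:
    """Adapter for externally produced per-line edge coordinates (e.g. a
    pose-estimation network) in the package CSV layout
    (frame, line_row, left_x, right_x, confidence)."""
    import pandas as pd

    df = pd.read_csv(path)
    rows = np.sort(df["line_row"].unique())
    n_f = int(df["frame"].max()) + 1
    left = np.full((n_f, rows.size), np.nan)
    right = np.full((n_f, rows.size), np.nan)
    confv = np.zeros((n_f, rows.size))
    row_ix = {r: i for i, r in enumerate(rows)}
    for _, rec in df.iterrows():
        i, j = int(rec["frame"]), row_ix[rec["line_row"]]
        left[i, j], right[i, j] = rec["left_x"], rec["right_x"]
        confv[i, j] = rec.get("confidence", 1.0)
    return EdgeTracks(rows, left, right, confv, fps=fps, t0=t0)
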