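"""Figure helpers: GVG heatmap, identity scatter, f_o range boxplots."""
from __future__ import annotations

import numpy as np

from .analysis import RangeSummary, RegressionResult
from .fo import FoTrack
from .gvg import Glottovibrogram


def plot_gvg(gvg: Glottovibrogram, ax=None, fo_track: FoTrack | None = None,
             cmap: str = "magma"):
    """Heatmap of opening width over time and AP position, optionally with
    an f_o track overlaid on a twin axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [gvg.times[0], gvg.times[-1], gvg.ap_positions[-1], gvg.ap_positions[0]]
    im = ax.imshow(gvg.width.T, aspect="auto", extent=extent, cmap=cmap)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("AP position (mm)")
    ax.figure.colorbar(im, ax=ax, label="opening width (mm)")
    if fo_track is not None:
        ax2 = ax.twinx()
        v = fo_track.valid
        ax2.plot(fo_track.times[v], fo_track.f0[v] / 1000, "c.", ms=3)
        ax2.set_ylabel("f_o (kHz)")
    return ax


def plot_identity(f0_vibration: FoTrack, f0_sound: FoTrack,
                  regression: RegressionResult | None = None, ax=None):
    """Sound f_o against vibration f_o with the dotted identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n = min(f0_vibration.times.size, f0_sound.times.size)
    both = f0_vibration.valid[:n] & f0_sound.valid[:n]
    x = f0_vibration.f0[:n][both] / 1000
    y = f0_sound.f0[:n][both] / 1000
    ax.plot(x, y, "o", ms=4, alpha=0.6)
    lim = [0, max(1e-9, 1.1 * max(x.max(initial=0), y.max(initial=0)))]
    ax.plot(lim, lim, ":", color="gray", label="identity")
    if regression is not None:
        xs = np.array(lim)
        ax.plot(xs, regression.slope * xs + regression.intercept / 1000, "-",
                label=f"slope {regression.slope:.3f}, r$^2$ {regression.r_squared:.3f}")
    ax.set_xlabel("vibration f_o (kHz)")
    ax.set_ylabel("sound f_o (kHz)")
    ax.legend()
    return ax


def plot_fo_ranges(summaries: dict[str, RangeSummary], ax=None):
    """Range boxplots (whiskers = min/max, no outlier trimming)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    stats = [{
        "label": name, "whislo": s.minimum / 1000, "q1": s.q1 / 1000,
        "med": s.median / 1000, "q3": s.q3 / 1000, "whishi": s.maximum / 1000,
        "fliers": [],
    } for name, s in summaries.items()]
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel("f_o (kHz)")
    return ax
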