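"""End-to-end analysis driver.

``run_pipeline`` takes one trial (on disk or in memory) through
segmentation → glottovibrogram → vibration f_o → sound f_o (engine
auto-selected) → identity regression → phonation-threshold pressure, and
records every numeric parameter that influenced any result in a
provenance log.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import analysis, fo, gvg, onset as onset_mod, segmentation as seg
from .errors import StageError
from .signals import PressureTrace, SoundTrace
from .trial_io import TrialBundle


@dataclass
class PipelineConfig:
    """Every tunable that affects pipeline results, with defaults.

    Frequency gates are per structure: ventricular folds vibrate at a few
    kHz (threshold segmentation), vocal membranes at tens of kHz (edge
    tracking). Power floors are calibrated against the synthetic noise
    floor, not a claim about any particular instrument.
    """

    # segmentation
    dilation_margin_px: float = 1.0     # measured on calibration fixtures
    edge_band_rows: int = 3
    edge_smooth_sigma: float = 1.5
    edge_max_search_px: int = 12
    edge_split_t_min: float = 2.0
    edge_gate_px: float = 6.0
    edge_gate_frames: int = 3
    # f0 estimation
    yin_hop_frames: int = 10
    yin_ap_threshold: float = 0.1
    yin_window_periods: float = 4.0     # of the lowest expected f0; the
                                        # 2-period minimum leaves window-edge
                                        # bias on harmonic-rich signals
    vib_f0_min_ventricular: float = 800.0
    vib_f0_min_membrane: float = 9000.0  # just below the 10-20 kHz band;
                                         # keeps half-f0 lags out of range
    f0_range_ventricular: tuple = (1000.0, 5000.0)
    f0_range_membrane: tuple = (10_000.0, 20_000.0)
    vib_power_floor: float = 1e-6       # mm^2, opening-waveform AC power
    sound_power_floor: float = 1e-9     # Pa^2
    ridge_nfft: int = 2048
    ridge_overlap: float = 0.5
    ridge_penalty_per_bin: float = 1.0
    # onset
    onset_threshold_pa: float = 2e-4
    onset_power_window_s: float = 1e-3
    onset_hold_s: float = 2e-3
    pressure_cutoff_hz: float = 500.0


@dataclass
class PipelineResult:
    trial_id: str
    mode: str
    gvg: gvg.Glottovibrogram | None
    ap_index: int | None
    f0_vibration: fo.FoTrack | None
    f0_sound: fo.FoTrack | None
    regression: analysis.RegressionResult | None
    onset: onset_mod.OnsetResult
    sound_summary: analysis.RangeSummary | None
    vibration_summary: analysis.RangeSummary | None
    provenance: dict

    def report_row(self) -> dict:
        row = {"trial_id": self.trial_id, "mode": self.mode,
               "detected": self.onset.detected,
               "ptp_kPa": self.onset.ptp, "s_ptp_kPa_s": self.onset.s_ptp,
               "onset_s": self.onset.onset_time}
        if self.regression is not None:
            row.update({"slope": self.regression.slope,
                        "intercept_hz": self.regression.intercept,
                        "r_squared": self.regression.r_squared,
                        "n_hops": self.regression.n})
        if self.f0_vibration is not None and self.f0_vibration.n_valid:
            row["median_f0_vib_hz"] = float(
                np.median(self.f0_vibration.f0[self.f0_vibration.valid]))
        if self.f0_sound is not None and self.f0_sound.n_valid:
            row["median_f0_sound_hz"] = float(
                np.median(self.f0_sound.f0[self.f0_sound.valid]))
        return row


def run_pipeline(bundle, mode: str | None = None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Full analysis of one trial.

    ``bundle`` is a :class:`~glottovib.trial_io.TrialBundle` or a
    :class:`~glottovib.synth.SyntheticTrial`; ``mode`` is ``ventricular``
    (threshold segmentation) or ``membrane`` (scan-line edge tracking) and
    defaults to the bundle metadata. Stage failures are re-raised as
    :class:`StageError` carrying the stage name and trial id.
    """
    config = config or PipelineConfig()
    trial_id, load_stack, sound, pressure, threshold, mode = _unpack(bundle, mode)
    prov = {"trial_id": trial_id, "mode": mode, "config": asdict(config),
            "stages": {}}

    the_gvg = ap_index = f0_vib = f0_snd = regression = None
    vib_summary = snd_summary = None

    if load_stack is not None:
        f0_min = (config.vib_f0_min_ventricular if mode == "ventricular"
                  else config.vib_f0_min_membrane)
        try:
            stack = load_stack()
            if mode == "ventricular":
                masks = seg.segment_stack_threshold(stack, threshold)
                widths_px = masks.sum(axis=2).astype(float)
                corrected = np.where(widths_px > 0,
                                     np.maximum(widths_px - config.dilation_margin_px, 0),
                                     0.0)
                widths_mm = corrected * stack.pixel_scale
                prov["stages"]["segmentation"] = {
                    "method": "threshold", "threshold": threshold,
                    "dilation_margin_px": config.dilation_margin_px}
                the_gvg = gvg.build_gvg(widths_mm, fps=stack.fps,
                                        pixel_scale=stack.pixel_scale, t0=stack.t0)
            else:
                tracks = seg.track_edges_scanlines(
                    stack, band_rows=config.edge_band_rows,
                    smooth_sigma=config.edge_smooth_sigma,
                    max_search_px=config.edge_max_search_px,
                    split_t_min=config.edge_split_t_min,
                    gate_px=config.edge_gate_px,
                    gate_frames=config.edge_gate_frames)
                prov["stages"]["segmentation"] = {
                    "method": "edges", "n_lines": int(tracks.line_rows.size)}
                the_gvg = gvg.build_gvg(tracks, fps=stack.fps,
                                        pixel_scale=stack.pixel_scale, t0=stack.t0)
        except Exception as e:
            raise StageError("segmentation", trial_id, e) from e

        try:
            ap_index = gvg.max_opening_position(the_gvg)
            _, wave = gvg.opening_waveform(the_gvg, ap_index, demean=True)
            window = int(np.ceil(config.yin_window_periods * stack.fps / f0_min))
            f0_vib = fo.yin_f0(wave, stack.fps, window=window,
                               f0_min=f0_min, hop=config.yin_hop_frames,
                               ap_threshold=config.yin_ap_threshold,
                               power_floor=config.vib_power_floor, t0=stack.t0)
            prov["stages"]["vibration_f0"] = {
                "engine": "yin", "window": window, "hop": config.yin_hop_frames,
                "ap_index": int(ap_index), "f0_min": f0_min}
        except Exception as e:
            raise StageError("vibration_f0", trial_id, e) from e

        try:
            f0_range = (config.f0_range_ventricular if mode == "ventricular"
                        else config.f0_range_membrane)
            engine = fo.select_engine(f0_range, stack.fps)
            video_span = (stack.t0, stack.t0 + stack.n_frames / stack.fps)
            snd_slice = sound.slice_time(*video_span)
            if engine == "yin":
                snd_fps = analysis.resample_to_framerate(
                    snd_slice.samples, snd_slice.fs, stack.fps)
                window = int(np.ceil(config.yin_window_periods * stack.fps / f0_min))
                f0_snd = fo.yin_f0(snd_fps, stack.fps, window=window,
                                   f0_min=f0_min, hop=config.yin_hop_frames,
                                   ap_threshold=config.yin_ap_threshold,
                                   power_floor=config.sound_power_floor,
                                   t0=snd_slice.t0)
            else:
                f0_snd = fo.ridge_f0(snd_slice.samples, snd_slice.fs,
                                     nfft=config.ridge_nfft,
                                     overlap=config.ridge_overlap,
                                     penalty_per_bin=config.ridge_penalty_per_bin,
                                     power_floor=config.sound_power_floor,
                                     t0=snd_slice.t0)
            prov["stages"]["sound_f0"] = {
                "engine": engine, "expected_range_hz": list(f0_range),
                "resampled_to_fps": engine == "yin"}
        except Exception as e:
            raise StageError("sound_f0", trial_id, e) from e

        try:
            if f0_snd.engine == "yin":
                regression = analysis.identity_regression(f0_vib, f0_snd)
            if f0_vib.n_valid:
                vib_summary = analysis.fo_range_summary(f0_vib.f0[f0_vib.valid])
            if f0_snd.n_valid:
                snd_summary = analysis.fo_range_summary(f0_snd.f0[f0_snd.valid])
        except Exception as e:
            raise StageError("regression", trial_id, e) from e

    try:
        result_onset = onset_mod.compute_ptp(
            pressure, sound, threshold=config.onset_threshold_pa,
            power_window=config.onset_power_window_s,
            hold_time=config.onset_hold_s, cutoff_hz=config.pressure_cutoff_hz)
        prov["stages"]["onset"] = result_onset.to_dict()
    except Exception as e:
        raise StageError("onset", trial_id, e) from e

    return PipelineResult(trial_id=trial_id, mode=mode, gvg=the_gvg,
                          ap_index=ap_index, f0_vibration=f0_vib,
                          f0_sound=f0_snd, regression=regression,
                          onset=result_onset, sound_summary=snd_summary,
                          vibration_summary=vib_summary, provenance=prov)


def _unpack(bundle, mode):
    """Resolve a bundle into (trial_id, frame loader, sound, pressure,
    threshold, mode). Frame loading is deferred into the segmentation
    stage so that a corrupted video file fails there, by name."""
    from .synth import SyntheticTrial

    if isinstance(bundle, TrialBundle):
        def load_stack(b=bundle):
            stack = b.load_frames()
            if b.metadata.get("rotation_deg"):
                stack = seg.preprocess(stack, b.metadata["rotation_deg"])
            return stack

        has_video = bundle.has_video
        sound = bundle.load_sound()
        pressure = bundle.load_pressure()
        threshold = bundle.metadata["gray_threshold"]
        mode = mode or bundle.metadata.get("mode")
        trial_id = bundle.trial_id
    elif isinstance(bundle, SyntheticTrial):
        def load_stack(b=bundle):
            stack = b.frames
            if b.recipe.pre_rotate_deg:
                stack = seg.preprocess(stack, -b.recipe.pre_rotate_deg)
            return stack

        has_video = bundle.frames is not None
        sound, pressure = bundle.sound, bundle.pressure
        threshold = bundle.recipe.gray_threshold
        mode = mode or {"opaque": "ventricular", "translucent": "membrane",
                        "none": "none"}[bundle.recipe.mode]
        trial_id = bundle.recipe.name
    else:
        raise TypeError(f"cannot analyse {type(bundle).__name__}")
    if mode not in ("ventricular", "membrane", "none"):
        raise StageError("load", trial_id, ValueError(f"unknown mode '{mode}'"))
    if mode == "none" or not has_video:
        load_stack = None
    return trial_id, load_stack, sound, pressure, threshold, mode
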