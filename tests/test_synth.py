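"""Tests of the synthetic-trial generator: pressure protocols, gated
kinematics, rendering and the acoustic/kinematic frequency lock."""
import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from glottovib.errors import InvalidParameterError
from glottovib.segmentation import glottal_width_profile, segment_glottis_threshold
from glottovib.signals import running_rms
from glottovib.synth import (RECIPES, KinematicProfile, constant_f0,
                             generate_pressure, linear_sweep, make_trial,
                             render_frames, simulate_kinematics,
                             synthesize_sound)


class TestGeneratePressure:
    def test_slow_ramp_length_and_endpoint(self):
        p = generate_pressure("slow_ramp", fs=250_000)
        assert p.n == 1_500_001
        assert p.samples[0] == 0.0
        assert p.samples[-1] == pytest.approx(6.0)

    def test_slow_ramp_midramp_derivative_is_rate(self):
        p = generate_pressure("slow_ramp", fs=250_000)
        speed = np.diff(p.samples) * p.fs
        mid = speed[100:-100]
        assert np.allclose(mid, 1.0, atol=1e-6)

    def test_fast_pulses_four_disjoint_intervals(self):
        # evaluated analytically per trapezoid segment: 4 pulses reach the
        # 4 kPa peak and are separated by floor-level gaps
        p = generate_pressure("fast_pulses", fs=250_000)
        assert p.samples.max() == pytest.approx(4.0)
        above = p.samples > 2.0
        n_runs = int(np.sum(np.diff(above.astype(int)) == 1))
        assert n_runs == 4

    def test_pulse_rise_rate_is_configured(self):
        p = generate_pressure("fast_pulses", fs=250_000, rise_time=0.030)
        speed = np.diff(p.samples) * p.fs
        assert speed.max() == pytest.approx(4.0 / 0.030, rel=1e-6)

    @pytest.mark.parametrize("kwargs", [
        {"protocol": "slow_ramp", "fs": 0},
        {"protocol": "slow_ramp", "fs": 250_000, "rate": -1.0},
        {"protocol": "fast_pulses", "fs": 250_000, "width": 0.0},
        {"protocol": "fast_pulses", "fs": 250_000, "rise_time": 0.2},
        {"protocol": "sawtooth", "fs": 250_000},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            generate_pressure(**kwargs)

    def test_noise_is_out_of_band(self):
        # sensor noise must not corrupt the low-pass-filtered derivative
        from glottovib.onset import lowpass_pressure, pressure_speed

        p = generate_pressure("slow_ramp", fs=250_000, seed=7, noise_sd=0.05)
        _, speed = pressure_speed(lowpass_pressure(p))
        mid = speed[200_000:-200_000]
        assert np.abs(mid - 1.0).max() < 0.05


class TestSimulateKinematics:
    def test_onset_at_threshold_and_period(self):
        pressure = generate_pressure("slow_ramp", fs=250_000, hold_s=0.3)
        profile = KinematicProfile(duration=0.01, fps=20_000,
                                   f0_of_t=constant_f0(2000.0))
        kin = simulate_kinematics(profile, pressure, ptp_true=4.0)
        assert kin.onset_time == pytest.approx(4.0, abs=1e-3)
        assert kin.onset_pressure == pytest.approx(4.0, abs=0.01)
        # opening waveform period = fps / f0 = 10 frames
        half = kin.half_width()[:, 5]
        d = np.sign(half - half.mean())
        crossings = np.flatnonzero(np.diff(d) > 0)
        assert np.allclose(np.diff(crossings), 10, atol=1)

    def test_unsatisfiable_rate_gate_never_starts(self):
        pressure = generate_pressure("slow_ramp", fs=250_000)
        profile = KinematicProfile(duration=0.01, fps=20_000,
                                   f0_of_t=constant_f0(2000.0))
        kin = simulate_kinematics(profile, pressure, ptp_true=4.0,
                                  rate_gate=50.0)
        assert kin.onset_time is None
        assert np.allclose(kin.half_width(), profile.slit_half_px)

    def test_sweep_instantaneous_period_tracks_f0(self):
        fs = 250_000
        pressure = generate_pressure("slow_ramp", fs=fs, start=5.0, end=5.0,
                                     hold_s=0.2)
        f0 = linear_sweep(10_000.0, 20_000.0, 0.0, 0.2)
        profile = KinematicProfile(duration=0.1, fps=125_000, f0_of_t=f0)
        kin = simulate_kinematics(profile, pressure, ptp_true=4.0,
                                  video_t0=0.0)
        half = kin.half_width()[:, 5] - np.mean(kin.half_width()[:, 5])
        up = np.flatnonzero((half[:-1] < 0) & (half[1:] >= 0))
        periods = np.diff(up)                      # frames per cycle
        t_mid = kin.frame_times[up[:-1]]
        expected = profile.fps / f0(t_mid)
        assert np.all(np.abs(periods - expected) <= 1.0)


class TestRenderFrames:
    @staticmethod
    def _static_kinematics(half_px, fps=20_000, n_frames=10):
        pressure = generate_pressure("slow_ramp", fs=250_000, start=5.0,
                                     end=5.0, hold_s=0.05)
        profile = KinematicProfile(duration=n_frames / fps, fps=fps,
                                   f0_of_t=constant_f0(2000.0),
                                   amplitude_px=0.0, slit_half_px=half_px)
        return simulate_kinematics(profile, pressure, ptp_true=4.0,
                                   video_t0=0.0)

    def test_opaque_noiseless_width_exact(self):
        kin = self._static_kinematics(half_px=10.0)
        stack, line_rows = render_frames(kin, mode="opaque", noise_sd=0.0)
        mask = segment_glottis_threshold(stack.pixels[0], 100)
        width, _ = glottal_width_profile(mask.mask, 1.0, margin_px=1.0)
        assert np.all(width[line_rows] == 20.0)

    def test_translucent_threshold_underreports(self):
        kin = self._static_kinematics(half_px=10.0)
        stack, line_rows = render_frames(
            kin, mode="translucent", noise_sd=0.0, membrane_px=6.0,
            grays={"membrane": 160.0})        # membrane == fold exactly
        mask = segment_glottis_threshold(stack.pixels[0], 100)
        width, _ = glottal_width_profile(mask.mask, 1.0, margin_px=1.0)
        assert np.all(width[line_rows] < 20.0)

    def test_noisy_opaque_width_within_1px_99pct(self):
        # Monte-Carlo over >1,000 interior rows at 8-bit levels 40/160,
        # noise sd 5: thresholding stays pixel-accurate
        kin = self._static_kinematics(half_px=10.0, n_frames=15)
        stack, line_rows = render_frames(kin, mode="opaque", noise_sd=5.0,
                                         seed=99)
        r0, r1 = line_rows[0], line_rows[-1]
        errs = []
        for frame in stack.pixels:
            mask = segment_glottis_threshold(frame, 100)
            width, _ = glottal_width_profile(mask.mask, 1.0, margin_px=1.0)
            errs.append(np.abs(width[r0:r1 + 1] - 20.0))
        errs = np.concatenate(errs)
        assert errs.size > 1000
        assert np.mean(errs <= 1.0) >= 0.99

    def test_refuses_undersampled_video(self):
        pressure = generate_pressure("slow_ramp", fs=250_000, start=5.0,
                                     end=5.0, hold_s=0.05)
        profile = KinematicProfile(duration=0.001, fps=20_000,
                                   f0_of_t=constant_f0(8000.0))
        kin = simulate_kinematics(profile, pressure, ptp_true=4.0,
                                  video_t0=0.0)
        with pytest.raises(InvalidParameterError, match="undersample"):
            render_frames(kin, mode="opaque")

    def test_translucent_requires_membrane_near_fold(self):
        kin = self._static_kinematics(half_px=10.0)
        with pytest.raises(InvalidParameterError):
            render_frames(kin, mode="translucent", noise_sd=2.0,
                          grays={"membrane": 120.0})


class TestSynthesizeSound:
    def test_pure_tone_f0(self):
        from glottovib.fo import yin_f0

        snd = synthesize_sound(constant_f0(10_000.0), onset_time=0.0,
                               duration=0.1, fs=250_000, n_harmonics=1,
                               noise_sd=0.0, attack_s=0.001)
        tr = yin_f0(snd.samples[5000:], snd.fs, window=100, f0_min=5000.0,
                    hop=997)
        assert np.all(np.abs(tr.f0[tr.valid] - 10_000.0) < 1.0)

    def test_attack_envelope_crossing_by_linearity(self):
        # amplitude ramps 0 -> 2 mPa over 100 ms: the envelope passes the
        # 0.2 mPa onset criterion at exactly 10 % of the ramp
        snd = synthesize_sound(constant_f0(2000.0), onset_time=0.0,
                               duration=0.2, fs=250_000, amp_pa=2e-3,
                               attack_s=0.1, n_harmonics=1, noise_sd=0.0)
        t_cross = 0.01
        i = int(t_cross * snd.fs)
        # look back one tone period so envelope growth cannot bias upward
        peak = np.abs(snd.samples[i - 250:i + 1]).max()
        assert peak == pytest.approx(2e-4, rel=0.05)

    def test_silent_before_onset(self):
        snd = synthesize_sound(constant_f0(2000.0), onset_time=0.05,
                               duration=0.1, fs=250_000, noise_sd=0.0)
        assert np.all(snd.samples[:int(0.049 * snd.fs)] == 0.0)

    def test_acoustic_kinematic_lock(self, ventricular_trial):
        # zero-crossing counts of sound fundamental and opening waveform
        # agree to one cycle over any 10 ms during phonation
        tr = ventricular_trial
        kin = tr.kinematics
        t0, t1 = kin.frame_times[0], kin.frame_times[0] + 0.01
        half = kin.half_width()[:, 5]
        sel = (kin.frame_times >= t0) & (kin.frame_times < t1)
        k_cross = np.sum(np.diff(np.sign(half[sel] - half[sel].mean())) > 0)
        snd = tr.sound.slice_time(t0, t1)
        x = snd.samples - snd.samples.mean()
        s_cross = np.sum(np.diff(np.sign(x)) > 0)
        assert abs(int(k_cross) - int(s_cross)) <= 1


class TestMakeTrial:
    def test_same_seed_byte_identical(self, tmp_path):
        rec = replace(RECIPES["ventricular-slow-ramp"], video_duration=0.005,
                      protocol_params={"start": 3.5, "end": 6.0, "rate": 1.0,
                                       "hold_s": 0.1})
        def digest(d):
            return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(Path(d).iterdir())}
        make_trial(rec, seed=5, out_dir=tmp_path / "a")
        make_trial(rec, seed=5, out_dir=tmp_path / "b")
        make_trial(rec, seed=6, out_dir=tmp_path / "c")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")
        assert digest(tmp_path / "a") != digest(tmp_path / "c")

    def test_rate_gated_recipe_has_no_onset(self):
        tr = make_trial("membrane-slow-gated", seed=17)
        assert tr.truth["onset_time_s"] is None
        assert np.abs(tr.sound.samples).max() < 2e-4

    def test_truth_edges_inside_frame(self, membrane_trial):
        cols = membrane_trial.recipe.frame_shape[1]
        assert np.nanmin(membrane_trial.kinematics.left_x) >= 0
        assert np.nanmax(membrane_trial.kinematics.right_x) <= cols

    def test_unknown_recipe_rejected(self):
        with pytest.raises(InvalidParameterError, match="unknown recipe"):
            make_trial("no-such-recipe", seed=1)
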