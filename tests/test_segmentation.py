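"""Segmentation tests: threshold path, scan-line edge path, and the
equivalence of the two on opaque material."""
import numpy as np
import pytest

from glottovib.errors import InvalidParameterError
from glottovib.segmentation import (EdgeTracks, FrameStack,
                                    glottal_width_profile,
                                    horizontal_extent_profile,
                                    measure_dilation_margin, preprocess,
                                    read_edge_tracks_csv,
                                    segment_glottis_threshold,
                                    segment_stack_threshold,
                                    track_edges_scanlines)


def _stack(pixels, fps=20_000.0, scale=0.02):
    return FrameStack(np.asarray(pixels), fps=fps, pixel_scale=scale)


class TestPreprocess:
    def test_identity(self):
        frames = np.random.default_rng(0).integers(0, 255, (3, 32, 24)) \
            .astype(np.uint8)
        out = preprocess(_stack(frames), rotation_deg=0.0)
        assert np.allclose(out.pixels, frames)

    def test_rotation_90_swaps_bar_orientation(self):
        frame = np.full((40, 40), 200, dtype=np.uint8)
        frame[18:22, 5:35] = 30                      # horizontal bar
        out = preprocess(_stack(frame[None]), rotation_deg=90.0)
        mask = out.pixels[0] < 100
        rows_extent = np.ptp(np.flatnonzero(mask.any(axis=1)))
        cols_extent = np.ptp(np.flatnonzero(mask.any(axis=0)))
        assert rows_extent == pytest.approx(29, abs=1)   # was the long axis
        assert cols_extent == pytest.approx(3, abs=1)

    def test_rotation_round_trip_recovers_widths(self):
        from dataclasses import replace as drep

        from glottovib.synth import RECIPES, make_trial

        rec = drep(RECIPES["ventricular-slow-ramp"], video_noise_sd=0.0,
                   video_duration=0.004, pre_rotate_deg=7.0,
                   protocol_params={"start": 3.0, "end": 6.0, "rate": 1.0,
                                    "hold_s": 0.2})
        tr = make_trial(rec, seed=11)
        stack = preprocess(tr.frames, rotation_deg=-7.0)
        true_w = tr.kinematics.right_x - tr.kinematics.left_x
        masks = segment_stack_threshold(stack, 100)
        w = masks.sum(axis=2).astype(float)[:, tr.line_rows] - 1.0
        assert np.abs(w - true_w).mean() <= 1.0

    def test_empty_crop_rejected(self):
        with pytest.raises(InvalidParameterError):
            preprocess(_stack(np.zeros((1, 16, 16), np.uint8)),
                       crop_box=(4, 4, 0, 8))


class TestThresholdSegmentation:
    def test_uniform_bright_frame_is_closed(self):
        res = segment_glottis_threshold(np.full((20, 20), 200, np.uint8), 100)
        assert res.closed
        assert not res.mask.any()

    def test_rectangle_width_with_margin(self):
        frame = np.full((32, 64), 200, np.uint8)
        frame[4:-4, 22:42] = 30
        res = segment_glottis_threshold(frame, 100)
        raw, _ = glottal_width_profile(res.mask, 1.0)
        assert raw[16] == 20 + measure_dilation_margin()
        corrected, mm = glottal_width_profile(res.mask, 0.01,
                                              margin_px=measure_dilation_margin())
        assert corrected[16] == 20.0
        assert mm[16] == pytest.approx(0.20)

    def test_speckle_absorbed_and_simply_connected(self):
        from scipy import ndimage

        frame = np.full((32, 64), 200, np.uint8)
        frame[4:-4, 22:42] = 30
        frame[16, 30] = 250                      # bright speckle inside
        res = segment_glottis_threshold(frame, 100)
        filled = ndimage.binary_fill_holes(res.mask)
        assert np.array_equal(filled, res.mask)  # no holes: Euler number 1
        _, n = ndimage.label(res.mask)
        assert n == 1

    def test_largest_component_kept(self):
        frame = np.full((32, 64), 200, np.uint8)
        frame[4:20, 10:20] = 30                  # large blob
        frame[25:27, 40:42] = 30                 # small blob
        res = segment_glottis_threshold(frame, 100)
        assert res.mask[10, 15]
        assert not res.mask[25:27, 40:42].any()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        frame = rng.integers(0, 255, (24, 24)).astype(np.uint8)
        low = frame < 80
        high = frame < 160
        assert np.all(high[low])                 # sub-threshold region grows

    def test_stack_version_matches_per_frame(self, short_opaque_noiseless_trial):
        stack = short_opaque_noiseless_trial.frames
        sub = stack.pixels[:20]
        batch = segment_stack_threshold(_stack(sub, fps=stack.fps), 100)
        for i in range(sub.shape[0]):
            single = segment_glottis_threshold(sub[i], 100)
            assert np.array_equal(batch[i], single.mask)


class TestWidthProfile:
    def test_empty_mask_zero_profile(self):
        w, mm = glottal_width_profile(np.zeros((8, 8), bool), 0.01)
        assert np.all(w == 0) and np.all(mm == 0)

    def test_full_row_scaling(self):
        mask = np.zeros((4, 30), bool)
        mask[2] = True
        _, mm = glottal_width_profile(mask, 0.01)
        assert mm[2] == pytest.approx(0.30)

    def test_translation_invariance(self):
        mask = np.zeros((10, 20), bool)
        mask[3:7, 5:12] = True
        w1, _ = glottal_width_profile(mask, 1.0)
        padded = np.pad(mask, ((4, 4), (6, 6)))
        w2, _ = glottal_width_profile(padded, 1.0)
        assert np.array_equal(w1[w1 > 0], w2[w2 > 0])

    def test_extent_equals_count_for_solid_rows(self):
        mask = np.zeros((5, 20), bool)
        mask[2, 4:15] = True
        assert horizontal_extent_profile(mask)[2] == \
            glottal_width_profile(mask, 1.0)[0][2]


class TestEdgeTracking:
    def test_opaque_noiseless_matches_truth(self, short_opaque_noiseless_trial):
        tr = short_opaque_noiseless_trial
        tracks = track_edges_scanlines(tr.frames)
        kin = tr.kinematics
        assert np.nanmax(np.abs(tracks.left_x - kin.left_x)) <= 0.5
        assert np.nanmax(np.abs(tracks.right_x - kin.right_x)) <= 0.5

    def test_translucent_beats_threshold(self, membrane_trial):
        # the motivating failure mode: the membrane band reads like fold
        # tissue, so thresholding under-segments; edge tracking does not
        tr = membrane_trial
        tracks = track_edges_scanlines(tr.frames)
        kin = tr.kinematics
        true_mean = (kin.right_x - kin.left_x).mean(axis=0)
        edge_mean = np.nanmean(tracks.width_px, axis=0)
        masks = segment_stack_threshold(tr.frames, tr.recipe.gray_threshold)
        thr_mean = masks.sum(axis=2).astype(float)[:, tracks.line_rows].mean(axis=0)
        assert np.all(np.abs(edge_mean - true_mean) <= 1.0)
        assert np.all(thr_mean < true_mean - 5.0)

    def test_static_frames_constant_tracks(self):
        frame = np.full((128, 64), 160, np.uint8)
        frame[16:112, 26:38] = 40
        stack = _stack(np.repeat(frame[None], 12, axis=0))
        tracks = track_edges_scanlines(stack)
        assert np.nanstd(tracks.left_x, axis=0).max() == 0.0
        assert np.nanstd(tracks.right_x, axis=0).max() == 0.0

    def test_threshold_and_edge_paths_agree_on_opaque(self,
                                                      short_opaque_noiseless_trial):
        tr = short_opaque_noiseless_trial
        tracks = track_edges_scanlines(tr.frames)
        masks = segment_stack_threshold(tr.frames, 100)
        thr_w = masks.sum(axis=2).astype(float)[:, tracks.line_rows] - 1.0
        d = np.abs(thr_w - tracks.width_px)
        assert np.nanmean(d) <= 0.5
        assert np.nanpercentile(d, 95) <= 1.5

    def test_line_count_bounds(self, short_opaque_noiseless_trial):
        with pytest.raises(InvalidParameterError):
            track_edges_scanlines(short_opaque_noiseless_trial.frames,
                                  n_lines=7)

    def test_csv_adapter_round_trip(self, tmp_path):
        rows = np.arange(16, 106, 10)
        rng = np.random.default_rng(5)
        left = rng.uniform(20, 25, (6, rows.size))
        right = rng.uniform(35, 40, (6, rows.size))
        tracks = EdgeTracks(rows, left, right, np.ones_like(left), fps=1000.0)
        path = tmp_path / "edges.csv"
        tracks.to_frame().to_csv(path, index=False)
        back = read_edge_tracks_csv(path, fps=1000.0)
        assert np.allclose(back.left_x, left)
        assert np.allclose(back.right_x, right)
        assert np.array_equal(back.line_rows, rows)
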