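import numpy as np
import pytest

from rbcflow.detect import (
    DetectionParams,
    Detection,
    calibrate_channel_span,
    detect_sequence,
    estimate_background,
    segment_frame,
)
from rbcflow.errors import ConfigurationError, RejectedInputError
from rbcflow.evaluate import detection_fidelity, match_tracks, tracking_summary
from rbcflow.geometry import ChannelGeometry
from rbcflow.shapes import BACKGROUND_LEVEL, CELL_LEVEL, ShapeClass, render_cell
from rbcflow.synth import FlowPopulationConfig, empty_channel_image, generate_sequence
from rbcflow.track import (
    CellTrack,
    LinkingParams,
    build_tracks,
    estimate_velocity,
    link_tracks,
    normalized_lateral_position,
)


def _frame_with_cell(geometry, cx, cy, shape=ShapeClass.SPHERE, noise_sd=0.0, seed=0):
    """Noiseless channel image with one rendered cell centered at (cy, cx)."""
    img = empty_channel_image(geometry)
    patch = render_cell(shape)
    p = patch.shape[0]
    r0, c0 = int(round(cy)) - p // 2, int(round(cx)) - p // 2
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1 = min(r0 + p, img.shape[0])
    cc1 = min(c0 + p, img.shape[1])
    sub = patch[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
    img[rr0:rr1, cc0:cc1] -= BACKGROUND_LEVEL - sub
    if noise_sd:
        img = img + np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    return np.clip(img, 0, 255)


class TestBackground:
    def test_constant_frames_recovered_exactly(self, geometry):
        frame = empty_channel_image(geometry)
        frames = np.stack([frame] * 12)
        assert np.array_equal(estimate_background(frames), frame)

    def test_too_few_frames_rejected(self, geometry):
        frames = np.stack([empty_channel_image(geometry)] * 5)
        with pytest.raises(RejectedInputError):
            estimate_background(frames)

    def test_close_to_true_empty_channel(self, geometry, control_run):
        bg = control_run["background"]
        truth_bg = empty_channel_image(geometry)
        err = np.abs(bg - truth_bg).max()
        assert err <= control_run["config"].noise_sd

    def test_all_zero_frames(self):
        frames = np.zeros((12, 20, 30))
        assert np.array_equal(estimate_background(frames), np.zeros((20, 30)))

    def test_channel_span_calibration(self, geometry, control_run):
        assert calibrate_channel_span(control_run["background"]) == geometry.channel_span_px


class TestSegmentation:
    def test_empty_frame_no_detections(self, geometry):
        bg = empty_channel_image(geometry)
        rng = np.random.default_rng(0)
        frame = np.clip(bg + rng.normal(0, 4.0, bg.shape), 0, 255)
        assert segment_frame(frame, bg) == []

    def test_single_cell_subpixel_centroid(self, geometry):
        bg = empty_channel_image(geometry)
        frame = _frame_with_cell(geometry, 200.3, geometry.centerline_row, noise_sd=4.0)
        dets = segment_frame(frame, bg)
        assert len(dets) == 1
        assert abs(dets[0].centroid_x_px - 200.3) < 0.5
        assert abs(dets[0].centroid_y_px - geometry.centerline_row) < 0.5

    def test_cell_half_outside_discarded(self, geometry):
        bg = empty_channel_image(geometry)
        frame = _frame_with_cell(geometry, 0.0, geometry.centerline_row, noise_sd=4.0)
        assert segment_frame(frame, bg) == []

    def test_area_bounds_filter(self, geometry):
        bg = empty_channel_image(geometry)
        frame = _frame_with_cell(geometry, 200.0, geometry.centerline_row)
        assert segment_frame(frame, bg, DetectionParams(min_area_px=5000)) == []

    def test_shape_mismatch_rejected(self, geometry):
        bg = empty_channel_image(geometry)
        with pytest.raises(RejectedInputError):
            segment_frame(bg[:50], bg)


class TestLinkingAndEstimates:
    def test_single_cell_single_track(self, geometry):
        # ~2.1 mm/s -> ~38 px/frame -> ~20 in-view frames
        cfg = FlowPopulationConfig(
            velocity_range=(2.1, 2.1), cells_per_sequence=1, seed=2,
            fraction_pathological=0.0,
        )
        frames, truth = generate_sequence(geometry, cfg)
        per_frame, _ = detect_sequence(frames)
        tracks = build_tracks(per_frame, geometry, cfg.frame_rate_hz)
        assert len(tracks) == 1
        n_full = truth.observations.fully_visible.sum()
        assert tracks[0].n_frames == n_full

    def test_sparse_cells_no_identity_switches(self, geometry, control_run):
        matched = match_tracks(control_run["tracks"], control_run["truth"], geometry)
        summary = tracking_summary(matched, control_run["truth"])
        assert summary["all_pure"]
        assert summary["n_tracks"] <= summary["n_cells"]

    def test_detections_in_single_frame_dropped(self, geometry):
        d = Detection(5, 100.0, 50.0, 900, (30, 70, 70, 130))
        per_frame = [[] for _ in range(10)]
        per_frame[5] = [d]
        assert link_tracks(per_frame, geometry, 400.0) == []

    def test_velocity_exact_arithmetic(self, geometry):
        # 10 px/frame at 400 Hz and 0.1375 um/px is exactly 0.55 mm/s
        dets = [Detection(i, 100.0 + 10.0 * i, 49.5, 900, (0, 0, 1, 1)) for i in range(5)]
        track = CellTrack(0, dets)
        v = estimate_velocity(track, 400.0, 0.1375)
        assert v == pytest.approx(0.55, abs=1e-12)
        assert track.velocity_fit_residual_px == pytest.approx(0.0, abs=1e-9)

    def test_stationary_track_zero_velocity(self, geometry):
        dets = [Detection(i, 100.0, 49.5, 900, (0, 0, 1, 1)) for i in range(5)]
        assert estimate_velocity(CellTrack(0, dets), 400.0, 0.1375) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_short_track_rejected_for_velocity(self):
        dets = [Detection(i, 100.0 + i, 49.5, 900, (0, 0, 1, 1)) for i in range(2)]
        with pytest.raises(RejectedInputError):
            estimate_velocity(CellTrack(0, dets), 400.0, 0.1375)

    def test_bad_frame_rate_rejected(self, geometry):
        with pytest.raises(ConfigurationError):
            link_tracks([[]], geometry, 0.0)

    def test_lateral_position_extremes(self, geometry):
        on_axis = CellTrack(
            0, [Detection(i, 10.0 * i, geometry.centerline_row, 900, (0, 0, 1, 1)) for i in range(3)]
        )
        assert normalized_lateral_position(on_axis, geometry) == 0.0
        wall_row = geometry.centerline_row + geometry.width_px / 2 - 0.5
        at_wall = CellTrack(
            0, [Detection(i, 10.0 * i, wall_row, 900, (0, 0, 1, 1)) for i in range(3)]
        )
        assert normalized_lateral_position(at_wall, geometry) == pytest.approx(
            0.5, abs=0.01
        )

    def test_outside_span_excluded(self, geometry):
        track = CellTrack(
            0, [Detection(i, 10.0 * i, 2.0, 900, (0, 0, 1, 1)) for i in range(3)]
        )
        with pytest.raises(RejectedInputError):
            normalized_lateral_position(track, geometry)


class TestFidelityOnSyntheticControl:
    def test_detection_recall_precision(self, control_run):
        fid = detection_fidelity(control_run["per_frame"], control_run["truth"])
        assert fid["recall"] >= 0.99
        assert fid["precision"] >= 0.99
        assert fid["mean_centroid_error_px"] <= 0.5

    def test_velocity_and_lateral_accuracy(self, geometry, control_run):
        matched = match_tracks(control_run["tracks"], control_run["truth"], geometry)
        summary = tracking_summary(matched, control_run["truth"])
        assert summary["velocity_mare"] <= 0.02
        assert summary["yW_mae"] <= 0.01

    def test_slipper_offset_recovered_through_pipeline(self, geometry, control_run):
        matched = match_tracks(control_run["tracks"], control_run["truth"], geometry)
        slip = matched[matched.true_class == "slipper"]
        if len(slip) >= 3:
            assert slip.yW_abs_error.max() <= 0.01

    def test_mirror_flip_leaves_lateral_position_unchanged(self, geometry, control_run):
        """Flipping the frames about the channel centerline must not change
        any |y/W| (the geometry is symmetric about the centerline)."""
        flipped = control_run["frames"][:, ::-1, :]
        per_frame, _ = detect_sequence(flipped)
        tracks = build_tracks(per_frame, geometry, control_run["config"].frame_rate_hz)
        a = np.sort([t.mean_abs_yW for t in control_run["tracks"]])
        b = np.sort([t.mean_abs_yW for t in tracks])
        assert len(a) == len(b)
        assert np.allclose(a, b, atol=5e-3)
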