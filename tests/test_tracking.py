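"""Tracking chain: frame selection, segmentation, centroids, smoothing,
projection, velocity and phase detection."""

import numpy as np
import pytest

import condylokin as ck
from condylokin.series import MotionPhase, TrackRejectedError
from condylokin.synthetic import ground_truth_tracks, phantom_reference_lines
from condylokin.tracking import (
    compute_velocity,
    detect_phases,
    extract_centroids,
    pair_phases,
    project_displacement,
    segment_condyles,
    select_representative_frames,
    smooth_track,
)

from conftest import make_config


def _series(frames, plane="sagittal_right", spacing=0.36, period=100.0):
    frames = np.asarray(frames, dtype=float)
    return ck.FrameSeries(
        frames=frames,
        pixel_spacing_mm=(spacing, spacing),
        timestamps_ms=period * np.arange(len(frames)),
        plane=plane,
    )


def _track(positions, side="right", plane="sagittal_right", period=100.0, valid=None):
    positions = np.asarray(positions, dtype=float)
    return ck.CondyleTrack(
        side=side,
        plane=plane,
        timestamps_ms=period * np.arange(len(positions)),
        positions_mm=positions,
        valid=valid,
    )


def _signal(displacement, side="right", plane="axial", period=100.0):
    displacement = np.asarray(displacement, dtype=float)
    return ck.DisplacementSignal(
        timestamps_ms=period * np.arange(len(displacement)),
        displacement_mm=displacement,
        side=side,
        plane=plane,
    )


class TestRepresentativeFrames:
    def test_alternating_series_covers_both_groups(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        a[2:4, 2:4] = 1.0
        b[5:7, 5:7] = 1.0
        frames = np.stack([a if i % 2 == 0 else b for i in range(40)])
        idx = select_representative_frames(_series(frames), k=2, seed=0)
        assert len(idx) == 2
        assert {i % 2 for i in idx} == {0, 1}

    def test_k_equal_n_returns_all_indices(self):
        frames = np.random.default_rng(0).random((6, 4, 4))
        idx = select_representative_frames(_series(frames), k=6, seed=0)
        assert idx.tolist() == list(range(6))

    def test_constant_series_single_cluster(self):
        frames = np.ones((5, 4, 4))
        idx = select_representative_frames(_series(frames), k=1, seed=0)
        assert len(idx) == 1

    def test_k_larger_than_series_raises(self):
        with pytest.raises(ValueError):
            select_representative_frames(_series(np.ones((3, 4, 4))), k=4)


class TestSegmentation:
    def test_noiseless_phantom_recovered_exactly(self):
        cfg = make_config(n_cycles=1)
        tracks = ground_truth_tracks(cfg, "sagittal_right")
        masks = ck.render_mask_series(tracks, cfg, "sagittal_right")
        images = ck.render_image_series(masks, snr=np.inf)
        seg = segment_condyles(images)
        assert np.array_equal(seg.frames, masks.frames)
        assert seg.valid.all()

    def test_background_frame_flagged_invalid(self):
        frames = np.zeros((3, 16, 16))
        frames[0, 4:8, 4:8] = 1.0
        frames[2, 4:8, 4:8] = 1.0
        seg = segment_condyles(_series(frames), min_area_px=4)
        assert seg.valid.tolist() == [True, False, True]

    def test_all_frames_invalid_raises(self):
        with pytest.raises(ValueError):
            segment_condyles(_series(np.zeros((3, 8, 8))))

    def test_snr10_dice_above_095(self):
        cfg = make_config(n_cycles=1)
        tracks = ground_truth_tracks(cfg, "axial")
        masks = ck.render_mask_series(tracks, cfg, "axial")
        images = ck.render_image_series(masks, snr=10.0, seed=1)
        seg = segment_condyles(images)
        for got, truth in zip(seg.frames[::25], masks.frames[::25]):
            dice = 2 * np.sum(got & truth) / (got.sum() + truth.sum())
            assert dice >= 0.95


class TestCentroids:
    def test_single_pixel_centroid(self):
        frames = np.zeros((1, 20, 20), dtype=bool)
        frames[0, 12, 10] = True  # row 12, col 10
        masks = ck.MaskSeries(
            frames=frames,
            pixel_spacing_mm=(0.36, 0.36),
            timestamps_ms=np.array([0.0]),
            plane="sagittal_right",
        )
        (track,) = extract_centroids(masks)
        assert track.positions_mm[0] == pytest.approx([3.60, 4.32])

    def test_rectangle_centroid_is_geometric_centre(self):
        frames = np.zeros((1, 30, 30), dtype=bool)
        frames[0, 10:20, 4:10] = True
        masks = ck.MaskSeries(
            frames=frames,
            pixel_spacing_mm=(1.0, 1.0),
            timestamps_ms=np.array([0.0]),
            plane="sagittal_left",
        )
        (track,) = extract_centroids(masks)
        assert track.positions_mm[0] == pytest.approx([6.5, 14.5])

    def test_axial_side_assignment_uses_mid_sagittal_line(self):
        cfg = make_config(n_cycles=1)
        tracks = ground_truth_tracks(cfg, "axial")
        masks = ck.render_mask_series(tracks, cfg, "axial")
        line = phantom_reference_lines(cfg)["axial"]
        extracted = extract_centroids(masks, mid_sagittal=line)
        by_side = {t.side: t for t in extracted}
        # Subject right = image left = smaller x.
        assert (
            by_side["right"].positions_mm[:, 0].mean()
            < by_side["left"].positions_mm[:, 0].mean()
        )

    def test_dropped_frame_interpolated_within_one_pixel(self):
        cfg = make_config(n_cycles=1)
        tracks = ground_truth_tracks(cfg, "sagittal_right")
        masks = ck.render_mask_series(tracks, cfg, "sagittal_right")
        frames = masks.frames.copy()
        mid = masks.n_frames // 2
        frames[mid] = False
        broken = ck.MaskSeries(
            frames=frames,
            pixel_spacing_mm=masks.pixel_spacing_mm,
            timestamps_ms=masks.timestamps_ms,
            plane=masks.plane,
        )
        (track,) = extract_centroids(broken)
        assert track.valid[mid]
        err = np.abs(track.positions_mm[mid] - tracks[0].positions_mm[mid])
        assert err.max() <= masks.pixel_spacing_mm[0]

    def test_long_gap_rejects_track(self):
        frames = np.zeros((20, 16, 16), dtype=bool)
        frames[:, 4:8, 4:8] = True
        frames[5:15] = False  # 10-frame gap > limit, 50% validity
        masks = ck.MaskSeries(
            frames=frames,
            pixel_spacing_mm=(1.0, 1.0),
            timestamps_ms=100.0 * np.arange(20.0),
            plane="sagittal_right",
        )
        with pytest.raises(TrackRejectedError):
            extract_centroids(masks)

    def test_translation_equivariance_whole_pixels(self):
        frames = np.zeros((2, 30, 30), dtype=bool)
        frames[0, 5:12, 5:10] = True
        frames[1, 8:15, 11:16] = True  # +3 rows, +6 cols
        masks = ck.MaskSeries(
            frames=frames,
            pixel_spacing_mm=(0.5, 0.5),
            timestamps_ms=np.array([0.0, 100.0]),
            plane="sagittal_right",
        )
        (track,) = extract_centroids(masks)
        delta = track.positions_mm[1] - track.positions_mm[0]
        assert delta == pytest.approx([6 * 0.5, 3 * 0.5])


class TestSmoothing:
    def test_constant_track_unchanged(self):
        track = _track(np.tile([3.0, 4.0], (30, 1)))
        out = smooth_track(track, 11, 2)
        assert np.allclose(out.positions_mm, track.positions_mm)

    def test_linear_track_unchanged(self):
        t = np.arange(30.0)
        track = _track(np.column_stack([2 * t, -0.5 * t]))
        out = smooth_track(track, 11, 2)
        assert np.allclose(out.positions_mm, track.positions_mm, atol=1e-9)

    def test_noise_reduction_on_raised_cosine(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 5, 120)
        clean = 15.0 * 0.5 * (1 - np.cos(np.pi * t / 5))
        noisy = clean + rng.normal(0, 0.3, t.shape)
        track = _track(np.column_stack([noisy, np.zeros_like(t)]), period=42.0)
        out = smooth_track(track, 11, 2)
        rms_raw = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_smooth = np.sqrt(np.mean((out.positions_mm[:, 0] - clean) ** 2))
        assert rms_smooth < rms_raw

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(_track(np.zeros((30, 2))), 10, 2)


class TestProjectionAndVelocity:
    def test_projection_along_x_axis(self):
        track = _track([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0]])
        sig = project_displacement(track, ck.ReferenceLine.horizontal(5.0))
        assert sig.displacement_mm == pytest.approx([0.0, 1.0, 2.0])

    def test_motion_orthogonal_to_direction_is_zero(self):
        track = _track([[0.0, 0.0], [0.0, 3.0], [0.0, 6.0]])
        sig = project_displacement(track, ck.ReferenceLine.horizontal(0.0))
        assert np.allclose(sig.displacement_mm, 0.0)

    def test_diagonal_motion_projects_by_cos45(self):
        step = 1.0
        pos = np.cumsum(np.tile([step, step], (5, 1)), axis=0)
        sig = project_displacement(_track(pos), ck.ReferenceLine.horizontal(0.0))
        inc = np.diff(sig.displacement_mm)
        length = step * np.sqrt(2)
        assert np.allclose(inc, length / np.sqrt(2))

    def test_velocity_of_linear_displacement(self):
        sig = _signal(np.arange(10.0) * 0.2, period=100.0)  # 2 mm/s
        v = compute_velocity(sig)
        assert np.allclose(v, 2.0)

    def test_velocity_of_constant_signal_is_zero(self):
        assert np.allclose(compute_velocity(_signal(np.full(10, 3.0))), 0.0)

    def test_raised_cosine_peak_velocity_matches_closed_form(self):
        A, T = 15.0, 5.0
        t = np.arange(0, T, 0.021)
        sig = _signal(A * 0.5 * (1 - np.cos(np.pi * t / T)), period=21.0)
        v = compute_velocity(sig)
        assert v.max() == pytest.approx(np.pi * A / (2 * T), rel=0.02)


class TestPhaseDetection:
    def test_single_cycle_boundaries_within_one_frame(self):
        cfg = make_config(n_cycles=1)
        (sig, _), _ = ck.generate_displacement_profiles(cfg)
        phases = detect_phases(sig)
        assert [p.kind for p in phases] == ["opening", "closing"]
        dt = sig.frame_period_ms
        assert abs(phases[0].t_end_ms - 5000.0) <= dt
        assert phases[0].t_start_ms <= dt
        assert abs(phases[1].t_end_ms - 10_000.0) <= 2 * dt

    def test_constant_signal_has_no_phases(self):
        assert detect_phases(_signal(np.full(50, 2.0))) == []

    def test_three_cycles_detected(self):
        cfg = make_config(n_cycles=3)
        (sig, _), _ = ck.generate_displacement_profiles(cfg)
        phases = detect_phases(sig)
        kinds = [p.kind for p in phases]
        assert kinds.count("opening") == 3
        assert kinds.count("closing") == 3


class TestPhasePairing:
    def _phases(self, starts, duration=5000.0, kinds=("opening", "closing")):
        out = []
        for i, s in enumerate(starts):
            kind = kinds[i % 2]
            out.append(
                MotionPhase(
                    kind=kind,
                    start_index=i * 10,
                    end_index=i * 10 + 9,
                    t_start_ms=s,
                    t_end_ms=s + duration,
                )
            )
        return out

    def test_equal_lists_pair_fully(self):
        r = self._phases([0.0, 5000.0, 10_000.0, 15_000.0])
        pairs = pair_phases(r, self._phases([0.0, 5000.0, 10_000.0, 15_000.0]))
        assert len(pairs) == 4
        opening = [p for p in pairs if p.kind == "opening"]
        assert [p.cycle_index for p in opening] == [0, 1]

    def test_missing_left_phase_leaves_right_unmatched(self):
        r = self._phases([0.0, 5000.0, 10_000.0, 15_000.0])
        l = self._phases([0.0, 5000.0, 10_000.0])
        pairs = pair_phases(r, l)
        assert len(pairs) == 3
        assert all(
            not (p.kind == "closing" and p.right_phase.t_start_ms == 15_000.0)
            for p in pairs
        )

    def test_latency_shifted_phantom_still_pairs_all_phases(self):
        cfg = make_config(
            lagging_side="left",
            latency_fraction_open=0.2,
            latency_fraction_close=0.2,
            n_cycles=3,
        )
        (sig_r, sig_l), _ = ck.generate_displacement_profiles(cfg)
        pairs = pair_phases(detect_phases(sig_r), detect_phases(sig_l))
        kinds = [p.kind for p in pairs]
        assert kinds.count("opening") == 3
        assert kinds.count("closing") == 3


class TestFullChain:
    def test_noiseless_image_chain_reproduces_generator_signal(self):
        cfg = make_config(n_cycles=1)
        for plane in ("axial", "sagittal_left"):
            tracks = ground_truth_tracks(cfg, plane)
            masks = ck.render_mask_series(tracks, cfg, plane)
            images = ck.render_image_series(masks, snr=np.inf)
            seg = segment_condyles(images)
            lines = phantom_reference_lines(cfg)
            line = lines["axial"] if plane == "axial" else lines["sagittal"]
            extracted = extract_centroids(
                seg, mid_sagittal=line if plane == "axial" else None
            )
            spacing = masks.pixel_spacing_mm[0]
            for truth, got in zip(tracks, extracted):
                smoothed = smooth_track(got, 11, 2)
                sig = project_displacement(smoothed, line)
                ref = ck.synthetic.displacement_profile(
                    cfg, truth.side, truth.timestamps_ms / 1000.0
                )
                assert np.max(np.abs(sig.displacement_mm - ref)) <= spacing
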