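import numpy as np
import pytest

from chestmorph.phantom import (
    LATTICE_PITCH_CM,
    MARKER_COLOR,
    SKIN_COLOR,
    TABLE_COLOR,
    ArtifactSpec,
    PhantomConfig,
    PhantomConfigError,
    _breathing_cycles,
    _breathing_signal,
    _pose_matrix,
    _Surface,
    artifact_masks,
    generate_sequence,
    inject_artifacts,
    operator_seed,
    table_roi_box,
    true_marker_tracks,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        PhantomConfig().validate()

    @pytest.mark.parametrize("kwargs", [
        {"marker_radius": 0.0},
        {"frame_rate": 0.0},
        {"torso_profile": (6.0,) * 6},
        {"breathing_amplitude": (-0.1,) + (0.5,) * 6},
        {"mean_period": 0.0},
        {"period_jitter": 5.0},
        {"noise_sigma": -0.1},
        {"amplitude_jitter": 1.5},
        {"baseline_jitter": -0.1},
        {"left_nipple": (0.0, 0.0), "right_nipple": (0.0, 1.0),
         "navel": (0.0, 2.0)},  # collinear markers
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(PhantomConfigError):
            PhantomConfig(**kwargs).validate()

    def test_artifact_past_end_rejected(self):
        spec = ArtifactSpec(onset_time=59.0, duration=2.0, kind="spike", magnitude=1.0)
        with pytest.raises(PhantomConfigError):
            PhantomConfig(artifacts=(spec,)).validate()


class TestBreathingWaveform:
    def test_cycles_cover_duration(self):
        c = PhantomConfig(duration=20.0, seed=1)
        starts, periods, gains, offsets = _breathing_cycles(c, np.random.default_rng(1))
        assert starts[0] == 0.0
        assert (starts + periods)[-1] >= c.duration
        np.testing.assert_allclose(np.diff(starts), periods[:-1])
        assert np.all(np.abs(periods - c.mean_period) <= c.period_jitter + 1e-12)
        assert np.all(np.abs(gains - 1.0) <= c.amplitude_jitter + 1e-12)
        assert len(offsets) == len(starts) + 1

    def test_minima_at_cycle_starts_and_per_cycle_gain(self):
        starts = np.array([0.0, 3.0, 7.0])
        periods = np.array([3.0, 4.0, 3.0])
        gains = np.array([1.0, 0.8, 1.2])
        offsets = np.zeros(4)
        t = np.linspace(0, 10, 3001)
        s = _breathing_signal(t, starts, periods, gains, offsets)
        assert s[0] == pytest.approx(0.0, abs=1e-12)
        assert s[t == 3.0][0] == pytest.approx(0.0, abs=1e-9)
        # mid-cycle peaks reach the per-cycle gain
        assert s[t == 1.5][0] == pytest.approx(1.0, abs=1e-9)
        assert s[t == 5.0][0] == pytest.approx(0.8, abs=1e-9)

    def test_baseline_keeps_minima_at_cycle_starts(self):
        starts = np.array([0.0, 3.0, 6.0])
        periods = np.array([3.0, 3.0, 3.0])
        gains = np.ones(3)
        offsets = np.array([0.05, -0.05, 0.03, 0.0])
        t = np.linspace(0, 9, 9001)
        s = _breathing_signal(t, starts, periods, gains, offsets)
        k = np.argmin(np.abs(t - 3.0))
        assert s[k] <= s[max(k - 5, 0)] and s[k] <= s[k + 5]
        assert s[k] == pytest.approx(offsets[1], abs=1e-6)


class TestGeneration:
    def test_deterministic(self):
        c = PhantomConfig(duration=0.2, seed=11)
        s1, g1 = generate_sequence(c)
        s2, g2 = generate_sequence(c)
        np.testing.assert_array_equal(s1[0].points, s2[0].points)
        np.testing.assert_array_equal(g1.marker_centers, g2.marker_centers)

    def test_frame_count_rate_and_colors(self, phantom_short):
        config, seq, gt = phantom_short
        assert len(seq) == config.n_frames == 60
        assert seq.frame_rate == config.frame_rate
        colors = seq[0].colors
        for c in (TABLE_COLOR, SKIN_COLOR, MARKER_COLOR):
            assert (colors == np.array(c, dtype=np.uint8)).all(axis=1).any()

    def test_marker_centers_lie_on_surface(self, phantom_short):
        config, seq, gt = phantom_short
        # nearest cloud point to each true marker centre is close in z
        pts = seq[10].points
        for m in range(3):
            c = gt.marker_centers[10, m]
            d = np.linalg.norm(pts[:, :2] - c[:2], axis=1)
            near = pts[d < 0.3]
            assert abs(np.median(near[:, 2]) - c[2]) < 4 * config.noise_sigma

    def test_ground_truth_signal_matches_surface_motion(self, phantom_clean):
        config, seq, gt = phantom_clean
        # with zero noise the cloud ROI mean reproduces gt.r exactly
        ch = (3, 4)
        cx, cy = config.row_x[2], config.col_y[3]
        r = []
        for frame in seq:
            p = frame.points
            m = (np.abs(p[:, 0] - cx) <= 1.0) & (np.abs(p[:, 1] - cy) <= 1.0)
            r.append(config.camera_to_table_distance - p[m, 2].mean())
        np.testing.assert_allclose(np.asarray(r), gt.r[ch], atol=1e-5)

    def test_no_lattice_point_on_channel_roi_edge(self, phantom_short):
        config, seq, gt = phantom_short
        p = seq[0].points
        for rx in config.row_x:
            for edge in (rx - 1.0, rx + 1.0):
                assert np.abs(p[:, 0] - edge).min() > 0.1 * LATTICE_PITCH_CM
        for cy in config.col_y:
            for edge in (cy - 1.0, cy + 1.0):
                assert np.abs(p[:, 1] - edge).min() > 0.1 * LATTICE_PITCH_CM

    def test_true_minima_are_signal_minima(self, phantom_clean):
        config, seq, gt = phantom_clean
        r = gt.r[(4, 4)]
        for k in gt.minima_indices:
            assert r[k] <= r[k - 1] and r[k] <= r[k + 1]
        for k in gt.maxima_indices:
            assert r[k] >= r[k - 1] and r[k] >= r[k + 1]


class TestPose:
    def test_pose_matrix_orthonormal(self):
        R = _pose_matrix(PhantomConfig(tilt=(3.0, -2.0), yaw=5.0))
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_posed_cloud_is_rigid_transform_of_unposed(self):
        c0 = PhantomConfig(duration=0.1, seed=6, noise_sigma=0.0)
        c1 = PhantomConfig(duration=0.1, seed=6, noise_sigma=0.0,
                           tilt=(4.0, -3.0), yaw=8.0, offset=(1.0, -2.0, 0.5))
        s0, _ = generate_sequence(c0)
        s1, _ = generate_sequence(c1)
        R = _pose_matrix(c1)
        expected = s0[0].points @ R.T + np.asarray(c1.offset)
        np.testing.assert_allclose(s1[0].points, expected, atol=1e-4)


class TestTableRegion:
    def test_strips_contain_only_table_points(self, phantom_short):
        config, seq, gt = phantom_short
        surface = _Surface(config)
        p = np.asarray(seq[0].points, dtype=np.float64)
        P, _ = surface.base_and_amp(p[:, 0], p[:, 1])
        n = 0
        for box in table_roi_box(config):
            m = box.contains(p)
            n += m.sum()
            assert np.all(P[m] == 0.0)  # no torso points in any strip
        assert n > 1000

    def test_no_margin_raises(self):
        c = PhantomConfig(table_extent=(20.0, 12.0))  # torso fills the table
        with pytest.raises(PhantomConfigError):
            table_roi_box(c)


class TestArtifacts:
    def test_masks_cover_windows(self):
        c = PhantomConfig(duration=10.0, seed=2, artifacts=(
            ArtifactSpec(onset_time=2.0, duration=1.0, kind="spike",
                         magnitude=1.0, rows=(1, 2)),))
        masks, merged = artifact_masks(c.artifacts, c)
        lo, hi = 60, 90
        assert merged[lo:hi].all() and not merged[:lo].any() and not merged[hi:].any()
        assert masks[(1, 1)][lo:hi].all()
        assert not masks[(5, 1)].any()  # unaffected row

    def test_injection_moves_only_window_frames(self):
        c = PhantomConfig(duration=4.0, seed=2, noise_sigma=0.0)
        seq, _ = generate_sequence(c)
        ref = [f.points.copy() for f in seq]
        spec = ArtifactSpec(onset_time=1.0, duration=1.0, kind="step-shift",
                            magnitude=0.7)
        inject_artifacts(seq, [spec], c)
        moved = [not np.array_equal(f.points, r) for f, r in zip(seq, ref)]
        assert not any(moved[:30]) and all(moved[30:60]) and not any(moved[60:])
        # the step moves affected points toward the camera by the magnitude
        delta = ref[45][:, 2] - seq[45].points[:, 2]
        assert delta.max() == pytest.approx(0.7, abs=1e-4)

    def test_overlapping_specs_warn(self):
        c = PhantomConfig(duration=6.0, seed=2)
        seq, _ = generate_sequence(PhantomConfig(duration=6.0, seed=2, noise_sigma=0.0))
        specs = [ArtifactSpec(onset_time=1.0, duration=2.0, kind="drift", magnitude=0.5),
                 ArtifactSpec(onset_time=2.0, duration=2.0, kind="spike", magnitude=0.5)]
        with pytest.warns(UserWarning, match="overlap"):
            inject_artifacts(seq, specs, c)


class TestHelpers:
    def test_true_marker_tracks_match_ground_truth(self, phantom_short):
        config, seq, gt = phantom_short
        tracks = true_marker_tracks(gt)
        assert len(tracks) == len(seq)
        np.testing.assert_allclose(tracks[5].centers(), gt.marker_centers[5])

    def test_operator_seed_is_offset_not_exact(self, phantom_short):
        config, seq, gt = phantom_short
        seed = operator_seed(gt)
        err = np.linalg.norm(seed.centers()[:, :2] - gt.marker_centers[0][:, :2], axis=1)
        assert np.all(err > 0.1) and np.all(err < 1.0)
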