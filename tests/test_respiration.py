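import numpy as np
import pytest

from chestmorph.respiration import (
    WAVELET_CENTER_FREQUENCY,
    BreathFeatureModel,
    RespirationError,
    breath_features,
    compute_scalogram,
    detect_artifact_samples,
    detect_extrema,
    gate_breaths,
    remove_artifact_breaths,
    scale_to_frequency,
    scales_for_band,
    separate_breaths,
    smooth,
    wavelet,
)

FS = 30.0


def _raised_cosine(duration=20.0, period=4.0, amp=1.5, fs=FS):
    t = np.arange(0, duration, 1 / fs)
    return t, amp * (0.5 - 0.5 * np.cos(2 * np.pi * t / period))


class TestSmoothing:
    def test_preserves_breathing_band(self):
        t, x = _raised_cosine()
        y = smooth(x, FS)
        assert np.abs(y[60:-60] - x[60:-60]).max() < 0.01 * x.max()

    def test_attenuates_high_frequency(self):
        t, x = _raised_cosine()
        rng = np.random.default_rng(0)
        noisy = x + 0.2 * np.sin(2 * np.pi * 8.0 * t) + rng.normal(0, 0.05, len(t))
        y = smooth(noisy, FS)
        assert np.abs(y[60:-60] - x[60:-60]).max() < 0.05

    def test_zero_phase(self):
        # a symmetric pulse stays centered after filtering
        t = np.arange(0, 10, 1 / FS)
        x = np.exp(-((t - 5.0) ** 2) / 0.5)
        y = smooth(x, FS)
        assert abs(t[np.argmax(y)] - 5.0) < 1.5 / FS

    def test_too_short(self):
        with pytest.raises(RespirationError, match="short"):
            smooth(np.zeros(10), FS)


class TestExtrema:
    def test_cosine_extrema_alternate(self):
        t, x = _raised_cosine(duration=20.0, period=4.0)
        minima, maxima = detect_extrema(x)
        # maxima at mid-cycle 2, 6, 10, 14, 18 s; interior minima at 4, 8, 12, 16 s
        np.testing.assert_allclose(t[maxima], [2, 6, 10, 14, 18], atol=2 / FS)
        np.testing.assert_allclose(t[minima], [4, 8, 12, 16], atol=2 / FS)

    def test_endpoints_never_extrema(self):
        x = np.concatenate([np.linspace(1, 0, 30), np.linspace(0, 1, 30)])
        with pytest.warns(UserWarning):  # only one minimum -> zero breaths
            minima, maxima = detect_extrema(x)
        assert 0 not in minima and len(x) - 1 not in minima
        assert 0 not in maxima and len(x) - 1 not in maxima

    def test_plateau_resolves_to_leftmost(self):
        x = np.concatenate([np.arange(5.0), np.full(4, 5.0), np.arange(5.0)[::-1]])
        with pytest.warns(UserWarning):  # no interior minima at all
            _, maxima = detect_extrema(x)
        assert maxima.tolist() == [5]

    def test_alternation_repaired(self):
        from chestmorph.respiration import _repair_alternation

        # two consecutive maxima with no minimum between: keep the higher one
        x = np.array([0, 1, 2, 1.8, 1.9, 2.5, 1, 0, 1, 0], dtype=float)
        minima, maxima = _repair_alternation(x, np.array([7]), np.array([2, 5, 8]))
        assert maxima.tolist() == [5, 8] and minima.tolist() == [7]

    def test_detected_extrema_strictly_alternate(self):
        rng = np.random.default_rng(11)
        x = smooth(rng.normal(size=600), FS, cutoff_hz=2.0)
        minima, maxima = detect_extrema(x)
        kinds = sorted([(i, "min") for i in minima] + [(i, "max") for i in maxima])
        for (_, ka), (_, kb) in zip(kinds[:-1], kinds[1:]):
            assert ka != kb

    def test_monotonic_signal_warns_zero_breaths(self):
        with pytest.warns(UserWarning, match="zero breaths"):
            minima, _ = detect_extrema(np.linspace(0, 1, 100))
        assert len(minima) == 0


class TestBreathSeparation:
    def test_counts_and_features(self):
        t, x = _raised_cosine(duration=20.0, period=4.0, amp=1.5)
        minima, maxima = detect_extrema(x)
        breaths = separate_breaths(x, minima, maxima, FS)
        assert len(breaths) == 3  # 4 interior minima -> 3 complete segments
        for b in breaths:
            assert b.period == pytest.approx(4.0, abs=2 / FS)
            assert b.amplitude == pytest.approx(1.5, rel=0.02)
            assert b.start_min_index < b.max_index < b.end_min_index

    def test_invalid_ordering_rejected(self):
        from chestmorph.respiration import BreathSegment

        with pytest.raises(ValueError):
            BreathSegment(0, 10, 5, 20, 1.0, 1.0)


class TestWavelet:
    def test_shape_and_center_frequency(self):
        assert wavelet(np.array([0.0]))[0] == pytest.approx(1.0)
        # even function
        t = np.linspace(-3, 3, 101)
        np.testing.assert_allclose(wavelet(t), wavelet(-t), atol=1e-15)
        # oscillation frequency: pi*sqrt(2/ln2)/(2 pi)
        assert WAVELET_CENTER_FREQUENCY == pytest.approx(
            np.sqrt(2.0 / np.log(2.0)) / 2.0)

    def test_scales_cover_band(self):
        scales = scales_for_band(FS, n_scales=16, f_min=0.05, f_max=5.0)
        freqs = scale_to_frequency(scales, FS)
        assert freqs.min() == pytest.approx(0.05)
        assert freqs.max() == pytest.approx(5.0)

    def test_scalogram_matches_naive_quadrature(self):
        # oracle: W(a, b) = (1/sqrt a) * sum_t x(t) psi((t - b)/a), done with
        # an explicit double loop, compared to the fftconvolve implementation
        rng = np.random.default_rng(42)
        x = rng.normal(size=120)
        scales = np.array([2.0, 5.0, 11.3])
        got = compute_scalogram(x, scales)

        pad = int(np.ceil(4.0 * scales.max()))
        pad = min(pad, len(x) - 1)
        xp = np.pad(x, pad, mode="reflect")
        tt = np.arange(len(xp))
        expected = np.empty((len(scales), len(x)))
        for k, a in enumerate(scales):
            for b in range(len(x)):
                arg = (tt - (b + pad)) / a
                keep = np.abs(arg) <= np.ceil(4.0 * a) / a
                expected[k, b] = abs(np.sum(xp[keep] * wavelet(arg[keep])) / np.sqrt(a))
        np.testing.assert_allclose(got.magnitude, expected, atol=1e-9)

    def test_scalogram_peaks_at_matching_scale(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 0.5 * t)
        scales = scales_for_band(FS, 32, 0.05, 5.0)
        mag = compute_scalogram(x, scales).magnitude
        best = scale_to_frequency(scales, FS)[np.argmax(mag.mean(axis=1))]
        assert best == pytest.approx(0.5, rel=0.15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_scalogram(np.array([]), np.array([2.0]))
        with pytest.raises(ValueError):
            compute_scalogram(np.ones(10), np.array([-1.0]))


class TestArtifactDetection:
    def test_percentile_rule_is_exact(self):
        # by construction the flagged fraction equals 1 - percentile/100
        rng = np.random.default_rng(7)
        sig = {(4, 4): rng.normal(size=3000)}
        masks, merged = detect_artifact_samples(sig)
        crit_flagged = masks[(4, 4)].mean()
        assert crit_flagged == pytest.approx(0.01, abs=0.002)
        # the merged mask covers every raw exceedance
        assert not (masks[(4, 4)] & ~merged).any()

    def test_transient_localized(self):
        t, x = _raised_cosine(duration=60.0, period=4.0)
        x = x.copy()
        k0 = int(30.0 * FS)
        x[k0:k0 + 15] += 1.5  # abrupt 0.5 s shift
        masks, merged = detect_artifact_samples({(4, 4): x})
        flagged = np.nonzero(masks[(4, 4)])[0]
        assert len(flagged) > 0
        assert np.all(np.abs(flagged - (k0 + 7)) < FS)  # crest within 1 s
        # the merged mask extends the crest by the localization tolerance
        spread = np.nonzero(merged)[0]
        assert np.all(np.abs(spread - (k0 + 7)) < 2 * FS)

    def test_union_across_channels(self):
        from chestmorph.config import RunConfig

        rng = np.random.default_rng(9)
        a = rng.normal(size=1000)
        b = rng.normal(size=1000)
        cfg = RunConfig(artifact_dilation_s=0.0)  # isolate the union itself
        masks, merged = detect_artifact_samples({(1, 1): a, (2, 2): b}, cfg)
        np.testing.assert_array_equal(merged, masks[(1, 1)] | masks[(2, 2)])

    def test_merged_mask_dilation_width(self):
        from chestmorph.config import RunConfig

        x = np.zeros(600)
        x[300] = 50.0  # a single impulse dominates the criterion
        masks, merged = detect_artifact_samples(
            {(4, 4): x}, RunConfig(artifact_dilation_s=1.0))
        lo, hi = np.nonzero(masks[(4, 4)])[0][[0, -1]]
        span = np.nonzero(merged)[0]
        assert span[0] == max(lo - 30, 0) and span[-1] == min(hi + 30, 599)


class TestBreathCleaning:
    def _breaths(self):
        t, x = _raised_cosine(duration=24.0, period=4.0)
        minima, maxima = detect_extrema(x)
        return separate_breaths(x, minima, maxima, FS), len(x)

    def test_overlapping_breaths_removed(self):
        breaths, n = self._breaths()
        mask = np.zeros(n, dtype=bool)
        mask[breaths[1].max_index] = True  # artifact inside breath 1 only
        kept, removed = remove_artifact_breaths(breaths, mask)
        assert [b.breath_id for b in removed] == [breaths[1].breath_id]
        assert len(kept) == len(breaths) - 1

    def test_all_removed_raises(self):
        breaths, n = self._breaths()
        with pytest.raises(RespirationError, match="no clean breathing"):
            remove_artifact_breaths(breaths, np.ones(n, dtype=bool))


class TestGating:
    def _features(self, n, seed, mean=(4.0, 1.5), sd=(0.2, 0.1)):
        rng = np.random.default_rng(seed)
        return rng.normal(mean, sd, size=(n, 2))

    def test_self_gate_keeps_typical_breaths(self):
        f = self._features(40, 1)
        keep, keep_b, (model, model_b) = gate_breaths(f)
        assert keep_b is None and model_b is None
        assert keep.mean() >= 0.9

    def test_outlier_rejected(self):
        f = np.vstack([self._features(30, 2), [[12.0, 6.0]]])
        keep, _, _ = gate_breaths(f)
        assert not keep[-1]
        assert keep[:-1].mean() > 0.9

    def test_two_session_gate_is_intersection(self):
        fa = self._features(30, 3)
        fb = self._features(30, 4, mean=(4.1, 1.45))
        keep_a, keep_b, (ma, mb) = gate_breaths(fa, fb)
        floor = 0.05
        np.testing.assert_array_equal(
            keep_a, (ma.membership(fa) >= floor) & (mb.membership(fa) >= floor))
        np.testing.assert_array_equal(
            keep_b, (ma.membership(fb) >= floor) & (mb.membership(fb) >= floor))

    def test_disjoint_sessions_reject_everything(self):
        fa = self._features(30, 5)
        fb = self._features(30, 6, mean=(9.0, 4.0), sd=(0.05, 0.02))
        keep_a, keep_b, _ = gate_breaths(fa, fb)
        assert keep_a.sum() == 0 and keep_b.sum() == 0

    def test_membership_matches_chi2_tail(self):
        from scipy.stats import chi2

        f = self._features(200, 8)
        model = BreathFeatureModel.fit(f)
        pt = model.mean + np.array([0.2, 0.1])
        diff = pt - model.mean
        d2 = diff @ np.linalg.inv(model.covariance) @ diff
        assert model.membership(pt)[0] == pytest.approx(chi2.sf(d2, df=2))

    def test_identical_breaths_degenerate_covariance(self):
        f = np.tile([4.0, 1.5], (10, 1))
        keep, _, _ = gate_breaths(f)
        assert keep.all()

    def test_too_few_breaths(self):
        with pytest.raises(RespirationError, match="at least 5"):
            BreathFeatureModel.fit(np.ones((3, 2)))

    def test_breath_features_shape(self):
        breaths, _ = TestBreathCleaning()._breaths()
        f = breath_features(breaths)
        assert f.shape == (len(breaths), 2)
        assert breath_features([]).shape == (0, 2)
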