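"""Standardization chain: filtering, normalization, length, smoothing,
augmentation bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poseload as pl
from poseload.features import DEFAULT_TOPOLOGY, bone_vectors
from poseload.preprocess import gaussian_kernel
from poseload.synth import PoseSequence


def _seq(coords, beats=(), fps=25.0):
    return PoseSequence(coords=np.asarray(coords, float), fps=fps, genre=0,
                        difficulty=1, lfhf=1.5, delta_alpha=0.2,
                        beat_frames=np.array(beats, dtype=int))


def _random_seq(rng, t=100):
    return _seq(rng.normal(size=(t, 25, 3)))


class TestGrayVarianceFilter:
    def test_blurry_and_sharp_frames(self):
        constant = np.full((8, 8), 40.0)            # variance 0: blurry
        checker = np.indices((8, 8)).sum(0) % 2 * 255.0  # variance 16256.25
        assert np.isclose(checker.var(), 127.5 ** 2)
        kept = pl.gray_variance_filter([constant, checker, constant])
        assert kept == [1]

    def test_zero_threshold_keeps_everything(self):
        frames = [np.zeros((4, 4)), np.ones((4, 4))]
        assert pl.gray_variance_filter(frames, threshold=0.0) == [0, 1]

    def test_empty_and_bad_input(self):
        assert pl.gray_variance_filter([]) == []
        with pytest.raises(ValueError, match="2-D"):
            pl.gray_variance_filter([np.zeros((2, 2, 3))])


class TestMinMaxNormalize:
    def test_endpoint_and_midpoint_identities(self):
        stats = pl.NormalizationStats(x_min=np.full((25, 3), 1.0),
                                      x_max=np.full((25, 3), 3.0))
        coords = np.full((4, 25, 3), 2.0)
        coords[0] = 1.0  # -> 0
        coords[1] = 3.0  # -> 1
        out = pl.minmax_normalize(_seq(coords), stats).coords
        assert np.allclose(out[0], 0.0)
        assert np.allclose(out[1], 1.0)
        assert np.allclose(out[2], 0.5)

    def test_degenerate_axis_maps_to_zero(self):
        stats = pl.NormalizationStats(x_min=np.zeros((25, 3)),
                                      x_max=np.zeros((25, 3)))
        out = pl.minmax_normalize(_seq(np.ones((3, 25, 3))), stats).coords
        assert np.allclose(out, 0.0)

    def test_idempotent_on_own_stats(self, rng):
        seq = _random_seq(rng, t=30)
        stats = pl.NormalizationStats.from_sequences([seq])
        once = pl.minmax_normalize(seq, stats)
        own = pl.NormalizationStats.from_sequences([once])
        twice = pl.minmax_normalize(once, own)
        assert np.allclose(once.coords, twice.coords, atol=1e-12)

    def test_stats_json_roundtrip(self, rng):
        seq = _random_seq(rng, t=10)
        stats = pl.NormalizationStats.from_sequences([seq])
        back = pl.NormalizationStats.from_json(stats.to_json())
        assert np.array_equal(back.x_min, stats.x_min)


class TestStandardizeLength:
    def test_exact_length_is_identity(self, rng):
        seq = _random_seq(rng, t=100)
        out = pl.standardize_length(seq, target=100)
        assert len(out) == 1 and np.array_equal(out[0].coords, seq.coords)

    def test_interpolation_preserves_linear_ramp(self):
        t = np.arange(50, dtype=float)
        coords = np.tile(t[:, None, None], (1, 25, 3))
        out = pl.standardize_length(_seq(coords), target=100)
        assert len(out) == 1 and out[0].coords.shape == (100, 25, 3)
        expected = np.linspace(0.0, 49.0, 100)
        assert np.allclose(out[0].coords[:, 0, 0], expected, atol=1e-9)

    def test_beat_segmentation_count(self, rng):
        seq = _seq(rng.normal(size=(250, 25, 3)), beats=(0, 100, 200))
        out = pl.standardize_length(seq, target=100)
        assert len(out) == 3
        assert all(s.coords.shape[0] == 100 for s in out)

    def test_uniform_fallback_without_beats(self, rng):
        seq = _seq(rng.normal(size=(250, 25, 3)))
        out = pl.standardize_length(seq, target=100)
        assert len(out) == 3
        assert all(s.coords.shape[0] == 100 for s in out)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(t=st.integers(min_value=2, max_value=600))
    def test_length_law(self, t):
        rng = np.random.default_rng(t)
        seq = _seq(rng.normal(size=(t, 25, 3)))
        for piece in pl.standardize_length(seq, target=100):
            assert piece.coords.shape[0] == 100


class TestGaussianSmooth:
    def test_constant_signal_unchanged(self):
        seq = _seq(np.full((40, 25, 3), 2.5))
        out = pl.gaussian_smooth(seq)
        assert np.allclose(out.coords, 2.5)

    def test_impulse_centre_equals_kernel_centre_weight(self):
        # independent evaluation of the discrete Gaussian, sigma 0.8, window 5
        x = np.arange(-2, 3, dtype=float)
        w = np.exp(-0.5 * (x / 0.8) ** 2)
        w /= w.sum()
        coords = np.zeros((41, 25, 3))
        coords[20] = 1.0
        out = pl.gaussian_smooth(_seq(coords))
        assert np.allclose(out.coords[20], w[2], atol=1e-12)
        assert np.allclose(gaussian_kernel(5, 0.8), w)

    def test_variance_non_increasing(self, rng):
        seq = _random_seq(rng, t=200)
        out = pl.gaussian_smooth(seq)
        var_before = seq.coords.reshape(200, -1).var(axis=0)
        var_after = out.coords.reshape(200, -1).var(axis=0)
        assert np.all(var_after <= var_before + 1e-12)

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            pl.gaussian_smooth(_random_seq(rng), window=4)


class TestAugment:
    def test_zero_magnitudes_are_identity(self, rng):
        seq = _random_seq(rng)
        spec = pl.AugmentSpec(temporal_scale_pct=0, spatial_noise_pct=0,
                              angle_jitter_deg=0, seed=0)
        out = pl.augment(seq, spec)
        assert np.array_equal(out.coords, seq.coords)

    def test_spatial_noise_bound_on_normalized_sequence(self, rng):
        coords = rng.uniform(0.0, 1.0, size=(100, 25, 3))
        seq = _seq(coords)
        for seed in range(50):
            spec = pl.AugmentSpec(temporal_scale_pct=0, spatial_noise_pct=5,
                                  angle_jitter_deg=0, seed=seed)
            delta = np.abs(pl.augment(seq, spec).coords - coords)
            assert delta.max() <= 0.05 + 1e-12

    def test_angle_jitter_bounded_and_length_preserving(self, rng):
        cfg = pl.GenConfig(n_sequences=10, seed=0)
        seq = pl.generate_sequence(cfg, difficulty=3, seed=1)
        spec = pl.AugmentSpec(temporal_scale_pct=0, spatial_noise_pct=0,
                              angle_jitter_deg=3, seed=2)
        out = pl.augment(seq, spec)
        b0 = bone_vectors(seq, DEFAULT_TOPOLOGY)
        b1 = bone_vectors(out, DEFAULT_TOPOLOGY)
        assert np.allclose(np.linalg.norm(b0, axis=-1),
                           np.linalg.norm(b1, axis=-1), atol=1e-9)
        cos = (b0 * b1).sum(-1) / (np.linalg.norm(b0, axis=-1)
                                   * np.linalg.norm(b1, axis=-1))
        angles = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        assert angles.max() <= 3.0 + 1e-6

    def test_temporal_factor_within_ten_percent(self):
        from poseload.preprocess import draw_temporal_factor
        for seed in range(1000):
            f = draw_temporal_factor(np.random.default_rng(seed), 10.0)
            assert 0.9 <= f <= 1.1

    def test_augment_preserves_frame_count(self, rng):
        seq = _random_seq(rng)
        out = pl.augment(seq, pl.AugmentSpec(seed=3))
        assert out.coords.shape == seq.coords.shape

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            pl.AugmentSpec(spatial_noise_pct=-1)
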