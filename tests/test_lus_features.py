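"""Unit and property tests for the four imaging statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aerolus.errors import ConfigurationError, DomainError, UndefinedStatisticError
from aerolus.lus_features import (
    FeatureVector,
    RoiSpec,
    UltrasoundClip,
    clip_features,
    coefficient_of_variation,
    extract_roi,
    mean_pixel_intensity,
    power_spectrum_auc,
)
from aerolus.simulate import SimulationConfig, default_rois, generate_clip

from _oracles import clip_features_loop, cov_loop, mpi_loop, naive_power_auc


class TestExtractRoi:
    def test_full_frame_roi_is_identity(self):
        frame = np.arange(10000).reshape(100, 100) % 256
        roi = RoiSpec(top_row=0, left_col=0, depth_cm=1.0, width_px=100)
        block = extract_roi(frame, roi, pixel_spacing_cm_per_px=0.01)
        np.testing.assert_array_equal(block, frame)

    def test_depth_converts_to_rows(self):
        frame = np.zeros((300, 50))
        roi = RoiSpec(top_row=10, left_col=5, depth_cm=2.0, width_px=20)
        block = extract_roi(frame, roi, pixel_spacing_cm_per_px=0.01)
        assert block.shape == (200, 20)

    def test_out_of_bounds_roi_rejected(self):
        frame = np.zeros((100, 50))
        roi = RoiSpec(top_row=50, left_col=0, depth_cm=1.0, width_px=20)
        with pytest.raises(DomainError):
            extract_roi(frame, roi, pixel_spacing_cm_per_px=0.01)

    def test_non_integer_row_count_rejected(self):
        roi = RoiSpec(top_row=0, left_col=0, depth_cm=1.0, width_px=20)
        with pytest.raises(DomainError):
            extract_roi(np.zeros((100, 50)), roi, pixel_spacing_cm_per_px=0.03)


class TestMoments:
    @pytest.mark.parametrize(
        "block, expected",
        [
            (np.full((5, 7), 100.0), 100.0),
            (np.array([[0.0, 50.0], [100.0, 150.0]]), 75.0),
        ],
    )
    def test_mpi_arithmetic(self, block, expected):
        assert mean_pixel_intensity(block) == expected

    def test_mpi_matches_pixel_sum_oracle_on_synthetic_frame(self):
        cfg = SimulationConfig.desk_scale()
        clip = generate_clip(cfg, 0.6, "inflation", seed=7)
        block = clip.frames[0][40:120, 20:60].astype(float)
        assert mean_pixel_intensity(block) == pytest.approx(mpi_loop(block), rel=1e-12)

    def test_cov_constant_block_is_zero(self):
        assert coefficient_of_variation(np.full((4, 4), 37.0)) == 0.0

    def test_cov_two_point_block(self):
        # population SD of {50, 150} is 50, mean 100
        assert coefficient_of_variation(np.array([[50.0, 150.0]])) == pytest.approx(0.5)

    def test_cov_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            coefficient_of_variation(np.zeros((3, 3)))

    def test_empty_block_rejected(self):
        with pytest.raises(DomainError):
            mean_pixel_intensity(np.empty((0, 4)))

    @settings(max_examples=30, derandomize=True)
    @given(
        scale=st.floats(min_value=0.1, max_value=5.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_mpi_linear_and_cov_invariant_under_scaling(self, scale, seed):
        block = np.random.default_rng(seed).uniform(10, 200, size=(12, 9))
        assert mean_pixel_intensity(scale * block) == pytest.approx(
            scale * mean_pixel_intensity(block), rel=1e-10
        )
        assert coefficient_of_variation(scale * block) == pytest.approx(
            coefficient_of_variation(block), rel=1e-10
        )


class TestPowerSpectrumAuc:
    SPACING = 0.1  # cm/px on a 16-px block: frequencies 0.625 k cycles/cm

    def test_constant_block_zero(self):
        block = np.full((16, 16), 42.0)
        for axis in ("parallel", "perpendicular"):
            assert power_spectrum_auc(block, axis, (0.5, 4.0), self.SPACING) == 0.0

    def test_cosine_grating_matches_naive_dft(self):
        x = np.arange(16)
        block = np.tile(np.cos(2 * np.pi * 3 * x / 16), (16, 1))  # varies across columns
        band = (0.5, 4.0)
        ours = power_spectrum_auc(block, "parallel", band, self.SPACING)
        oracle = naive_power_auc(block, "parallel", band, self.SPACING)
        assert ours == pytest.approx(oracle, rel=1e-9)
        assert ours > 0

    def test_cosine_grating_has_zero_perpendicular_power(self):
        x = np.arange(16)
        block = np.tile(np.cos(2 * np.pi * 3 * x / 16), (16, 1))
        assert power_spectrum_auc(block, "perpendicular", (0.5, 4.0), self.SPACING) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_random_block_matches_naive_dft_both_axes(self, rng):
        block = rng.uniform(0, 255, size=(16, 16))
        for axis in ("parallel", "perpendicular"):
            ours = power_spectrum_auc(block, axis, (0.7, 4.5), self.SPACING)
            oracle = naive_power_auc(block, axis, (0.7, 4.5), self.SPACING)
            assert ours == pytest.approx(oracle, rel=1e-9)

    def test_band_validation(self):
        block = np.zeros((16, 16))
        with pytest.raises(DomainError):
            power_spectrum_auc(block, "parallel", (0.0, 4.0), self.SPACING)
        with pytest.raises(DomainError):
            power_spectrum_auc(block, "parallel", (0.5, 10.0), self.SPACING)  # above Nyquist
        with pytest.raises(DomainError):
            power_spectrum_auc(np.zeros((8, 8)), "parallel", (0.5, 4.0), self.SPACING)

    @settings(max_examples=20, derandomize=True)
    @given(
        offset=st.floats(min_value=-50, max_value=50),
        scale=st.floats(min_value=0.1, max_value=3.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_offset_invariance_and_quadratic_scaling(self, offset, scale, seed):
        block = np.random.default_rng(seed).uniform(20, 200, size=(16, 16))
        base = power_spectrum_auc(block, "parallel", (0.5, 4.0), self.SPACING)
        shifted = power_spectrum_auc(block + offset, "parallel", (0.5, 4.0), self.SPACING)
        scaled = power_spectrum_auc(scale * block, "parallel", (0.5, 4.0), self.SPACING)
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(scale**2 * base, rel=1e-9)


class TestClipFeatures:
    def _clip(self, frames, spacing=0.01):
        return UltrasoundClip(frames=np.asarray(frames), pixel_spacing_cm_per_px=spacing)

    def test_single_roi_weighted_mean_is_plain_mean(self, rng):
        frames = rng.uniform(10, 200, size=(3, 64, 48))
        clip = self._clip(frames, spacing=0.05)
        roi = RoiSpec(top_row=4, left_col=4, depth_cm=1.0, width_px=32)
        fv = clip_features(clip, [roi], band=(1.0, 8.0))
        per_frame = [mean_pixel_intensity(extract_roi(f, roi, 0.05)) for f in frames]
        assert fv.mpi == pytest.approx(np.mean(per_frame), rel=1e-12)

    def test_area_weighted_pooling(self):
        # two equal-depth ROIs with areas in ratio 1:3 and MPI 10 and 20
        frame = np.zeros((25, 80))
        frame[0:20, 0:16] = 10.0
        frame[0:20, 20:68] = 20.0
        clip = self._clip(frame[None], spacing=0.1)
        rois = [
            RoiSpec(top_row=0, left_col=0, depth_cm=2.0, width_px=16),
            RoiSpec(top_row=0, left_col=20, depth_cm=2.0, width_px=48),
        ]
        fv = clip_features(clip, rois, band=(1.0, 4.0))
        assert fv.mpi == pytest.approx((1 * 10 + 3 * 20) / 4)  # 17.5

    def test_depth_assignment_requires_matching_roi(self, desk_config):
        clip = generate_clip(desk_config, 0.3, "inflation", seed=3)
        rois = [
            RoiSpec(top_row=44, left_col=17, depth_cm=2.0, width_px=100),
            RoiSpec(top_row=44, left_col=17, depth_cm=3.0, width_px=100),
        ]
        with pytest.raises(ConfigurationError):
            clip_features(clip, rois)  # no 4-cm ROI for MPI

    def test_pooled_mpi_cov_match_double_loop_oracle(self, desk_config):
        """Full 45-frame clip, all three ROI depths, area weighting."""
        clip = generate_clip(desk_config, 0.62, "inflation", seed=11)
        rois = default_rois(desk_config)
        band = (0.1, 2.0)
        depths = {"mpi": 4.0, "cov": 2.0, "auc_parallel": 4.0, "auc_perpendicular": 4.0}
        fv = clip_features(clip, rois, band=band)
        oracle = clip_features_loop(clip, rois, band, depths, stats=("mpi", "cov"))
        assert fv.mpi == pytest.approx(oracle["mpi"], rel=1e-12)
        assert fv.cov == pytest.approx(oracle["cov"], rel=1e-12)

    def test_pooled_spectral_aucs_match_naive_dft_oracle(self):
        """Small clip so the quadratic direct-sum DFT oracle is affordable."""
        cfg = SimulationConfig.desk_scale(frames_per_clip=3)
        clip = generate_clip(cfg, 0.62, "inflation", seed=11)
        rois = [
            RoiSpec(top_row=44, left_col=20, depth_cm=0.5, width_px=16),
            RoiSpec(top_row=44, left_col=60, depth_cm=0.5, width_px=24),
        ]
        band = (2.0, 10.0)
        depths = {"mpi": 0.5, "cov": 0.5, "auc_parallel": 0.5, "auc_perpendicular": 0.5}
        fv = clip_features(clip, rois, band=band)
        oracle = clip_features_loop(
            clip, rois, band, depths, stats=("auc_parallel", "auc_perpendicular")
        )
        assert fv.auc_parallel == pytest.approx(oracle["auc_parallel"], rel=1e-9)
        assert fv.auc_perpendicular == pytest.approx(oracle["auc_perpendicular"], rel=1e-9)

    def test_frame_order_permutation_invariance(self, desk_config, rng):
        clip = generate_clip(desk_config, 0.4, "inflation", seed=5)
        rois = default_rois(desk_config)
        fv = clip_features(clip, rois)
        permuted = UltrasoundClip(
            frames=clip.frames[rng.permutation(clip.n_frames)],
            pixel_spacing_cm_per_px=clip.pixel_spacing_cm_per_px,
        )
        fv2 = clip_features(permuted, rois)
        assert fv2.mpi == pytest.approx(fv.mpi, rel=1e-12)
        assert fv2.cov == pytest.approx(fv.cov, rel=1e-12)
        assert fv2.auc_parallel == pytest.approx(fv.auc_parallel, rel=1e-10)

    def test_feature_vector_rejects_negative_auc(self):
        with pytest.raises(DomainError):
            FeatureVector(mpi=1.0, cov=0.1, auc_parallel=-1.0, auc_perpendicular=0.0, roi_area_px=10)
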