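"""Closed-form checks and invariants of the quality metrics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from creambosso import ImageGrid, contrast, psnr, quality_report, shannon_entropy, snr, ssim
from creambosso.errors import InvalidInputError, UndefinedMetricError
from creambosso.metrics import estimate_noise_variance, mse


class TestContrast:
    def test_constant_image_has_zero_contrast(self):
        assert contrast(np.full((8, 8), 42.0)) == 0.0

    def test_bimodal_closed_form(self):
        img = np.concatenate([np.full(32, 50.0), np.full(32, 150.0)]).reshape(8, 8)
        assert contrast(img) == pytest.approx(1.0, abs=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(17)
        img = rng.uniform(1.0, 255.0, (12, 12))
        assert contrast(scale * img) == pytest.approx(contrast(img), rel=1e-9)

    def test_zero_mean_is_undefined_not_zero(self):
        with pytest.raises(UndefinedMetricError):
            contrast(np.zeros((5, 5)))


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert shannon_entropy(ImageGrid(np.full((16, 16), 7.0))) == 0.0

    def test_uniform_256_levels_eight_bits(self):
        img = ImageGrid(np.arange(256, dtype=float).reshape(16, 16), bit_depth=8)
        assert shannon_entropy(img) == pytest.approx(8.0, abs=1e-12)

    def test_two_equiprobable_levels_one_bit(self):
        img = ImageGrid(np.concatenate([np.full(32, 10.0), np.full(32, 200.0)]).reshape(8, 8))
        assert shannon_entropy(img) == pytest.approx(1.0, abs=1e-12)

    def test_16bit_range_anchored_to_bit_depth(self):
        # same values, different nominal range -> different binning
        values = np.arange(256, dtype=float).reshape(16, 16)
        assert shannon_entropy(ImageGrid(values, bit_depth=16)) < shannon_entropy(
            ImageGrid(values, bit_depth=8)
        )

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1),
           nbins=st.sampled_from([4, 16, 256]))
    def test_bounded_by_log2_nbins(self, seed, nbins):
        rng = np.random.default_rng(seed)
        img = ImageGrid(rng.uniform(0, 255, (10, 10)))
        h = shannon_entropy(img, nbins=nbins)
        assert 0.0 <= h <= math.log2(nbins) + 1e-12

    def test_invalid_nbins(self):
        with pytest.raises(InvalidInputError):
            shannon_entropy(np.ones((4, 4)), nbins=1)


class TestPsnr:
    def test_uniform_offset_closed_form(self):
        rng = np.random.default_rng(23)
        ref = rng.uniform(20, 200, (16, 16))
        assert psnr(ref + 10.0, ref) == pytest.approx(
            10 * math.log10(255**2 / 100), abs=1e-9
        )
        assert psnr(ref + 10.0, ref) == pytest.approx(28.131, abs=5e-4)

    def test_two_pixel_hand_case(self):
        a = np.array([[0.0, 10.0]])
        b = np.array([[0.0, 0.0]])
        assert mse(a, b) == 50.0
        assert psnr(a, b) == pytest.approx(10 * math.log10(65025 / 50), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(29)
        a, b = rng.uniform(0, 255, (8, 8)), rng.uniform(0, 255, (8, 8))
        assert psnr(a, b) == psnr(b, a)

    def test_identical_images_signal_infinity(self):
        a = np.ones((4, 4))
        assert psnr(a, a) == math.inf

    def test_monotone_decreasing_in_mse(self):
        ref = np.zeros((8, 8))
        assert psnr(ref + 5.0, ref) > psnr(ref + 20.0, ref)


class TestSnr:
    def test_mean100_sigma10_is_20db(self):
        assert snr(100.0, 100.0) == pytest.approx(20.0, abs=1e-12)

    def test_mean_equals_sigma_is_0db(self):
        assert snr(7.0, 49.0) == pytest.approx(0.0, abs=1e-12)

    def test_doubling_mean_adds_6db(self):
        assert snr(200.0, 100.0) - snr(100.0, 100.0) == pytest.approx(
            10 * math.log10(4), abs=1e-12
        )

    def test_zero_variance_signals_infinity(self):
        assert snr(10.0, 0.0) == math.inf

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(InvalidInputError):
            snr(0.0, 1.0)


class TestSsim:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(31)
        img = rng.uniform(0, 255, (16, 16))
        assert ssim(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(37)
        a, b = rng.uniform(0, 255, (16, 16)), rng.uniform(0, 255, (16, 16))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_constant_vs_constant_reduces_to_luminance_term(self):
        c1, c2 = 100.0, 120.0
        a = ImageGrid(np.full((16, 16), c1))
        b = ImageGrid(np.full((16, 16), c2))
        big_c1 = (0.01 * 255) ** 2
        expected = (2 * c1 * c2 + big_c1) / (c1**2 + c2**2 + big_c1)
        assert ssim(a, b) == pytest.approx(expected, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            ssim(np.ones((16, 16)), np.ones((16, 15)))


class TestNoiseVarianceAndReport:
    def test_variance_from_reference(self):
        rng = np.random.default_rng(41)
        ref = rng.uniform(50, 200, (16, 16))
        noise = rng.normal(0, 5, (16, 16))
        est = estimate_noise_variance(ref + noise, reference=ref)
        assert est == pytest.approx(np.var(noise), rel=1e-12)

    def test_variance_from_flat_mask(self):
        img = np.zeros((8, 8))
        img[:4] = 100.0
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True
        assert estimate_noise_variance(img, mask=mask) == 0.0

    def test_requires_reference_or_mask(self):
        with pytest.raises(InvalidInputError):
            estimate_noise_variance(np.ones((4, 4)))

    def test_report_without_reference_has_no_fidelity_metrics(self):
        rng = np.random.default_rng(43)
        rep = quality_report(ImageGrid(rng.uniform(0, 255, (16, 16))))
        assert rep.psnr_db is None and rep.ssim is None
        assert rep.contrast is not None and rep.entropy_bits > 0

    def test_report_with_reference_is_complete(self):
        rng = np.random.default_rng(47)
        ref = ImageGrid(rng.uniform(20, 200, (16, 16)))
        img = ImageGrid(np.clip(ref.pixels + rng.normal(0, 3, (16, 16)), 0, 255))
        rep = quality_report(img, reference=ref)
        assert rep.mse is not None and rep.mse > 0
        assert rep.psnr_db == pytest.approx(10 * math.log10(255**2 / rep.mse))
        assert -1.0 <= rep.ssim <= 1.0

    def test_undefined_contrast_reported_as_none(self):
        rep = quality_report(ImageGrid(np.zeros((16, 16))))
        assert rep.contrast is None
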