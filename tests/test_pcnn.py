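import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hepaseg import (
    ConfigurationError,
    InputError,
    NoiseSpec,
    PCNNParams,
    PhantomSpec,
    add_noise,
    denoise,
    detect_bright_impulses,
    generate_phantom,
    median_baseline,
    morph_clean,
    pcnn_iterate,
    psnr,
)
from hepaseg.pcnn import default_kernel

from .reference import grey_open_3x3_reference, pcnn_reference

ZERO_KERNEL = np.zeros((3, 3))


class TestPCNNIterate:
    def test_all_zero_image_never_fires(self):
        rec = pcnn_iterate(np.zeros((8, 8)), PCNNParams(n_iter=20))
        assert (rec.first_fire == 0).all()
        assert rec.fire_counts.sum() == 0

    def test_defaults_echoed_in_record(self):
        rec = pcnn_iterate(np.full((4, 4), 100.0))
        assert rec.params.beta == 0.5
        assert rec.params.v_e == 2.0
        assert rec.params.alpha_e == 0.3

    def test_uniform_image_fires_in_unison(self):
        rec = pcnn_iterate(np.full((6, 6), 120.0), PCNNParams(n_iter=10))
        fired = rec.first_fire
        assert fired.min() == fired.max() >= 1

    def test_bright_pixel_fires_before_background_uncoupled(self):
        img = np.full((7, 7), 100.0)
        img[3, 3] = 255.0
        params = PCNNParams(kernel=ZERO_KERNEL, n_iter=20)
        rec = pcnn_iterate(img, params)
        bright = rec.first_fire[3, 3]
        rest = np.delete(rec.first_fire.ravel(), 3 * 7 + 3)
        assert bright >= 1
        assert (rest == 0).all() or bright < rest[rest > 0].min()

    @pytest.mark.parametrize("feedback", ["full", "stimulus_only"])
    def test_matches_straight_line_reference(self, feedback, rng):
        img = rng.integers(0, 256, size=(6, 6)).astype(float)
        params = PCNNParams(n_iter=12, feedback=feedback)
        rec = pcnn_iterate(img, params)
        expected = pcnn_reference(
            img, beta=0.5, v_e=2.0, alpha_e=0.3, alpha_f=0.1, v_f=0.5,
            alpha_l=1.0, v_l=0.2, kernel=default_kernel().tolist(),
            n_iter=12, feedback=feedback,
        )
        np.testing.assert_array_equal(rec.first_fire, expected)

    def test_threshold_strictly_decreasing_for_silent_neuron(self):
        img = np.full((5, 5), 200.0)
        img[0, 0] = 0.0  # zero stimulus: U stays 0, neuron never fires
        rec = pcnn_iterate(img, PCNNParams(kernel=ZERO_KERNEL, n_iter=15),
                           record_states=True)
        assert rec.first_fire[0, 0] == 0
        thresholds = [s.E[0, 0] for s in rec.states]
        assert all(b < a for a, b in zip(thresholds, thresholds[1:]))

    def test_intensity_ordering_uncoupled(self):
        levels = [50, 100, 150, 200, 250]
        img = np.repeat(np.array(levels, dtype=float)[:, None], 5, axis=1)
        rec = pcnn_iterate(img, PCNNParams(kernel=ZERO_KERNEL, n_iter=30))
        first = rec.first_fire[:, 0]
        assert (first > 0).all()
        assert (np.diff(first) <= 0).all()  # brighter rows fire no later
        assert (rec.first_fire == first[:, None]).all()  # equal rows in unison

    def test_empty_image_rejected(self):
        with pytest.raises(InputError):
            pcnn_iterate(np.empty((0, 0)))


class TestDetectBrightImpulses:
    def test_uniform_image_flags_all_with_full_window(self):
        img = np.full((8, 8), 90.0)
        params = PCNNParams(n_iter=10)
        flags = detect_bright_impulses(img, params, window=10)
        assert flags.all()

    def test_all_zero_image_flags_nothing(self):
        assert detect_bright_impulses(np.zeros((8, 8)), window=1).sum() == 0

    def test_salt_pixels_flagged_in_first_window(self):
        img, _ = generate_phantom(PhantomSpec(size=64), seed=7)
        assert img.max() < 255
        noisy = add_noise(img, NoiseSpec(impulse_density=0.02, salt_vs_pepper=1.0, seed=7))
        salt = (noisy == 255) & (img != 255)
        flags = detect_bright_impulses(noisy, window=1).astype(bool)
        assert (flags & salt).sum() == salt.sum()  # flagged superset of salt

    def test_window_validation(self):
        img = np.full((4, 4), 10.0)
        with pytest.raises(ConfigurationError):
            detect_bright_impulses(img, window=0)
        with pytest.raises(ConfigurationError):
            detect_bright_impulses(img, PCNNParams(n_iter=5), window=6)


class TestMorphClean:
    def test_empty_flag_is_noop(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        out = morph_clean(img, np.zeros_like(img))
        assert np.array_equal(out, img)

    def test_isolated_impulse_removed(self):
        img = np.full((9, 9), 100, dtype=np.uint8)
        img[4, 4] = 255
        flags = np.zeros_like(img)
        flags[4, 4] = 1
        out = morph_clean(img, flags)
        assert out[4, 4] == 100
        assert out[4, 4] == grey_open_3x3_reference(img, 4, 4)

    def test_3x3_bright_square_survives_opening(self):
        img = np.full((11, 11), 20, dtype=np.uint8)
        img[4:7, 4:7] = 200
        flags = np.zeros_like(img)
        flags[4:7, 4:7] = 1
        out = morph_clean(img, flags)
        assert (out[4:7, 4:7] == 200).all()  # square contains the element

    def test_unflagged_pixels_bit_identical(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        flags = (rng.random((32, 32)) < 0.2).astype(np.uint8)
        out = morph_clean(img, flags)
        assert np.array_equal(out[flags == 0], img[flags == 0])

    def test_opening_matches_enumeration_oracle(self, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        flags = np.ones_like(img)
        out = morph_clean(img, flags)
        for i in range(10):
            for j in range(10):
                assert out[i, j] == grey_open_3x3_reference(img, i, j)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            morph_clean(np.zeros((4, 4)), np.zeros((5, 5)))


class TestDenoise:
    def test_uniform_image_unchanged(self):
        img = np.full((16, 16), 77, dtype=np.uint8)
        assert np.array_equal(denoise(img), img)

    def test_psnr_improves_on_noisy_phantom(self, small_phantom_pair):
        img, _ = small_phantom_pair
        noisy = add_noise(img, NoiseSpec(impulse_density=0.02, seed=7))
        cleaned = denoise(noisy)
        assert psnr(img, cleaned) > psnr(img, noisy)

    def test_second_pass_changes_fewer_pixels(self, small_phantom_pair):
        img, _ = small_phantom_pair
        noisy = add_noise(img, NoiseSpec(impulse_density=0.02, seed=7))
        once = denoise(noisy)
        twice = denoise(once)
        assert (twice != once).sum() <= (once != noisy).sum()


class TestPSNR:
    def test_constant_difference_closed_form(self):
        a = np.zeros((2, 2))
        b = np.full((2, 2), 5.0)
        expected = 10 * math.log10(255 ** 2 / 25)
        assert psnr(a, b) == pytest.approx(expected, rel=1e-9)
        assert psnr(a, b) == pytest.approx(34.1514, abs=1e-3)

    def test_single_pixel_difference(self):
        a = np.zeros((16, 16))
        b = a.copy()
        b[0, 0] = 255.0
        assert psnr(a, b) == pytest.approx(10 * math.log10(256), rel=1e-9)

    def test_symmetric(self, rng):
        a = rng.integers(0, 256, (8, 8)).astype(float)
        b = rng.integers(0, 256, (8, 8)).astype(float)
        assert psnr(a, b) == psnr(b, a)

    def test_identical_images_reported_as_infinite(self):
        a = np.full((4, 4), 9.0)
        assert psnr(a, a) == math.inf


class TestMedianBaseline:
    def test_uniform_unchanged(self):
        img = np.full((8, 8), 42, dtype=np.uint8)
        assert np.array_equal(median_baseline(img, 3), img)

    def test_single_impulse_removed(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 255
        assert median_baseline(img, 3)[4, 4] == 0

    def test_improves_psnr_on_noisy_phantom(self, small_phantom_pair):
        img, _ = small_phantom_pair
        noisy = add_noise(img, NoiseSpec(impulse_density=0.02, seed=7))
        assert psnr(img, median_baseline(noisy, 3)) > psnr(img, noisy)

    @pytest.mark.parametrize("k", [2, 4, 1])
    def test_bad_kernel_size_rejected(self, k):
        with pytest.raises(ConfigurationError):
            median_baseline(np.zeros((4, 4), dtype=np.uint8), k)
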