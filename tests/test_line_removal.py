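"""Line removal: HSV, inRange, Gabor, vertical opening, dilation, merge."""

import math

import numpy as np
import pytest

from mammoprep.artefact_removal import StructuringElement, remove_artefacts
from mammoprep.line_removal import (
    GaborParams,
    IntensityRange,
    dilate,
    gabor_filter,
    gabor_kernel,
    in_range,
    invert_mask,
    open_vertical,
    remove_line,
    rgb_to_hsv,
)
from mammoprep.phantom import PhantomSpec, generate_phantom

from .conftest import random_mask
from .oracles import dilate_bruteforce, gabor_value, hsv_pixel


class TestRgbToHsv:
    def test_pure_red(self):
        px = np.array([[[255, 0, 0]]], dtype=np.uint8)
        h, s, v = rgb_to_hsv(px)[0, 0]
        assert (h, s, v) == (0, 255, 255)

    def test_gray_has_zero_saturation(self):
        px = np.array([[[128, 128, 128]]], dtype=np.uint8)
        assert rgb_to_hsv(px)[0, 0, 1] == 0

    def test_value_is_channel_max(self, rng):
        img = rng.integers(0, 256, (20, 20, 3)).astype(np.uint8)
        assert np.array_equal(rgb_to_hsv(img)[..., 2], img.max(axis=2))

    def test_matches_per_pixel_oracle(self, rng):
        img = rng.integers(0, 256, (25, 40, 3)).astype(np.uint8)
        hsv = rgb_to_hsv(img)
        for y in range(25):
            for x in range(40):
                r, g, b = (int(v) for v in img[y, x])
                assert tuple(int(v) for v in hsv[y, x]) == hsv_pixel(r, g, b)

    def test_rejects_single_channel(self):
        with pytest.raises(ValueError):
            rgb_to_hsv(np.zeros((4, 4), dtype=np.uint8))


class TestInRange:
    RANGE = IntensityRange((0, 0, 200), (255, 255, 255))

    def test_bright_pixel_selected(self):
        px = np.array([[[10, 50, 210]]], dtype=np.uint8)
        assert in_range(px, self.RANGE)[0, 0] == 255

    def test_value_below_bound_rejected(self):
        px = np.array([[[10, 50, 199]]], dtype=np.uint8)
        assert in_range(px, self.RANGE)[0, 0] == 0

    def test_matches_conjunction_oracle(self, rng):
        img = rng.integers(0, 256, (30, 30, 3)).astype(np.uint8)
        out = in_range(img, self.RANGE)
        for y in range(30):
            for x in range(30):
                inside = all(
                    self.RANGE.low[c] <= img[y, x, c] <= self.RANGE.high[c]
                    for c in range(3)
                )
                assert out[y, x] == (255 if inside else 0)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            IntensityRange((10, 0, 0), (0, 255, 255))


class TestGaborKernel:
    def test_center_is_cos_psi(self):
        for psi in (0.0, 1.0, 20.0):
            params = GaborParams(psi=psi)
            k = gabor_kernel(params)
            assert k[2, 2] == pytest.approx(math.cos(psi))

    def test_even_symmetry_for_zero_phase(self):
        k = gabor_kernel(GaborParams(theta=0.0, psi=0.0))
        assert np.allclose(k, k[:, ::-1])

    def test_matches_direct_formula(self, rng):
        for _ in range(50):
            params = GaborParams(
                ksize=(5, 7),
                sigma=float(rng.uniform(0.5, 5)),
                theta=float(rng.uniform(0, 2 * math.pi)),
                lambd=float(rng.uniform(0.5, 5)),
                gamma=float(rng.uniform(0.2, 2)),
                psi=float(rng.uniform(0, 2 * math.pi)),
            )
            k = gabor_kernel(params)
            for iy, y in enumerate(range(-3, 4)):
                for ix, x in enumerate(range(-2, 3)):
                    assert k[iy, ix] == pytest.approx(
                        gabor_value(
                            x, y, params.sigma, params.theta, params.lambd,
                            params.gamma, params.psi,
                        ),
                        abs=1e-12,
                    )

    def test_rejects_even_kernel(self):
        with pytest.raises(ValueError):
            GaborParams(ksize=(4, 5))


class TestGaborFilter:
    def test_zero_in_zero_out(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        assert gabor_filter(mask, GaborParams()).sum() == 0

    def test_impulse_response_matches_clipped_kernel(self):
        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[10, 10] = 255
        out = gabor_filter(mask, GaborParams())
        k = gabor_kernel(GaborParams())
        # correlation flips nothing: response at (10+dy, 10+dx) = k[2-dy, 2-dx]*255
        for dy in range(-2, 3):
            for dx in range(-2, 3):
                expected = 255 if np.clip(k[2 - dy, 2 - dx] * 255, 0, 255) >= 127 else 0
                assert out[10 + dy, 10 + dx] == expected

    def test_matches_sliding_window_sum(self, rng):
        mask = random_mask(rng, (20, 20), p=0.3)
        params = GaborParams()
        k = gabor_kernel(params)
        # edge-inclusive reflection, the border rule of the filter stage
        padded = np.pad(mask.astype(np.float64), 2, mode="symmetric")
        expected = np.zeros((20, 20))
        for y in range(20):
            for x in range(20):
                expected[y, x] = (padded[y : y + 5, x : x + 5] * k).sum()
        out = gabor_filter(mask, params)
        rebin = np.where(np.clip(expected, 0, 255) >= 127, 255, 0)
        assert np.array_equal(out, rebin)


class TestVerticalOpening:
    def test_tall_line_unchanged(self):
        mask = np.zeros((60, 20), dtype=np.uint8)
        mask[5:45, 10] = 255  # height 40
        assert np.array_equal(open_vertical(mask), mask)

    def test_short_blob_removed(self):
        mask = np.zeros((60, 60), dtype=np.uint8)
        mask[10:30, 10:30] = 255  # height 20 < 30
        assert open_vertical(mask).sum() == 0

    def test_every_surviving_run_is_at_least_30(self, rng):
        mask = random_mask(rng, (80, 40), p=0.8)
        out = open_vertical(mask)
        for col in range(40):
            run = 0
            for v in np.r_[out[:, col], 0]:
                if v:
                    run += 1
                else:
                    assert run == 0 or run >= 30
                    run = 0


class TestDilate:
    def test_empty_stays_empty(self):
        assert dilate(np.zeros((10, 10), dtype=np.uint8)).sum() == 0

    def test_single_pixel_becomes_5x5_block(self):
        mask = np.zeros((11, 11), dtype=np.uint8)
        mask[5, 5] = 255
        out = dilate(mask)
        expected = np.zeros((11, 11), dtype=np.uint8)
        expected[3:8, 3:8] = 255
        assert np.array_equal(out, expected)

    def test_matches_bruteforce_max_filter(self, rng):
        mask = random_mask(rng, (32, 32), p=0.2)
        out = dilate(mask, StructuringElement(5, 5)) == 255
        assert np.array_equal(out, dilate_bruteforce(mask == 255, 5, 5))

    def test_extensive(self, rng):
        mask = random_mask(rng, (32, 32), p=0.3)
        out = dilate(mask)
        assert not ((mask == 255) & (out == 0)).any()


class TestInvertMask:
    def test_complement_values(self):
        mask = np.array([[0, 255]], dtype=np.uint8)
        assert invert_mask(mask).tolist() == [[255, 0]]

    def test_involution_and_cover(self, rng):
        mask = random_mask(rng, (16, 16))
        assert np.array_equal(invert_mask(invert_mask(mask)), mask)
        assert ((mask | invert_mask(mask)) == 255).all()


class TestRemoveLine:
    def test_attached_line_erased(self, phantom_with_everything, config):
        img, truth = phantom_with_everything
        cleaned = remove_artefacts(img, config)
        out = remove_line(cleaned, config)
        line = truth.line_mask == 255
        assert (out[line] == 0).mean() >= 0.95

    def test_identity_without_bright_vertical_runs(self, plain_phantom, config):
        img, truth = plain_phantom
        cleaned = remove_artefacts(img, config)
        assert np.array_equal(remove_line(cleaned, config), cleaned)

    def test_all_black_unchanged(self, config):
        blank = np.zeros((64, 64), dtype=np.uint8)
        assert np.array_equal(remove_line(blank, config), blank)

    def test_only_line_neighbourhood_modified(self, phantom_with_everything, config):
        """Erased pixels stay within the Gabor + dilation margin of the line."""
        from scipy import ndimage

        img, truth = phantom_with_everything
        cleaned = remove_artefacts(img, config)
        out = remove_line(cleaned, config)
        erased = (cleaned > 0) & (out == 0)
        margin = ndimage.binary_dilation(truth.line_mask == 255, np.ones((9, 9)))
        assert not (erased & ~margin).any()
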