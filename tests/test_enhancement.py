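"""Enhancement: gamma map, CLAHE, LUT recoloring and the full chain."""

import numpy as np
import pytest

from mammoprep.config import PipelineConfig
from mammoprep.enhancement import (
    CLAHEParams,
    GammaParams,
    builtin_gfb_lut,
    clahe,
    double_clahe,
    enhance,
    gamma_correct,
    green_fire_blue,
    identity_lut,
    load_lut,
)
from mammoprep.phantom import PhantomSpec, generate_phantom, lesion_contrast

from .oracles import global_hist_eq


class TestGamma:
    def test_g1_is_identity(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert np.array_equal(gamma_correct(img, GammaParams(1.0)), img)

    @pytest.mark.parametrize("g", [0.5, 1.0, 2.0, 3.0])
    def test_endpoints_fixed_and_monotone(self, g):
        ramp = np.arange(256, dtype=np.uint8).reshape(1, -1)
        out = gamma_correct(ramp, GammaParams(g))[0]
        assert out[0] == 0 and out[-1] == 255
        assert (np.diff(out.astype(int)) >= 0).all()

    def test_worked_value(self):
        img = np.array([[64]], dtype=np.uint8)
        assert gamma_correct(img, GammaParams(2.0))[0, 0] == 128

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            GammaParams(0.0)


class TestClahe:
    def test_constant_image_stays_constant(self):
        img = np.full((64, 64), 90, dtype=np.uint8)
        out = clahe(img, CLAHEParams())
        assert np.unique(out).size == 1

    def test_single_tile_no_clip_equals_global_histeq(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = clahe(img, CLAHEParams(clip_limit_norm=None, tile_grid=(1, 1)))
        assert np.array_equal(out, global_hist_eq(img))

    def test_output_in_range_and_tile_mapping_monotone(self, rng):
        from mammoprep.enhancement import _tile_mapping

        img = rng.integers(0, 256, (96, 96)).astype(np.uint8)
        out = clahe(img, CLAHEParams())
        assert out.min() >= 0 and out.max() <= 255
        lut = _tile_mapping(img[:12, :12], CLAHEParams())
        assert (np.diff(lut.astype(int)) >= 0).all()

    def test_clipped_histogram_bound(self, rng):
        """Every clipped bin stays <= C_L plus the redistribution increment."""
        from mammoprep.enhancement import CLAHEParams

        params = CLAHEParams(clip_limit_norm=1.0)
        tile = rng.integers(0, 64, (28, 28)).astype(np.uint8)  # skewed histogram
        n_avg = tile.size / params.gray_levels
        clip = max(1, int(params.clip_limit_norm * n_avg))
        hist = np.bincount(tile.ravel(), minlength=256)
        excess = int(np.sum(np.maximum(hist - clip, 0)))
        clipped = np.minimum(hist, clip) + excess // 256
        clipped[: excess % 256] += 1
        assert clipped.max() <= clip + excess // 256 + 1

    def test_rejects_multichannel(self):
        with pytest.raises(ValueError):
            clahe(np.zeros((8, 8, 3), dtype=np.uint8))

    def test_non_divisible_size_handled(self, rng):
        img = rng.integers(0, 256, (50, 37)).astype(np.uint8)
        out = clahe(img, CLAHEParams(tile_grid=(8, 8)))
        assert out.shape == img.shape


class TestDoubleClahe:
    def test_equals_two_manual_passes(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        params = CLAHEParams()
        assert np.array_equal(double_clahe(img, params), clahe(clahe(img, params), params))

    def test_constant_stays_constant(self):
        img = np.full((32, 32), 200, dtype=np.uint8)
        assert np.unique(double_clahe(img)).size == 1

    def test_second_pass_does_not_reduce_breast_contrast(self):
        """On a low-contrast phantom the second pass keeps or increases the
        intensity spread inside the breast."""
        img, truth = generate_phantom(PhantomSpec(seed=21, tissue_density=0.4))
        breast = truth.breast_mask == 255
        p1 = clahe(img)
        p2 = clahe(p1)
        assert p2[breast].std() >= p1[breast].std() * 0.95


class TestGreenFireBlue:
    def test_lookup_at_zero(self):
        lut = builtin_gfb_lut()
        img = np.zeros((2, 2), dtype=np.uint8)
        assert (green_fire_blue(img)[0, 0] == lut[0]).all()

    def test_identity_lut_replicates_channels(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        out = green_fire_blue(img, identity_lut())
        for c in range(3):
            assert np.array_equal(out[..., c], img)

    def test_builtin_table_hue_progression(self):
        lut = builtin_gfb_lut()
        r, g, b = (int(v) for v in lut[60])
        assert b > g > r  # low intensities blue-dominant
        r, g, b = (int(v) for v in lut[230])
        assert r >= 200 and g >= 200 and b < 50  # high intensities yellow

    def test_pure_per_intensity_function(self, rng):
        img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        perm = rng.permutation(144)
        shuffled = img.ravel()[perm].reshape(12, 12)
        out_then_permute = green_fire_blue(img).reshape(144, 3)[perm]
        permute_then_out = green_fire_blue(shuffled).reshape(144, 3)
        assert np.array_equal(out_then_permute, permute_then_out)

    def test_rejects_malformed_lut(self):
        with pytest.raises(ValueError):
            green_fire_blue(np.zeros((4, 4), np.uint8), np.zeros((100, 3), np.uint8))


class TestLutIO:
    def test_imagej_binary_roundtrip(self, tmp_path):
        lut = builtin_gfb_lut()
        raw = np.concatenate([lut[:, 0], lut[:, 1], lut[:, 2]]).astype(np.uint8)
        path = tmp_path / "gfb.lut"
        path.write_bytes(raw.tobytes())
        assert np.array_equal(load_lut(path), lut)

    def test_csv_dialect(self, tmp_path):
        lut = builtin_gfb_lut()
        path = tmp_path / "gfb.csv"
        lines = ["R,G,B"] + [",".join(str(int(v)) for v in row) for row in lut]
        path.write_text("\n".join(lines))
        assert np.array_equal(load_lut(path), lut)

    def test_rejects_truncated_binary(self, tmp_path):
        path = tmp_path / "bad.lut"
        path.write_bytes(b"\x00" * 100)
        with pytest.raises(ValueError):
            load_lut(path)


class TestEnhance:
    def test_neutral_parameters_give_identity(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        cfg = PipelineConfig(gamma_value=1.0, clahe_passes=0)
        out = enhance(img, cfg, lut=identity_lut())
        for c in range(3):
            assert np.array_equal(out[..., c], img)

    def test_output_shape_contract(self, plain_phantom, config):
        img, _ = plain_phantom
        out = enhance(img, config)
        assert out.shape == (*img.shape, 3)
        assert out.dtype == np.uint8

    def test_lesion_contrast_increases(self, config):
        """Grayscale enhancement raises lesion-to-surround contrast on
        low-contrast phantoms (averaged over seeds)."""
        gains = []
        for seed in range(8):
            img, truth = generate_phantom(PhantomSpec(seed=300 + seed))
            _, stages = enhance(img, config, return_stages=True)
            gains.append(
                lesion_contrast(stages["clahe2"], truth) - lesion_contrast(img, truth)
            )
        assert np.mean(gains) > 0
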