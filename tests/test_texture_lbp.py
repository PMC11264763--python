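"""LBP maps, heterogeneity maps, weighted histograms, LBGLCM and the pyramid."""

import numpy as np
import pytest

from gliomatex import (
    heterogeneity_maps,
    heterogeneity_weighted_lbp,
    image_pyramid,
    lbglcm_features,
    lbp_binary_to_decimal,
    lbp_histogram_features,
    lbp_map,
    multiscale_lbglcm,
    quantize_gray,
)
from gliomatex.fixtures_io import ParameterError
from gliomatex.texture import compute_glcm, glcm_features

from _oracles import lbp_oracle, riu2_oracle


class TestLbpMap:
    def test_worked_string_conversion(self):
        assert lbp_binary_to_decimal("11001001") == 201

    def test_constant_image_all_bits_set(self):
        m = lbp_map(np.full((6, 6), 9), P=8, R=1, variant="basic")
        assert np.all(m.codes == 255)  # s(0) = 1 convention

    def test_constant_image_riu2_class(self):
        m = lbp_map(np.full((6, 6), 9), P=8, R=1, variant="riu2")
        assert np.all(m.codes == 8)  # the all-ones uniform class

    def test_matches_naive_oracle_away_from_fp_ties(self, rng):
        img = rng.integers(0, 256, (12, 12))
        m = lbp_map(img, P=8, R=1, variant="basic")
        want, tie_margin = lbp_oracle(img, 8, 1)
        safe = tie_margin > 1e-6
        assert safe.mean() > 0.5  # the comparison is not vacuous
        np.testing.assert_array_equal(m.codes[safe], want[safe])

    def test_riu2_histogram_rotation_invariant_exact(self, rng):
        img = rng.integers(0, 256, (16, 16))
        base = np.bincount(lbp_map(img, 8, 1, "riu2").codes.ravel(), minlength=10)
        for k in (1, 2, 3):
            rot = np.bincount(lbp_map(np.rot90(img, k), 8, 1, "riu2").codes.ravel(),
                              minlength=10)
            np.testing.assert_array_equal(base, rot)
        for flip in (np.flipud, np.fliplr):
            f = np.bincount(lbp_map(flip(img), 8, 1, "riu2").codes.ravel(),
                            minlength=10)
            np.testing.assert_array_equal(base, f)

    def test_riu2_class_mapping_against_enumeration(self, rng):
        """basic codes and riu2 codes of the same image agree with the
        rotation-class oracle pixel by pixel."""
        img = rng.integers(0, 256, (10, 10))
        basic = lbp_map(img, 8, 1, "basic").codes
        riu2 = lbp_map(img, 8, 1, "riu2").codes
        mapped = np.vectorize(lambda c: riu2_oracle(int(c), 8))(basic)
        np.testing.assert_array_equal(riu2, mapped)

    def test_too_small_image_rejected(self):
        with pytest.raises(ParameterError):
            lbp_map(np.zeros((2, 2)), P=8, R=1)


class TestLbpHistograms:
    def test_blocks_normalized_and_sized(self, rng):
        img = rng.integers(0, 256, (32, 32))
        feats = lbp_histogram_features(img)
        assert len(feats) == 10 + 18 + 26  # P+2 bins per (P, R)
        for P, R in ((8, 1), (16, 2), (24, 3)):
            block = [v for k, v in feats.items() if k.startswith(f"p{P}r{R}.")]
            assert sum(block) == pytest.approx(1.0)

    def test_constant_image_one_hot_blocks(self):
        feats = lbp_histogram_features(np.full((32, 32), 5))
        for P, R in ((8, 1), (16, 2), (24, 3)):
            block = [v for k, v in feats.items() if k.startswith(f"p{P}r{R}.")]
            assert max(block) == 1.0 and sum(block) == 1.0


class TestHeterogeneity:
    def test_constant_neighborhood_limits(self):
        het = heterogeneity_maps(np.full((8, 8), 3), P=8, R=1)
        np.testing.assert_allclose(het.variance_map, 0.0)
        np.testing.assert_allclose(het.homogeneity_map, 1.0)

    def test_half_half_neighborhood_variance(self):
        # neighbors half 0, half 255: V = (255/2)^2 = 16256.25
        img = np.array([[9, 0, 9], [255, 7, 0], [9, 255, 9]], float)
        het = heterogeneity_maps(img, P=4, R=1)
        # P=4, R=1 neighbors of the center: (right, up, left, down) = (0, 0, 255, 255)
        assert het.variance_map[0, 0] == pytest.approx(127.5 ** 2)

    def test_variance_matches_two_pass_oracle(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(float)
        P, R = 8, 1
        het = heterogeneity_maps(img, P=P, R=R)
        import math
        for r in range(1, 15):
            for c in range(1, 15):
                samples = []
                for p in range(P):
                    th = 2 * math.pi * p / P
                    ry, cx = r - R * math.sin(th), c + R * math.cos(th)
                    y0, x0 = int(math.floor(ry)), int(math.floor(cx))
                    fy, fx = ry - y0, cx - x0
                    y1 = min(y0 + 1, img.shape[0] - 1)
                    x1 = min(x0 + 1, img.shape[1] - 1)
                    samples.append(img[y0, x0] * (1 - fy) * (1 - fx)
                                   + img[y0, x1] * (1 - fy) * fx
                                   + img[y1, x0] * fy * (1 - fx)
                                   + img[y1, x1] * fy * fx)
                mu = sum(samples) / P
                v = sum((s - mu) ** 2 for s in samples) / P
                assert het.variance_map[r - 1, c - 1] == pytest.approx(v, abs=1e-8)

    def test_homogeneity_bounds(self, rng):
        img = rng.integers(0, 256, (20, 20))
        het = heterogeneity_maps(img, P=8, R=1)
        assert np.all(het.variance_map >= 0)
        assert np.all(het.homogeneity_map <= 1.0)


class TestWeightedLbp:
    def test_constant_image_all_zero_vector(self):
        img = np.full((10, 10), 4)
        m = lbp_map(img, 8, 1, "riu2")
        het = heterogeneity_maps(img, 8, 1)
        hist = heterogeneity_weighted_lbp(m, het, mode="variance")
        assert hist.sum() == 0.0

    def test_uniform_weights_reduce_to_plain_histogram(self, rng):
        img = rng.integers(0, 256, (12, 12))
        m = lbp_map(img, 8, 1, "riu2")
        het = heterogeneity_maps(img, 8, 1)
        het.variance_map = np.full_like(het.variance_map, 3.7)
        got = heterogeneity_weighted_lbp(m, het, mode="variance")
        plain = np.bincount(m.codes.ravel(), minlength=10) / m.codes.size
        np.testing.assert_allclose(got, plain, atol=1e-12)

    @pytest.mark.parametrize("mode", ["variance", "dissimilarity"])
    def test_matches_per_pixel_accumulation(self, rng, mode):
        img = rng.integers(0, 256, (16, 16))
        m = lbp_map(img, 8, 1, "riu2")
        het = heterogeneity_maps(img, 8, 1)
        got = heterogeneity_weighted_lbp(m, het, mode=mode)
        w = het.variance_map if mode == "variance" else 1 - het.homogeneity_map
        acc = np.zeros(10)
        for r in range(m.codes.shape[0]):
            for c in range(m.codes.shape[1]):
                acc[m.codes[r, c]] += w[r, c]
        np.testing.assert_allclose(got, acc / acc.sum(), atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        img = rng.integers(0, 256, (12, 12))
        m = lbp_map(img, 8, 1, "riu2")
        het = heterogeneity_maps(img[:10, :10], 8, 1)
        with pytest.raises(ParameterError):
            heterogeneity_weighted_lbp(m, het)


class TestLbglcm:
    def test_constant_image_degenerate(self):
        f = lbglcm_features(np.full((12, 12), 5))
        assert f["contrast"] == 0 and f["energy"] == 1

    def test_equals_manual_chain(self, rng):
        img = rng.integers(0, 256, (16, 16))
        got = lbglcm_features(img, P=8, R=1, levels=64)
        codes = lbp_map(img, 8, 1, "basic").codes
        q = quantize_gray(codes, 64, bit_depth=8)
        per_dir = [glcm_features(m) for m in compute_glcm(q, 64)]
        for k in got:
            assert got[k] == pytest.approx(np.mean([f[k] for f in per_dir]))

    def test_blob_density_separates_classes(self, small_dataset):
        from gliomatex.preprocess import luminance
        labs = np.array(small_dataset.labels)
        contrast = np.array([
            lbglcm_features(luminance(im))["contrast"]
            for im in small_dataset.images])
        lo = contrast[labs == small_dataset.label_codebook[0]].mean()
        hi = contrast[labs == small_dataset.label_codebook[-1]].mean()
        assert lo != pytest.approx(hi, rel=1e-3)


class TestPyramid:
    def test_size_halving(self):
        levels = image_pyramid(np.zeros((512, 512), np.uint8), 3)
        assert [l.shape[0] for l in levels] == [512, 256, 128]

    def test_single_level_identity(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        (only,) = image_pyramid(img, 1)
        np.testing.assert_array_equal(only, img)

    def test_constant_preserved_at_all_levels(self):
        for lvl in image_pyramid(np.full((64, 64), 9, np.uint8), 3):
            assert np.all(lvl == 9)

    def test_too_many_levels_rejected(self):
        with pytest.raises(ParameterError):
            image_pyramid(np.zeros((32, 32), np.uint8), 3)


class TestMultiscaleLbglcm:
    def test_single_scale_reduces_to_lbglcm(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        got = multiscale_lbglcm(img, n_levels=1)
        want = lbglcm_features(img, levels=128)
        for k, v in want.items():
            assert got[f"l0.{k}"] == pytest.approx(v)

    def test_descriptor_length(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        assert len(multiscale_lbglcm(img, n_levels=2)) == 2 * 6

    def test_scale_consistency_with_downsampled_input(self, fixture_dataset):
        """Level-1 features of an image track level-0 features of its
        antialiased factor-2 downsample."""
        from skimage.transform import rescale

        from gliomatex.preprocess import luminance
        rs = []
        for img in fixture_dataset.images[:20]:
            g = luminance(img)
            full = multiscale_lbglcm(g, n_levels=2, glcm_levels=(64, 64))
            lvl1 = np.array([v for k, v in full.items() if k.startswith("l1.")])
            small = rescale(g.astype(float) / 255.0, 0.5, anti_aliasing=True)
            small8 = np.round(small * 255).astype(np.uint8)
            lvl0 = np.array(list(lbglcm_features(small8, levels=64).values()))
            r = np.corrcoef(lvl1, lvl0)[0, 1]
            rs.append(r)
        assert np.mean(rs) >= 0.95
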