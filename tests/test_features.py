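"""Descriptor blocks: LBP, GLCM/Haralick, FCH, fusion, deep embedding."""

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern

from endokit.errors import ContractError, ImageFormatError, ParameterError
from endokit.features import (
    GLCM_OFFSETS,
    FeatureVector,
    RandomProjectionExtractor,
    deep_extract,
    fch_bin_centers,
    fch_features,
    fuse,
    fuse_deep,
    glcm_features,
    glcm_table,
    haralick_features,
    lbp_codes,
    lbp_features,
    quantize,
)


class TestLBP:
    def test_default_length_is_203(self, random_gray):
        assert len(lbp_features(random_gray)) == 203

    def test_constant_roi_single_full_code_bin(self):
        fv = lbp_features(np.full((16, 16), 9.0))
        nz = np.flatnonzero(fv.values)
        assert nz.size == 1
        assert fv.values[nz[0]] == pytest.approx(1.0)
        # all-ones code 2^8−1 = 255 lands in the last bin
        assert nz[0] == 202

    def test_center_code_matches_bitwise_oracle(self, rng):
        """Per-bit threshold-and-weight enumeration with bilinear sampling."""
        img = rng.permutation(np.arange(9.0)).reshape(3, 3)

        def bilinear(r, c):
            r0, c0 = int(np.floor(r)), int(np.floor(c))
            fr, fc = r - r0, c - c0
            r1, c1 = min(r0 + 1, 2), min(c0 + 1, 2)
            return (
                img[r0, c0] * (1 - fr) * (1 - fc)
                + img[r0, c1] * (1 - fr) * fc
                + img[r1, c0] * fr * (1 - fc)
                + img[r1, c1] * fr * fc
            )

        expected = 0
        for p in range(8):
            ang = 2 * np.pi * p / 8
            dr, dc = -np.sin(ang), np.cos(ang)
            dr = round(dr) if abs(dr - round(dr)) < 1e-9 else dr
            dc = round(dc) if abs(dc - round(dc)) < 1e-9 else dc
            if bilinear(1 + dr, 1 + dc) - img[1, 1] >= 0:
                expected += 1 << p
        assert lbp_codes(img)[1, 1] == expected

    def test_codes_match_skimage_on_random_images(self, rng):
        for _ in range(20):
            img = rng.uniform(0, 255, (16, 16))
            ours = lbp_codes(img)
            ref = local_binary_pattern(img, P=8, R=1, method="default")
            np.testing.assert_array_equal(ours[1:-1, 1:-1], ref[1:-1, 1:-1])

    def test_histogram_sums_to_one(self, random_gray):
        assert lbp_features(random_gray).values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_roi_too_small(self):
        with pytest.raises(ImageFormatError):
            lbp_codes(np.zeros((2, 2)))

    def test_256_bin_exact_mode(self, random_gray):
        fv = lbp_features(random_gray, bins=256)
        assert len(fv) == 256


class TestGLCM:
    def test_length_is_13(self, random_gray):
        assert len(glcm_features(random_gray)) == 13

    def test_constant_roi_degenerate_values(self):
        fv = glcm_features(np.full((16, 16), 5.0))
        named = dict(zip(
            ["energy", "contrast", "correlation"], [fv.values[0], fv.values[1], fv.values[2]]
        ))
        assert named["energy"] == pytest.approx(1.0)
        assert named["contrast"] == pytest.approx(0.0)
        assert fv.values[8] == pytest.approx(0.0)  # entropy

    def test_checkerboard_counts_by_hand(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        table = glcm_table(board, (0, 1), n_levels=2)
        # 12 horizontal pairs, all (0,1) or (1,0); symmetric accumulation
        np.testing.assert_allclose(table, [[0.0, 0.5], [0.5, 0.0]])
        contrast = sum(
            table[i, j] * (i - j) ** 2 for i in range(2) for j in range(2)
        )
        assert contrast == pytest.approx(1.0)

    def test_tables_are_normalized_and_symmetric(self, rng):
        levels = rng.integers(0, 8, (12, 12))
        for off in GLCM_OFFSETS:
            t = glcm_table(levels, off, 8)
            assert t.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(t, t.T)

    def test_matches_skimage_oracle(self, rng):
        """Energy/contrast/correlation/IDM agree with graycomatrix+graycoprops."""
        # skimage pairs angle π/4 with the (−1,−1) step and 3π/4 with (−1,1);
        # under symmetric accumulation the four-offset set is identical.
        angle_of = {(0, 1): 0.0, (-1, -1): np.pi / 4, (-1, 0): np.pi / 2,
                    (-1, 1): 3 * np.pi / 4}
        for _ in range(20):
            levels = rng.integers(0, 8, (10, 10))
            for off, ang in angle_of.items():
                ours = glcm_table(levels, off, 8)
                ref = graycomatrix(
                    levels.astype(np.uint8), [1], [ang], levels=8,
                    symmetric=True, normed=True,
                )[:, :, 0, 0]
                np.testing.assert_allclose(ours, ref, atol=1e-12)
                feats = haralick_features(ours)
                assert feats[0] == pytest.approx(
                    float(graycoprops(ref[:, :, None, None], "ASM")[0, 0])
                )
                assert feats[1] == pytest.approx(
                    float(graycoprops(ref[:, :, None, None], "contrast")[0, 0])
                )
                assert feats[4] == pytest.approx(
                    float(graycoprops(ref[:, :, None, None], "homogeneity")[0, 0])
                )
                sk_corr = float(graycoprops(ref[:, :, None, None], "correlation")[0, 0])
                assert feats[2] == pytest.approx(sk_corr, abs=1e-9)

    def test_shift_invariance_in_exact_level_regime(self, rng):
        values = rng.permutation(np.repeat(np.arange(6.0), 20))[:100].reshape(10, 10)
        base = glcm_features(values, n_levels=6)
        shifted = glcm_features(values + 37.0, n_levels=6)
        np.testing.assert_allclose(base.values, shifted.values, atol=1e-12)

    def test_masked_pairs_only(self):
        levels = np.zeros((6, 6), np.intp)
        levels[:, 3:] = 1
        mask = np.zeros((6, 6), bool)
        mask[:, :3] = True  # only level-0 pixels visible
        t = glcm_table(levels, (0, 1), 2, mask=mask)
        np.testing.assert_allclose(t, [[1.0, 0.0], [0.0, 0.0]])


class TestFCH:
    def test_length_is_16(self, random_rgb):
        assert len(fch_features(random_rgb)) == 16

    def test_single_color_crisp_one_bin(self):
        roi = np.full((8, 8, 3), 0, np.uint8)
        roi[..., 0] = 200
        fv = fch_features(roi, mode="crisp")
        assert (fv.values == 1.0).sum() == 1
        assert fv.values.sum() == pytest.approx(1.0)

    def test_half_red_half_blue_crisp(self):
        roi = np.zeros((8, 8, 3), np.uint8)
        roi[:4, :, 0] = 255  # pure red rows
        roi[4:, :, 2] = 255  # pure blue rows
        fv = fch_features(roi, mode="crisp")
        nonzero = np.sort(fv.values[fv.values > 0])
        np.testing.assert_allclose(nonzero, [0.5, 0.5])

    def test_fuzzy_histogram_sums_to_one(self, random_rgb):
        fv = fch_features(random_rgb, mode="fuzzy")
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (fv.values > 0).all()  # fuzzy memberships spread everywhere

    def test_rejects_gray_input(self, random_gray):
        with pytest.raises(ImageFormatError):
            fch_features(random_gray)

    def test_lattice_has_16_distinct_centers(self):
        centers = fch_bin_centers()
        assert centers.shape == (16, 3)
        assert len({tuple(c) for c in centers}) == 16


class TestFusion:
    def test_published_block_widths(self, random_rgb, random_gray):
        lbp = lbp_features(random_gray)
        glcm = glcm_features(random_gray)
        fch = fch_features(random_rgb)
        fused = fuse([lbp, glcm, fch])
        assert (len(lbp), len(glcm), len(fch), len(fused)) == (203, 13, 16, 232)
        assert fused.blocks == ["lbp", "glcm", "fch"]

    def test_single_block_identity(self, random_gray):
        fv = glcm_features(random_gray)
        out = fuse([fv])
        np.testing.assert_array_equal(out.values, fv.values)

    def test_order_preserved_index_by_index(self, rng):
        a = FeatureVector(rng.normal(size=4), ["a"] * 4)
        b = FeatureVector(rng.normal(size=3), ["b"] * 3)
        fused = fuse([a, b])
        np.testing.assert_array_equal(fused.values[:4], a.values)
        np.testing.assert_array_equal(fused.values[4:], b.values)

    def test_associativity(self, rng):
        a = FeatureVector(rng.normal(size=5), ["a"] * 5)
        b = FeatureVector(rng.normal(size=2), ["b"] * 2)
        c = FeatureVector(rng.normal(size=3), ["c"] * 3)
        left = fuse([fuse([a, b]), c])
        right = fuse([a, fuse([b, c])])
        np.testing.assert_array_equal(left.values, right.values)
        assert left.block_labels == right.block_labels

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            fuse([])

    def test_deterministic_232_pipeline(self, random_rgb, random_gray):
        v1 = fuse([lbp_features(random_gray), glcm_features(random_gray),
                   fch_features(random_rgb)]).values
        v2 = fuse([lbp_features(random_gray), glcm_features(random_gray),
                   fch_features(random_rgb)]).values
        np.testing.assert_array_equal(v1, v2)


class TestDeepExtract:
    def test_default_width_4096(self, random_rgb):
        assert len(deep_extract(random_rgb)) == 4096

    def test_seed_determinism_and_image_sensitivity(self, rng):
        img1 = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        img2 = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        ex = RandomProjectionExtractor(width=64, seed=7)
        v1 = deep_extract(img1, ex).values
        v1b = deep_extract(img1, RandomProjectionExtractor(width=64, seed=7)).values
        v2 = deep_extract(img2, ex).values
        np.testing.assert_array_equal(v1, v1b)
        assert (v1 != v2).any()

    def test_width_contract_enforced(self, random_rgb):
        class Liar:
            width = 10

            def __call__(self, img):
                return np.zeros(7)

        with pytest.raises(ContractError):
            deep_extract(random_rgb, Liar())

    def test_fuse_deep_widths(self, random_rgb, random_gray):
        hand = fuse([lbp_features(random_gray), glcm_features(random_gray),
                     fch_features(random_rgb)])
        deep = deep_extract(random_rgb)
        hybrid = fuse_deep(deep, hand)
        assert len(hybrid) == 4328
        small = deep_extract(random_rgb, RandomProjectionExtractor(width=8))
        assert len(fuse_deep(small, hand)) == 240
        assert fuse_deep(small, hand).blocks == ["deep", "lbp", "glcm", "fch"]

    def test_fuse_deep_requires_full_handcrafted(self, random_rgb, random_gray):
        deep = deep_extract(random_rgb, RandomProjectionExtractor(width=8))
        partial = lbp_features(random_gray)
        with pytest.raises(ContractError):
            fuse_deep(deep, partial)


def test_quantize_spans_levels(rng):
    img = rng.uniform(10, 90, (12, 12))
    q = quantize(img, 32)
    assert q.min() == 0 and q.max() == 31
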