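"""Feature bank: texture code operators against literal oracles,
texton/shape/colour conventions, deep encoders and concatenation."""

import numpy as np
import pytest

from pulmoseg import featx
from pulmoseg.featx import (
    EPS, RING_OFFSETS, FeatureVector, SobelMaskSet, TextonDictionary,
    color_features, concat_features, deep_features, improved_lbp_code,
    improved_lbp_map, lgip_code, lgip_map, multi_texton_features,
    shape_features, texture_features, train_deep_encoders,
)


# ---------------------------------------------------------------------------
# literal oracles (independent loop implementations)
# ---------------------------------------------------------------------------

def ilbp_oracle_map(image):
    """Per-pixel improved-LBP codes via explicit loops on the padded
    image, following the gradient-context formula literally."""
    pad = np.pad(image, 2, mode="symmetric")
    h, w = image.shape
    out = np.zeros((h, w), dtype=int)
    for y in range(h):
        for x in range(w):
            gc = image[y, x]
            cy, cx = y + 2, x + 2
            ring = [pad[cy + dy, cx + dx] for dy, dx in RING_OFFSETS]
            code = 0
            for i, (dy, dx) in enumerate(RING_OFFSETS):
                p = ring[i]
                adj = ring[(i - 1) % 8] + ring[(i + 1) % 8]
                left = pad[cy + dy, cx + dx - 1]
                right = pad[cy + dy, cx + dx + 1]
                top = pad[cy + dy - 1, cx + dx]
                g = ((p * p - adj / max(abs(p), EPS))
                     * ((left + right) / max(top, EPS)))
                if g - gc >= 0:
                    code |= 1 << i
            out[y, x] = code
    return out


def lgip_oracle_map(image, masks):
    pad = np.pad(image, 1, mode="symmetric")
    h, w = image.shape
    out = np.zeros((h, w), dtype=int)
    for y in range(h):
        for x in range(w):
            patch = pad[y:y + 3, x:x + 3]
            code = 0
            for i, m in enumerate(masks.masks):
                if (m * patch).sum() > 0:
                    code |= 1 << i
            out[y, x] = code
    return out


# ---------------------------------------------------------------------------
# Sobel masks and LGIP
# ---------------------------------------------------------------------------

class TestSobelMasks:
    def test_all_masks_sum_to_zero_and_m4_antisymmetry(self):
        ms = SobelMaskSet()
        for m in ms.masks:
            assert abs(m.sum()) < 1e-12
        np.testing.assert_array_equal(ms.masks[4], -ms.masks[0])

    def test_m0_horizontal_m2_vertical(self):
        ms = SobelMaskSet()
        np.testing.assert_array_equal(
            ms.masks[0], [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]])
        np.testing.assert_array_equal(
            ms.masks[2], [[-1, -2, -1], [0, 0, 0], [1, 2, 1]])


class TestLGIP:
    def test_constant_patch_gives_code_zero(self):
        assert lgip_code(np.full((3, 3), 0.4)) == 0

    def test_vertical_step_edge_sets_horizontal_bit(self):
        patch = np.array([[0, 1, 1], [0, 1, 1], [0, 1, 1]], dtype=float)
        code = lgip_code(patch)
        assert code & 1          # M0 (horizontal gradient) responds
        assert not (code & 16)   # M4 = -M0 does not

    def test_rotation_permutes_responses_by_two_positions(self):
        ms = SobelMaskSet()
        rng = np.random.default_rng(7)
        for _ in range(20):
            patch = rng.random((3, 3))
            r = np.array([(m * patch).sum() for m in ms.masks])
            r_cw = np.array([(m * np.rot90(patch, k=-1)).sum()
                             for m in ms.masks])
            np.testing.assert_allclose(r_cw, np.roll(r, 2), atol=1e-12)

    def test_map_matches_loop_oracle_exactly(self):
        rng = np.random.default_rng(8)
        img = rng.integers(0, 256, (12, 12)).astype(float)
        np.testing.assert_array_equal(lgip_map(img),
                                      lgip_oracle_map(img, SobelMaskSet()))


class TestImprovedLBP:
    def test_zero_patch_threshold_at_tie_gives_ones(self):
        # every g_i = 0 = g_c: the threshold fires on >= 0, so all bits set
        assert improved_lbp_code(np.zeros((5, 5))) == 255

    def test_constant_patch_of_two_gives_255(self):
        # g_i = (4 - 4/2)·(4/2) = 4 ≥ g_c = 2 for every ring pixel
        assert improved_lbp_code(np.full((5, 5), 2.0)) == 255

    def test_codes_match_literal_oracle_on_random_patches(self):
        rng = np.random.default_rng(9)
        img = rng.integers(0, 256, (10, 11)).astype(float)
        np.testing.assert_array_equal(improved_lbp_map(img),
                                      ilbp_oracle_map(img))

    def test_code_of_interior_pixel_agrees_with_map(self):
        rng = np.random.default_rng(10)
        img = rng.random((9, 9))
        codes = improved_lbp_map(img)
        for y in range(2, 7):
            for x in range(2, 7):
                assert codes[y, x] == improved_lbp_code(
                    img[y - 2:y + 3, x - 2:x + 3])

    def test_code_rejects_wrong_patch_size(self):
        with pytest.raises(ValueError):
            improved_lbp_code(np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# textons
# ---------------------------------------------------------------------------

class TestMultiTexton:
    def test_constant_image_lands_in_uniform_bin(self):
        out = multi_texton_features(np.full((16, 16), 0.5))
        assert out[1] == 1.0  # all-zeros template after degenerate Otsu
        assert out.sum() == pytest.approx(1.0)

    def test_unit_checkerboard_is_all_diagonal(self):
        img = np.indices((16, 16)).sum(axis=0) % 2 == 0
        out = multi_texton_features(img.astype(float))
        assert out[4] + out[5] == pytest.approx(1.0)

    def test_matches_block_loop_oracle(self):
        rng = np.random.default_rng(11)
        img = (rng.random((20, 20)) > 0.5).astype(float)
        out = multi_texton_features(img)
        binary = img > 0.5  # Otsu on {0,1} image splits at interior point
        counts = np.zeros(7)
        for i in range(0, 20, 2):
            for j in range(0, 20, 2):
                counts[TextonDictionary.classify_block(
                    binary[i:i + 2, j:j + 2])] += 1
        np.testing.assert_allclose(out, counts / counts.sum(), atol=1e-12)


# ---------------------------------------------------------------------------
# shape and colour
# ---------------------------------------------------------------------------

class TestShapeFeatures:
    def test_square_circularity_is_pi_over_four(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True  # 20×20 square, perimeter 4n = 80
        area, per, circ, aspect, ecc, sol = shape_features(mask)
        assert area == 400
        assert per == pytest.approx(80.0)
        assert circ == pytest.approx(np.pi / 4)
        assert aspect == pytest.approx(1.0)
        assert sol == pytest.approx(1.0)

    def test_rasterised_circle_circularity(self):
        from skimage.draw import disk

        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = disk((30, 30), 20)
        mask[rr, cc] = True
        circ = shape_features(mask)[2]
        assert 0.85 <= circ <= 1.1

    def test_empty_mask_gives_zero_vector(self):
        np.testing.assert_array_equal(shape_features(np.zeros((8, 8))),
                                      np.zeros(6))

    def test_largest_component_is_used(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:4, 2:4] = True       # small distractor
        mask[10:25, 10:20] = True   # 15×10 rectangle
        area, _, _, aspect, _, _ = shape_features(mask)
        assert area == 150
        assert aspect == pytest.approx(1.5)


class TestColorFeatures:
    def test_constant_region_is_one_hot(self):
        img = np.full((8, 8), 0.5)
        h = color_features(img, np.ones((8, 8)))
        assert h.sum() == pytest.approx(1.0)
        assert (h > 0).sum() == 1

    def test_two_level_image_splits_half_and_half(self):
        img = np.full((8, 8), 0.2)
        img[:, 4:] = 0.8
        h = color_features(img, np.ones((8, 8)))
        nz = np.flatnonzero(h)
        assert len(nz) == 2
        np.testing.assert_allclose(h[nz], 0.5)

    def test_bins_validation_and_empty_mask(self):
        with pytest.raises(ValueError):
            color_features(np.zeros((4, 4)), np.ones((4, 4)), bins=1)
        np.testing.assert_array_equal(
            color_features(np.zeros((4, 4)), np.zeros((4, 4))), np.zeros(32))


# ---------------------------------------------------------------------------
# texture aggregation
# ---------------------------------------------------------------------------

class TestTextureFeatures:
    def test_constant_region_gives_lgip_one_hot_at_zero(self):
        img = np.full((16, 16), 0.6)
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:12, 4:12] = True
        tex = texture_features(img, mask)
        lgip_hist = tex[:256]
        assert lgip_hist[0] == pytest.approx(1.0)

    def test_histogram_blocks_are_distributions(self):
        rng = np.random.default_rng(12)
        img = rng.random((32, 32))
        mask = np.ones((32, 32), dtype=bool)
        tex = texture_features(img, mask)
        assert tex[:256].sum() == pytest.approx(1.0, abs=1e-9)
        assert tex[256:512].sum() == pytest.approx(1.0, abs=1e-9)
        assert tex[512:].sum() == pytest.approx(1.0, abs=1e-9)
        assert (tex >= 0).all()

    def test_full_mask_histogram_equals_pixel_loop_oracle(self):
        rng = np.random.default_rng(13)
        img = rng.random((32, 32))
        mask = np.ones((32, 32), dtype=bool)
        tex = texture_features(img, mask)
        codes = lgip_oracle_map(img, SobelMaskSet())
        hist = np.bincount(codes.ravel(), minlength=256) / codes.size
        np.testing.assert_allclose(tex[:256], hist, atol=1e-12)

    def test_empty_mask_gives_zero_convention(self):
        np.testing.assert_array_equal(
            texture_features(np.random.default_rng(1).random((8, 8)),
                             np.zeros((8, 8))),
            np.zeros(519))

    def test_invariant_to_background_border_outside_mask(self):
        rng = np.random.default_rng(14)
        img = rng.random((16, 16))
        mask = np.zeros((16, 16), dtype=bool)
        mask[5:11, 5:11] = True
        grown = np.pad(img, 4, constant_values=0.2)
        grown_mask = np.pad(mask, 4)
        np.testing.assert_allclose(texture_features(img * mask, mask),
                                   texture_features(grown * grown_mask,
                                                    grown_mask), atol=1e-12)
        np.testing.assert_allclose(shape_features(mask),
                                   shape_features(grown_mask), atol=1e-12)


# ---------------------------------------------------------------------------
# deep features and concatenation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_encoders(phantom_bank):
    from pulmoseg.itcnn import apply_mask

    masked = [apply_mask(s.image, s.mask) for s in phantom_bank]
    labels = np.array([s.label for s in phantom_bank])
    idx = np.random.default_rng(0).permutation(len(masked))
    tr = idx[:100]
    enc = train_deep_encoders([masked[i] for i in tr], labels[tr], 3,
                              epochs=5, seed=2)
    return enc, masked, labels, idx


def test_deep_features_deterministic_and_sized(trained_encoders):
    enc, masked, _, _ = trained_encoders
    a = deep_features(masked[0], enc)
    b = deep_features(masked[0], enc)
    np.testing.assert_array_equal(a, b)
    assert len(a) == enc.output_dim


def test_linear_probe_on_deep_features_beats_chance(trained_encoders):
    from sklearn.linear_model import LogisticRegression

    enc, masked, labels, idx = trained_encoders
    tr, te = idx[:100], idx[100:]
    feats = featx.deep_features_batch(np.stack(masked), enc)
    probe = LogisticRegression(max_iter=2000).fit(feats[tr], labels[tr])
    acc = probe.score(feats[te], labels[te])
    assert acc > 1 / 3 + 0.2


def test_full_feature_vector_linearly_separates_classes(trained_encoders,
                                                        phantom_bank):
    """F = [Tex, Sha, Col, De] feeds a linear classifier to >90%
    3-class accuracy on default phantoms (held-out)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    enc, masked, labels, idx = trained_encoders
    deep = featx.deep_features_batch(np.stack(masked), enc)
    rows = []
    for i, s in enumerate(phantom_bank):
        rows.append(np.concatenate([
            texture_features(masked[i], s.mask),
            shape_features(s.mask),
            color_features(s.image, s.mask),
            deep[i]]))
    F = np.stack(rows)
    tr, te = idx[:100], idx[100:]
    clf = make_pipeline(StandardScaler(),
                        LogisticRegression(max_iter=3000))
    clf.fit(F[tr], labels[tr])
    assert clf.score(F[te], labels[te]) > 0.90


class TestConcatFeatures:
    def test_total_length_and_round_trip(self):
        rng = np.random.default_rng(15)
        blocks = [rng.random(775), rng.random(6), rng.random(32),
                  rng.random(128)]
        fv = concat_features(*blocks)
        assert len(fv.vector) == 775 + 6 + 32 + 128
        for name, blk in zip(("tex", "sha", "col", "deep"), blocks):
            np.testing.assert_array_equal(fv.block(name), blk)

    def test_declared_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            concat_features(np.zeros(3), np.zeros(6), np.zeros(32),
                            np.zeros(128),
                            expected_lengths=(4, 6, 32, 128))

    def test_serialisation_is_reproducible(self):
        rng = np.random.default_rng(16)
        blocks = [rng.random(5), rng.random(6), rng.random(7), rng.random(8)]
        v1 = concat_features(*blocks).vector.tobytes()
        v2 = concat_features(*blocks).vector.tobytes()
        assert v1 == v2
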