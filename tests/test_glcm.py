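"""Co-occurrence counting against brute-force oracles and hand-derived statistics."""

import numpy as np
import pytest

from texhawk.glcm import (
    GLCMConfig,
    GLCMatrix,
    TextureStats,
    angle_to_offset,
    compute_glcm,
    extract_texture_vector,
    glcm_statistics,
    quantize_image,
    texture_feature_names,
)


def brute_force_glcm(image, levels, distance, angle_deg, symmetric):
    """Double-loop pair counter, independent of the vectorized implementation."""
    dr, dc = angle_to_offset(angle_deg, distance)
    h, w = image.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[image[r, c], image[r2, c2]] += 1
                if symmetric:
                    counts[image[r2, c2], image[r, c]] += 1
    return counts


class TestComputeGLCM:
    def test_two_row_image_horizontal_pairs(self):
        img = np.array([[0, 0], [1, 1]])
        cfg = GLCMConfig(levels=2, symmetric=False, normalize=True)
        g = compute_glcm(img, cfg, (1, 0))
        np.testing.assert_allclose(g.p, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_single_cell(self):
        img = np.full((8, 8), 3)
        cfg = GLCMConfig(levels=8)
        for angle in (0, 45, 90, 135):
            g = compute_glcm(img, cfg, (1, angle))
            assert g.p[3, 3] == pytest.approx(1.0)
            assert np.count_nonzero(g.p) == 1

    def test_symmetric_matrix_equals_transpose(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 6, (12, 12))
        g = compute_glcm(img, GLCMConfig(levels=6, symmetric=True), (1, 45))
        np.testing.assert_array_equal(g.p, g.p.T)

    @pytest.mark.parametrize("distance", [1, 2])
    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("symmetric", [False, True])
    def test_matches_brute_force_counts(self, distance, angle, symmetric):
        rng = np.random.default_rng(distance * 100 + angle)
        for _ in range(10):
            h, w = rng.integers(4, 17, 2)
            img = rng.integers(0, 5, (h, w))
            cfg = GLCMConfig(levels=5, symmetric=symmetric, normalize=False)
            got = compute_glcm(img, cfg, (distance, angle)).p
            want = brute_force_glcm(img, 5, distance, angle, symmetric)
            np.testing.assert_array_equal(got, want)

    def test_matches_skimage_under_symmetry(self):
        """Independent library cross-check, with the angle-mirroring that makes
        the two direction conventions agree for symmetric matrices."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(3)
        img = rng.integers(0, 8, (20, 20)).astype(np.uint8)
        mapping = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
        for angle_deg, sk_angle in mapping.items():
            ours = compute_glcm(img, GLCMConfig(levels=8, symmetric=True, normalize=False), (1, angle_deg)).p
            theirs = graycomatrix(img, [1], [sk_angle], levels=8, symmetric=True, normed=False)[:, :, 0, 0]
            np.testing.assert_array_equal(ours, theirs)

    def test_offset_exceeding_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            compute_glcm(np.zeros((3, 3), int), GLCMConfig(levels=2), (5, 0))

    def test_out_of_range_intensities_rejected(self):
        with pytest.raises(ValueError, match="quantize"):
            compute_glcm(np.array([[0, 9]]), GLCMConfig(levels=4), (1, 0))


class TestStatistics:
    def test_worked_diagonal_example(self):
        g = GLCMatrix(p=np.array([[0.5, 0.0], [0.0, 0.5]]), distance=1, angle_deg=0, normalized=True)
        s = glcm_statistics(g)
        assert s.energy == pytest.approx(0.5)
        assert s.contrast == pytest.approx(0.0)
        assert s.homogeneity == pytest.approx(1.0)

    def test_single_off_diagonal_cell(self):
        p = np.zeros((3, 3))
        p[1, 0] = 1.0  # |i-j| = 1
        s = glcm_statistics(GLCMatrix(p=p, distance=1, angle_deg=0, normalized=True))
        assert s.contrast == pytest.approx(1.0)
        assert s.homogeneity == pytest.approx(0.5)
        assert s.energy == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_uniform_matrix_energy(self, k):
        p = np.full((k, k), 1.0 / k**2)
        s = glcm_statistics(GLCMatrix(p=p, distance=1, angle_deg=0, normalized=True))
        assert s.energy == pytest.approx(1.0 / k**2)

    def test_unnormalized_input_rejected(self):
        g = GLCMatrix(p=np.array([[2.0, 0.0], [0.0, 2.0]]), distance=1, angle_deg=0, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            glcm_statistics(g)

    def test_statistic_bounds_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        cfg = GLCMConfig(levels=6)
        for _ in range(200):
            img = rng.integers(0, 6, (9, 9))
            for angle in (0, 90):
                s = glcm_statistics(compute_glcm(img, cfg, (1, angle)))
                assert 0 < s.energy <= 1
                assert 0 < s.homogeneity <= 1
                assert s.contrast >= 0
                assert s.entropy >= 0
                assert -1 - 1e-12 <= s.correlation <= 1 + 1e-12


class TestTextureVector:
    def test_default_config_yields_20_named_features(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 16, (16, 16))
        vec, names = extract_texture_vector(img, GLCMConfig(levels=16))
        assert len(vec) == 20
        assert len(names) == 20
        assert len(set(names)) == 20
        assert names == texture_feature_names(GLCMConfig(levels=16))

    def test_constant_image_energies_one_contrasts_zero(self):
        vec, names = extract_texture_vector(np.full((10, 10), 2), GLCMConfig(levels=8))
        by_name = dict(zip(names, vec))
        for name, value in by_name.items():
            if name.endswith("energy"):
                assert value == pytest.approx(1.0)
            if name.endswith("contrast"):
                assert value == pytest.approx(0.0)

    def test_rotation_swaps_horizontal_and_vertical_blocks(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 8, (16, 16))
        cfg = GLCMConfig(levels=8)
        vec, names = extract_texture_vector(img, cfg)
        vec_rot, _ = extract_texture_vector(np.rot90(img), cfg)
        by_name = dict(zip(names, vec))
        by_name_rot = dict(zip(names, vec_rot))
        for stat in ("energy", "contrast", "homogeneity"):
            assert by_name[f"glcm:d1_a0_{stat}"] == pytest.approx(by_name_rot[f"glcm:d1_a90_{stat}"])
            assert by_name[f"glcm:d1_a90_{stat}"] == pytest.approx(by_name_rot[f"glcm:d1_a0_{stat}"])


class TestQuantize:
    def test_downquantize_range(self):
        img = np.arange(256).reshape(16, 16)
        q = quantize_image(img, 8, source_levels=256)
        assert q.min() == 0 and q.max() == 7
        assert np.array_equal(np.unique(q), np.arange(8))

    def test_no_op_when_levels_suffice(self):
        img = np.array([[0, 3], [1, 2]])
        np.testing.assert_array_equal(quantize_image(img, 8), img)
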