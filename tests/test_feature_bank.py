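"""Feature bank: per-block oracle checks, dimension conformance, invariances."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.filters import gabor_kernel

from vstmap import feature_bank as fb
from vstmap.image import LesionImage, MaskError

from .conftest import make_disk_image


def two_level_disk(frac_high=0.5, lo=100, hi=120, radius=12):
    """Disk lesion whose pixels take two values in a given proportion."""
    img = make_disk_image(radius=radius)
    rr, cc = np.nonzero(img.primary_mask)
    n_hi = int(round(frac_high * rr.size))
    pixels = img.pixels.astype(np.int16).copy()
    pixels[img.primary_mask] = lo
    pixels[rr[:n_hi], cc[:n_hi]] = hi
    return LesionImage(pixels=pixels, primary_mask=img.primary_mask)


class TestIntensityBlock:
    def test_constant_lesion(self, disk_img):
        v = fb.extract_intensity_block(disk_img)
        assert v[0] == 100.0  # median
        assert v[1] == pytest.approx(0.0)  # entropy of a single value

    def test_balanced_two_valued_entropy_is_one_bit(self):
        # 20x20 square lesion: exactly 200 pixels at each of two values
        mask = np.zeros((96, 96), bool)
        mask[38:58, 38:58] = True
        pixels = np.full((96, 96), 50, np.int16)
        rr, cc = np.nonzero(mask)
        pixels[rr[:200], cc[:200]] = 100
        pixels[rr[200:], cc[200:]] = 120
        v = fb.extract_intensity_block(LesionImage(pixels, mask))
        assert v[1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_contrast_at_every_ring_scale(self, disk_img):
        v = fb.extract_intensity_block(disk_img)
        assert np.allclose(v[3:6], 50.0)

    def test_empty_mask_rejected(self, disk_img):
        bad = LesionImage(disk_img.pixels, np.zeros_like(disk_img.primary_mask))
        with pytest.raises(MaskError):
            fb.extract_intensity_block(bad)


class TestTextureBlock:
    def test_constant_patch_glcm(self, disk_img):
        v = fb.extract_texture_block(disk_img)
        contrast, correlation, energy = v[0:4], v[4:8], v[8:12]
        assert np.allclose(contrast, 0.0)
        assert np.allclose(energy, 1.0)

    def test_rle_against_run_enumeration_oracle(self, disk_img):
        cfg = fb.FeatureConfig()
        patch, mpatch = fb._masked_patch(disk_img)
        q = fb._quantize(patch, mpatch, cfg.rle_levels)
        # brute-force enumeration of horizontal runs
        runs = []
        for row in q:
            start = 0
            for i in range(1, len(row) + 1):
                if i == len(row) or row[i] != row[start]:
                    runs.append((int(row[start]), i - start))
                    start = i
        # constant patch: one maximal run per row
        assert len(runs) == q.shape[0]
        assert all(length == q.shape[1] for _, length in runs)
        n_runs = len(runs)
        sre = sum(1.0 / length**2 for _, length in runs) / n_runs
        lre = sum(float(length) ** 2 for _, length in runs) / n_runs
        rp = n_runs / q.size
        v = fb.extract_texture_block(disk_img)
        rle = v[-7:]
        assert rle[0] == pytest.approx(sre, rel=1e-12)
        assert rle[1] == pytest.approx(lre, rel=1e-12)
        assert rle[4] == pytest.approx(rp, rel=1e-12)

    def test_gabor_stripes_peak_in_tuned_channel(self):
        # vertical stripes of period 4 px -> frequency 0.25 cycles/px
        shape = (96, 96)
        cols = np.arange(shape[1])
        pix = (100 + 50 * np.sin(2 * np.pi * cols / 4.0))[None, :].repeat(shape[0], 0)
        mask = np.zeros(shape, bool)
        mask[30:62, 30:62] = True
        img = LesionImage(pix, mask)
        g = fb._gabor_features(*fb._masked_patch(img))
        means = g[0::2].reshape(len(fb.GABOR_FREQUENCIES), len(fb.GABOR_THETAS))
        got = np.unravel_index(np.argmax(means), means.shape)

        # oracle: direct filter-response computation with explicit kernels
        patch, mpatch = fb._masked_patch(img)
        oracle = np.zeros_like(means)
        for i, f in enumerate(fb.GABOR_FREQUENCIES):
            for j, t in enumerate(fb.GABOR_THETAS):
                k = gabor_kernel(f, theta=t)
                resp = np.abs(fftconvolve(patch, k, mode="same"))
                oracle[i, j] = resp[mpatch].mean()
        expected = np.unravel_index(np.argmax(oracle), oracle.shape)
        assert got == expected
        assert fb.GABOR_FREQUENCIES[got[0]] == pytest.approx(0.25)

    def test_small_bounding_box_rejected_naming_block(self):
        mask = np.zeros((96, 96), bool)
        mask[47:49, 40:50] = True  # 2 x 10 strip: 20 px but bbox < 8 rows
        img = LesionImage(np.where(mask, 100, 50).astype(np.int16), mask)
        with pytest.raises(fb.BlockError, match="texture"):
            fb.extract_texture_block(img)


class TestShapeBlock:
    def test_disk_is_round(self, disk_img):
        v = fb.extract_shape_block(disk_img)
        assert v[1] <= 0.1  # eccentricity
        assert v[19] <= 0.5  # radial-distance sd, px

    def test_rectangle_eccentricity_matches_moment_oracle(self):
        mask = np.zeros((96, 96), bool)
        mask[40:44, 20:60] = True  # 4 x 40
        img = LesionImage(np.where(mask, 100, 50).astype(np.int16), mask)
        v = fb.extract_shape_block(img)
        # oracle: eccentricity of the coordinate-covariance ellipse
        pts = np.argwhere(mask).astype(float)
        pts -= pts.mean(axis=0)
        eig = np.linalg.eigvalsh(pts.T @ pts / len(pts))
        expected = np.sqrt(1.0 - eig[0] / eig[1])
        assert v[1] == pytest.approx(expected, abs=1e-9)

    def test_disk_more_compact_than_star(self):
        disk = make_disk_image(radius=14)
        ang = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        radii = np.where(np.arange(16) % 2 == 0, 20.0, 7.0)
        rr, cc = draw_polygon(48 + radii * np.sin(ang), 48 + radii * np.cos(ang))
        star_mask = np.zeros((96, 96), bool)
        star_mask[rr, cc] = True
        star = LesionImage(np.where(star_mask, 100, 50).astype(np.int16), star_mask)
        assert fb.extract_shape_block(disk)[0] > fb.extract_shape_block(star)[0]

    def test_border_touching_mask_rejected(self):
        img = make_disk_image(radius=12, center=(6, 48))
        with pytest.raises(fb.BlockError, match="border"):
            fb.extract_shape_block(img)


class TestHistogramBlock:
    def test_constant_lesion_single_bin(self, disk_img):
        v = fb.extract_histogram_block(disk_img)
        bins = v[12:]
        assert np.count_nonzero(bins) == 1

    def test_bin_counts_conserve_pixel_count(self):
        img = two_level_disk(0.3, lo=-300, hi=900)  # outside the HU window too
        v = fb.extract_histogram_block(img)
        assert v[12:].sum() == img.primary_mask.sum()

    def test_flat_lesion_lbp_mass_in_flat_code(self, disk_img):
        v = fb.extract_histogram_block(disk_img)
        fractions = v[:10]
        # oracle: a constant neighbourhood yields the all-ones uniform
        # pattern, whose uniform-LBP code equals the number of set bits (8)
        flat_code = 8
        assert int(np.argmax(fractions)) == flat_code
        assert fractions[flat_code] > 0.5


class TestEdgeBlock:
    def test_blur_reduces_mean_sharpness(self, disk_img):
        sharp = fb.extract_edge_block(disk_img)[:60].mean()
        blurred_pixels = gaussian_filter(disk_img.pixels.astype(float), 2.0)
        blurred = LesionImage(blurred_pixels, disk_img.primary_mask)
        assert fb.extract_edge_block(blurred)[:60].mean() < sharp

    def test_symmetric_disk_has_uniform_sharpness(self):
        pixels = gaussian_filter(make_disk_image(radius=14).pixels.astype(float), 1.5)
        img = LesionImage(pixels, make_disk_image(radius=14).primary_mask)
        s = fb.extract_edge_block(img)[:60]
        assert s.std() / s.mean() < 0.12

    def test_ramp_profiles_match_directional_derivative(self):
        img0 = make_disk_image(radius=12)
        ramp = (10.0 * np.arange(96))[None, :].repeat(96, 0)
        img = LesionImage(ramp, img0.primary_mask)
        s = fb.extract_edge_block(img)[:60]
        _, normals = fb._contour_samples(img.primary_mask, 60)
        expected = 10.0 * np.abs(normals[:, 1])  # bilinear sampling is exact on a plane
        assert np.allclose(s, expected, atol=1e-9)

    def test_too_short_contour_rejected(self):
        mask = np.zeros((96, 96), bool)
        rr, cc = draw_disk((48, 48), 5)
        mask[rr, cc] = True
        img = LesionImage(np.where(mask, 100, 50).astype(np.int16), mask)
        with pytest.raises(fb.BlockError, match="contour"):
            fb.extract_edge_block(img)


class TestAssembly:
    def test_dimensions_495_and_496(self, disk_img):
        assert fb.assemble_feature_vector(disk_img).size == fb.N_TRADITIONAL
        assert fb.assemble_feature_vector(disk_img, similar_count=2).size == fb.N_FULL
        assert len(fb.feature_names(False)) == fb.N_TRADITIONAL
        assert len(fb.feature_names(True)) == fb.N_FULL

    def test_block_dims_match_table(self):
        sums = {}
        for d in fb.FEATURE_FAMILIES:
            sums[d.block] = sums.get(d.block, 0) + d.dim
        assert sums == fb.BLOCK_DIMS

    def test_assembly_equals_block_concatenation(self, disk_img):
        cfg = fb.FeatureConfig()
        parts = np.concatenate(
            [
                fb.extract_intensity_block(disk_img, cfg),
                fb.extract_texture_block(disk_img, cfg),
                fb.extract_shape_block(disk_img, cfg),
                fb.extract_histogram_block(disk_img, cfg),
                fb.extract_edge_block(disk_img, cfg),
            ]
        )
        assert np.array_equal(fb.assemble_feature_vector(disk_img, cfg=cfg), parts)

    def test_determinism(self, disk_img):
        a = fb.assemble_feature_vector(disk_img)
        b = fb.assemble_feature_vector(disk_img)
        assert np.array_equal(a, b)

    def test_translation_invariance(self):
        a = fb.assemble_feature_vector(make_disk_image(shape=(110, 110), center=(48, 48)))
        b = fb.assemble_feature_vector(make_disk_image(shape=(110, 110), center=(53, 55)))
        assert np.allclose(a, b, atol=1e-9)


class TestZScore:
    def test_population_sd_convention(self):
        fm = fb.FeatureMatrix(np.array([[1.0], [2.0], [3.0]]), ["a"], ["x", "y", "z"])
        out = fb.zscore_normalize(fm)
        assert np.allclose(out.values.ravel(), [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        mean, sd = out.norm_stats
        assert mean[0] == pytest.approx(2.0) and sd[0] == pytest.approx(np.sqrt(2 / 3))

    def test_constant_column_maps_to_zero(self):
        fm = fb.FeatureMatrix(np.full((4, 2), 7.0), ["a", "b"], list("wxyz"))
        assert np.allclose(fb.zscore_normalize(fm).values, 0.0)

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(0)
        fm = fb.FeatureMatrix(rng.normal(size=(20, 5)), list("abcde"), [str(i) for i in range(20)])
        once = fb.zscore_normalize(fm)
        twice = fb.zscore_normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-8)

    def test_single_sample_rejected(self):
        fm = fb.FeatureMatrix(np.ones((1, 3)), list("abc"), ["s"])
        with pytest.raises(ValueError):
            fb.zscore_normalize(fm)

    def test_apply_norm_stats_uses_training_statistics(self):
        rng = np.random.default_rng(1)
        fm = fb.zscore_normalize(
            fb.FeatureMatrix(rng.normal(size=(10, 3)), list("abc"), [str(i) for i in range(10)])
        )
        x = rng.normal(size=3)
        mean, sd = fm.norm_stats
        assert np.allclose(fb.apply_norm_stats(x, fm.norm_stats), (x - mean) / sd)
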