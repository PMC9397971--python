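"""Thickness, echogenicity, masked GLCM and homogeneity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.feature import graycomatrix, graycoprops

from mubkit.biomarkers import (
    GLCMSpec,
    average_triplicate,
    BiomarkerSet,
    echogenicity,
    extract_biomarkers,
    glcm,
    homogeneity,
    mean_thickness,
    quantize,
)
from mubkit.errors import InvalidParameterError, InvalidROIError
from mubkit.geometry import RegionOfInterest, rasterize_roi, trim_lateral_margins
from mubkit.synthetic import TendonImageParams, render_tendon_image
from mubkit.geometry import roi_from_ground_truth

from .conftest import make_image, rect_polygon

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(pixels, mask, levels, angle, distance=1, symmetric=True):
    """Pair-by-pair enumeration oracle for the masked GLCM."""
    q = (pixels.astype(int) * levels) // 256
    dr, dc = (o * distance for o in OFFSETS[angle])
    counts = np.zeros((levels, levels))
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def roi_from_mask(mask):
    lo = np.argwhere(mask)
    (r0, c0), (r1, c1) = lo.min(axis=0), lo.max(axis=0)
    return RegionOfInterest(polygon=np.array(rect_polygon(r0, r1, c0, c1), float),
                            mask=mask)


class TestMeanThickness:
    def test_rectangular_band(self):
        mask = np.zeros((200, 50), dtype=bool)
        mask[40:143, 10:40] = True  # 103 rows tall
        img = make_image(np.zeros((200, 50)), row_spacing_mm=0.05)
        assert mean_thickness(roi_from_mask(mask), img) == pytest.approx(5.15)

    def test_trapezoid_matches_per_column_count(self, rng):
        mask = np.zeros((150, 30), dtype=bool)
        extents = rng.integers(100, 111, size=30)
        for c, e in enumerate(extents):
            mask[10:10 + e, c] = True
        img = make_image(np.zeros((150, 30)), row_spacing_mm=0.05)
        expected = 0.05 * extents.mean()
        assert mean_thickness(roi_from_mask(mask), img) == pytest.approx(expected)

    def test_interior_holes_do_not_shrink_extent(self):
        mask = np.zeros((100, 20), dtype=bool)
        mask[20:60, 5:15] = True
        holey = mask.copy()
        holey[30:40, 5:15] = False  # internal hole
        img = make_image(np.zeros((100, 20)))
        assert mean_thickness(roi_from_mask(holey), img) == \
            mean_thickness(roi_from_mask(mask), img)
        # the area variant, by contrast, shrinks
        assert mean_thickness(roi_from_mask(holey), img, method="area") < \
            mean_thickness(roi_from_mask(mask), img, method="area")

    def test_intensity_invariance(self, rng):
        mask = np.zeros((60, 20), dtype=bool)
        mask[10:40, 2:18] = True
        roi = roi_from_mask(mask)
        a = make_image(rng.integers(0, 255, (60, 20)))
        b = make_image(np.full((60, 20), 200))
        assert mean_thickness(roi, a) == mean_thickness(roi, b)

    def test_empty_column_inside_band_errors(self):
        mask = np.zeros((50, 20), dtype=bool)
        mask[10:30, 5:9] = True
        mask[10:30, 10:15] = True  # column 9 empty inside the band
        img = make_image(np.zeros((50, 20)))
        with pytest.raises(InvalidROIError):
            mean_thickness(roi_from_mask(mask), img)


class TestEchogenicity:
    def test_constant_and_mixture(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        roi = roi_from_mask(mask)
        assert echogenicity(roi, make_image(np.full((20, 20), 77))) == 77.0
        px = np.full((20, 20), 60)
        px[10:15, 5:15] = 80  # half of the mask pixels
        assert echogenicity(roi, make_image(px)) == 70.0

    def test_matches_brute_force(self, rng):
        px = rng.integers(0, 256, (30, 30))
        mask = rng.random((30, 30)) < 0.4
        mask[15, 15] = True
        roi = RegionOfInterest(polygon=np.array(rect_polygon(0, 29, 0, 29), float),
                               mask=mask)
        total = sum(px[r, c] for r in range(30) for c in range(30) if mask[r, c])
        expected = total / mask.sum()
        assert echogenicity(roi, make_image(px)) == pytest.approx(expected)

    def test_vertical_translation_invariance_on_constant(self):
        img = make_image(np.full((60, 30), 123))
        m1 = np.zeros((60, 30), dtype=bool)
        m1[5:25, 5:25] = True
        m2 = np.roll(m1, 20, axis=0)
        assert echogenicity(roi_from_mask(m1), img) == \
            echogenicity(roi_from_mask(m2), img)


class TestGLCM:
    def test_constant_image_single_diagonal_cell(self):
        img = make_image(np.full((10, 10), 100))
        roi = roi_from_mask(np.ones((10, 10), dtype=bool))
        P = glcm(roi, img, GLCMSpec(levels=8), angle=0)
        level = quantize(np.array([100]), 8)[0]
        assert P.sum() == pytest.approx(1.0)
        assert P[level, level] == pytest.approx(1.0)
        assert homogeneity(P) == pytest.approx(1.0)

    def test_checkerboard_90_all_off_diagonal(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 255
        img = make_image(board)
        roi = roi_from_mask(np.ones((4, 4), dtype=bool))
        P = glcm(roi, img, GLCMSpec(levels=2), angle=90)
        assert P[0, 0] == P[1, 1] == 0.0
        assert P[0, 1] + P[1, 0] == pytest.approx(1.0)
        assert homogeneity(P) == pytest.approx(0.5)

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force_enumeration(self, rng, angle, symmetric):
        for _ in range(6):
            n = int(rng.integers(5, 17))
            px = rng.integers(0, 256, (n, n))
            mask = rng.random((n, n)) < 0.7
            mask[n // 2, n // 2] = True
            roi = RegionOfInterest(
                polygon=np.array(rect_polygon(0, n - 1, 0, n - 1), float),
                mask=mask)
            spec = GLCMSpec(levels=16, symmetric=symmetric)
            try:
                P = glcm(roi, make_image(px), spec, angle)
            except InvalidROIError:
                continue  # no admissible pair in this draw
            expected = brute_force_glcm(px, mask, 16, angle, symmetric=symmetric)
            np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_agrees_with_skimage_on_full_mask(self, rng):
        """Independent cross-check against the reference texture toolbox."""
        px = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        levels = 32
        roi = roi_from_mask(np.ones((20, 20), dtype=bool))
        img = make_image(px)
        q = quantize(px, levels).astype(np.uint8)
        # skimage angles are measured with the row axis pointing down, so
        # its pi/4 diagonal is our 135-degree one (equal under symmetry)
        angles_rad = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
        for angle, rad in angles_rad.items():
            P = glcm(roi, img, GLCMSpec(levels=levels), angle)
            ref = graycomatrix(q, [1], [rad], levels=levels, symmetric=True,
                               normed=True)[:, :, 0, 0]
            np.testing.assert_allclose(P, ref, atol=1e-12)
            assert homogeneity(P) == pytest.approx(
                graycoprops(ref[:, :, None, None], "homogeneity")[0, 0])

    def test_rotation_symmetry(self, rng):
        """Symmetric GLCM is invariant under a 180-degree image rotation."""
        px = rng.integers(0, 256, (12, 15))
        mask = rng.random((12, 15)) < 0.8
        roi = RegionOfInterest(polygon=np.array(rect_polygon(0, 11, 0, 14), float),
                               mask=mask)
        roi_rot = RegionOfInterest(polygon=roi.polygon, mask=mask[::-1, ::-1])
        for angle in (0, 45, 90, 135):
            P = glcm(roi, make_image(px), GLCMSpec(levels=8), angle)
            P_rot = glcm(roi_rot, make_image(px[::-1, ::-1]), GLCMSpec(levels=8),
                         angle)
            np.testing.assert_allclose(P, P_rot, atol=1e-12)

    def test_no_valid_pair_errors(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 3] = True
        roi = RegionOfInterest(polygon=np.array(rect_polygon(3, 3, 3, 3), float),
                               mask=mask)
        with pytest.raises(InvalidROIError):
            glcm(roi, make_image(np.zeros((10, 10))), GLCMSpec(), 0)


class TestHomogeneity:
    def test_identity_diagonal_is_one(self):
        P = np.eye(8) / 8
        assert homogeneity(P) == 1.0

    def test_unnormalized_errors(self):
        with pytest.raises(InvalidParameterError):
            homogeneity(np.eye(4))

    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((8, 8))
        P /= P.sum()
        expected = sum(P[i, j] / (1 + (i - j) ** 2)
                       for i in range(8) for j in range(8))
        assert homogeneity(P) == pytest.approx(expected, abs=1e-12)
        expected_abs = sum(P[i, j] / (1 + abs(i - j))
                           for i in range(8) for j in range(8))
        assert homogeneity(P, kernel="inverse_abs") == \
            pytest.approx(expected_abs, abs=1e-12)
        assert 0 < homogeneity(P) <= 1


class TestExtractBiomarkers:
    def _trimmed(self, image, boundaries):
        roi = rasterize_roi(roi_from_ground_truth(boundaries), image)
        return trim_lateral_margins(roi, image)

    def test_noise_free_longitudinal_recovery(self, flat_longitudinal):
        params, image, boundaries = flat_longitudinal
        b = extract_biomarkers(image, self._trimmed(image, boundaries))
        assert b.mean_thickness_mm == pytest.approx(params.thickness_mm,
                                                    abs=2 * image.row_spacing_mm)
        assert b.echogenicity == pytest.approx(params.mean_echo, abs=1.0)
        assert b.plane == "longitudinal"

    def test_isotropic_texture_angles_agree(self):
        # speckle only (no striation): transverse multidirectional mean
        # should agree with any single angle
        params = TendonImageParams(plane="transverse", fibril_contrast=0.0,
                                   speckle_scale=0.5, psf_mm=0.0)
        image, boundaries = render_tendon_image(params, 128, 128, rng_seed=3)
        roi = self._trimmed(image, boundaries)
        spec = GLCMSpec()
        hs = [homogeneity(glcm(roi, image, spec, a)) for a in spec.angles]
        b = extract_biomarkers(image, roi, spec)
        assert b.homogeneity == pytest.approx(np.mean(hs))
        for h in hs:
            assert abs(h - b.homogeneity) < 0.02

    def test_plane_mismatch_errors(self, flat_longitudinal):
        _, image, boundaries = flat_longitudinal
        roi = rasterize_roi(roi_from_ground_truth(boundaries), image)
        transverse_width = trim_lateral_margins(roi, image, target_width_mm=5.0)
        with pytest.raises(InvalidROIError):
            extract_biomarkers(image, transverse_width)


class TestAverageTriplicate:
    def _set(self, thickness, plane="longitudinal"):
        return BiomarkerSet(mean_thickness_mm=thickness, echogenicity=70.0,
                            homogeneity=0.6, plane=plane)

    def test_identical_sets_unchanged(self):
        avg = average_triplicate([self._set(5.0)] * 3)
        assert avg.mean_thickness_mm == 5.0
        assert avg.n_images_averaged == 3

    def test_fieldwise_mean(self):
        avg = average_triplicate([self._set(t) for t in (5.0, 5.2, 5.4)])
        assert avg.mean_thickness_mm == pytest.approx(5.2)

    def test_mixed_planes_error(self):
        with pytest.raises(InvalidParameterError):
            average_triplicate([self._set(5.0), self._set(5.0),
                                self._set(5.0, plane="transverse")])

    def test_two_images_warns(self):
        with pytest.warns(UserWarning):
            avg = average_triplicate([self._set(5.0), self._set(5.2)])
        assert avg.n_images_averaged == 2
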