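"""Compositing pipeline: warping, normalization, bias and illumination
invariances."""

import numpy as np
import pytest

from satb2phenomics import CohortSpec, build_target, make_cohort
from satb2phenomics.face_average import (
    average_constellation,
    compose_group,
    group_average,
    hull_mask,
    normalize_illumination,
    subject_average,
    warp_image,
)
from satb2phenomics.face_geometry import LandmarkConstellation
from satb2phenomics.image import FaceImage
from satb2phenomics.synthetic_data import sample_constellations


@pytest.fixture(scope="module")
def reference_target():
    return build_target(sample_constellations(100, CohortSpec(), seed=9))


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(asymmetry_mean=2.0, asymmetry_sd=1.0)
    return make_cohort(3, 2, spec, seed=5)


class TestAverageConstellation:
    def test_single_image_identity(self, symmetric_face):
        c = symmetric_face.constellation
        assert np.array_equal(average_constellation([c]), c.points)

    def test_per_subject_first_not_image_weighted(self, symmetric_face,
                                                  bumpy_face):
        """10 copies of subject A's constellation and 1 of subject B's give
        the A/B midpoint, not a 10:1 weighted mean."""
        a = symmetric_face.constellation.copy()
        a.subject_id = "A"
        b = bumpy_face.constellation.copy()
        b.subject_id = "B"
        cs = [a.copy() for _ in range(10)] + [b]
        for c in cs[:10]:
            c.subject_id = "A"
        result = average_constellation(cs)
        midpoint = (a.points + b.points) / 2
        weighted = (10 * a.points + b.points) / 11
        assert np.allclose(result, midpoint)
        assert not np.allclose(result, weighted)

    def test_mirror_pair_gives_symmetric_mean(self, roles, symmetric_face):
        pts = symmetric_face.constellation.points
        axis = float(pts[roles.midline, 0].mean())
        from satb2phenomics.face_geometry import mirror_points
        a = LandmarkConstellation(pts + [2.0, 0.0], "A")
        b = LandmarkConstellation(mirror_points(pts + [2.0, 0.0], roles, axis),
                                  "B")
        mean = average_constellation([a, b])
        mirrored_mean = mirror_points(mean, roles, axis)
        assert np.allclose(mean, mirrored_mean)


class TestWarpImage:
    def test_identity_warp(self, bumpy_face):
        warped = warp_image(bumpy_face, bumpy_face.constellation.points)
        mask = hull_mask(bumpy_face.constellation.points, bumpy_face.shape)
        assert np.abs(warped - bumpy_face.pixels)[mask].mean() < 1.0

    def test_translation_warp(self, bumpy_face):
        dst = bumpy_face.constellation.points + [7.0, 0.0]
        warped = warp_image(bumpy_face, dst)
        shifted = np.empty_like(bumpy_face.pixels)
        shifted[:, 7:] = bumpy_face.pixels[:, :-7]
        shifted[:, :7] = 0
        mask = hull_mask(dst, bumpy_face.shape)
        assert np.abs(warped - shifted)[mask].mean() < 1e-6

    def test_round_trip_error_small(self, symmetric_face, bumpy_face):
        """Warp to another mesh and back; smooth faces reconstruct within
        2 intensity units mean absolute error inside the hull."""
        fwd = warp_image(symmetric_face, bumpy_face.constellation.points)
        back = warp_image(FaceImage(fwd, bumpy_face.constellation),
                          symmetric_face.constellation.points)
        mask = hull_mask(symmetric_face.constellation.points,
                         symmetric_face.shape)
        assert np.abs(back - symmetric_face.pixels)[mask].mean() < 2.0

    def test_degenerate_destination_rejected(self, bumpy_face):
        dst = bumpy_face.constellation.points.copy()
        dst[:, 1] = 10.0  # collapse to a line: every triangle degenerate
        with pytest.raises(Exception):
            warp_image(bumpy_face, dst)

    def test_point_count_mismatch(self, bumpy_face):
        with pytest.raises(ValueError):
            warp_image(bumpy_face, bumpy_face.constellation.points[:10])


class TestNormalizeIllumination:
    def test_equal_means_unchanged(self):
        mask = np.ones((10, 10), dtype=bool)
        imgs = [np.full((10, 10), 50.0), np.full((10, 10), 50.0)]
        out, ref, clip = normalize_illumination(imgs, mask)
        assert ref == 50.0
        assert all(np.array_equal(o, i) for o, i in zip(out, imgs))

    def test_means_100_and_200_become_150(self):
        mask = np.ones((4, 4), dtype=bool)
        out, ref, _ = normalize_illumination(
            [np.full((4, 4), 100.0), np.full((4, 4), 200.0)], mask)
        assert ref == 150.0
        assert out[0][mask].mean() == pytest.approx(150.0)
        assert out[1][mask].mean() == pytest.approx(150.0)

    def test_single_image_unchanged(self):
        mask = np.ones((4, 4), dtype=bool)
        img = np.full((4, 4), 80.0)
        out, ref, _ = normalize_illumination([img], mask)
        assert np.array_equal(out[0], img)

    def test_zero_mean_rejected(self):
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            normalize_illumination([np.zeros((4, 4))], mask)


class TestAveraging:
    def test_subject_average_is_pixel_mean(self):
        a, b = np.full((5, 5), 10.0), np.full((5, 5), 20.0)
        assert np.all(subject_average([a, b]) == 15.0)
        assert np.array_equal(subject_average([a, a]), a)

    def test_subject_average_shape_mismatch(self):
        with pytest.raises(ValueError):
            subject_average([np.zeros((5, 5)), np.zeros((6, 6))])

    def test_group_average_of_constants(self, symmetric_face):
        pts = symmetric_face.constellation.points
        g = group_average([np.zeros((5, 5)), np.full((5, 5), 100.0)], pts)
        assert np.all(g.average_image == 50.0)
        assert g.n_subjects == 2

    def test_single_subject_group_equals_personal_average(self, symmetric_face):
        pts = symmetric_face.constellation.points
        personal = np.full((5, 5), 33.0)
        g = group_average([personal], pts)
        assert np.array_equal(g.average_image, personal)


class TestComposeGroup:
    def test_duplicate_image_invariance_exact(self, cohort, reference_target,
                                              roles):
        """Duplicating every image of one subject leaves the composite
        bit-equal up to floating point — the anti-bias design goal."""
        base = compose_group(cohort, reference_target, roles, "g")
        sid = cohort[0].constellation.subject_id
        dup = cohort + [f.copy() for f in cohort
                        if f.constellation.subject_id == sid]
        again = compose_group(dup, reference_target, roles, "g")
        assert np.allclose(base.average_image, again.average_image,
                           atol=1e-9)
        assert np.allclose(base.mean_points, again.mean_points)

    def test_illumination_invariance(self, cohort, reference_target, roles):
        """Scaling one input image by a constant does not change the
        composite's structure: after normalizing out the cohort brightness
        reference (itself defined as the average across faces), the
        composites agree up to clipping effects."""
        base = compose_group(cohort, reference_target, roles, "g")
        scaled = [f.copy() for f in cohort]
        scaled[0].pixels = np.clip(scaled[0].pixels * 0.8, 0, 255)
        again = compose_group(scaled, reference_target, roles, "g")
        mask = hull_mask(base.mean_points, base.average_image.shape)
        rel_base = base.average_image / base.normalization_reference
        rel_again = again.average_image / again.normalization_reference
        assert np.abs(rel_base - rel_again)[mask].mean() < 0.005

    def test_composite_mean_equals_reference(self, cohort, reference_target,
                                             roles):
        comp = compose_group(cohort, reference_target, roles, "g")
        mask = hull_mask(comp.mean_points, comp.average_image.shape)
        assert comp.average_image[mask].mean() == pytest.approx(
            comp.normalization_reference, abs=1e-6)

    def test_symmetric_cohort_composite_is_symmetric(self, reference_target,
                                                     roles):
        """A zero-asymmetry cohort composites to a left/right symmetric
        image inside the face hull."""
        spec = CohortSpec(asymmetry_mean=0.0, asymmetry_sd=0.0, noise_sd=0.0)
        faces = make_cohort(4, 1, spec, seed=21)
        comp = compose_group(faces, reference_target, roles, "sym")
        img = comp.average_image
        axis = float(comp.mean_points[roles.midline, 0].mean())
        h, w = img.shape
        xs = np.arange(w)
        mirror_x = np.clip(np.round(2 * axis - xs).astype(int), 0, w - 1)
        mask = hull_mask(comp.mean_points, img.shape)
        flipped = img[:, mirror_x]
        assert np.abs(img - flipped)[mask].mean() < 2.0
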