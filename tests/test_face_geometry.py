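"""Meshing, alignment, asymmetry and mirroring geometry checks."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from satb2phenomics import (
    CohortSpec,
    FaceParams,
    TargetMesh,
    asymmetry_score,
    build_mesh,
    build_target,
    fit_alignment,
    point_deviations,
)
from satb2phenomics.face_geometry import (
    LandmarkConstellation,
    RoleMap,
    SimilarityTransform,
    mirror_points,
    symmetrize_constellation,
    transform_constellation,
)
from satb2phenomics.image import apply_alignment, mirror_face
from satb2phenomics.synthetic_data import face_landmarks, sample_constellations


class TestBuildMesh:
    def test_triangle_counts_on_minimal_sets(self):
        assert len(build_mesh([[0, 0], [1, 0], [0, 1]]).triangles) == 1
        square = build_mesh([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert len(square.triangles) == 2

    def test_coincident_points_named(self):
        pts = [[0, 0], [1, 0], [0, 1], [1, 0]]
        with pytest.raises(ValueError, match="1 and 3"):
            build_mesh(pts)

    def test_collinear_set_rejected(self):
        pts = [[float(i), 0.0] for i in range(5)]
        with pytest.raises(ValueError):
            build_mesh(pts)

    @pytest.mark.parametrize("seed", range(8))
    def test_euler_identity_on_generated_constellations(self, seed):
        """Delaunay triangle count obeys 2n - 2 - h for every generated
        36-point constellation (h = brute-force hull vertex count)."""
        (c,) = sample_constellations(1, CohortSpec(offset_sd=3.0), seed=seed)
        mesh = build_mesh(c)
        h = len(ConvexHull(c.points).vertices)
        assert len(mesh.triangles) == 2 * 36 - 2 - h

    def test_normalized_triangle_ordering(self):
        mesh = build_mesh(face_landmarks(FaceParams()))
        tri = mesh.triangles
        assert np.all(tri[:, 0] < tri[:, 1]) and np.all(tri[:, 1] < tri[:, 2])
        assert np.array_equal(
            tri, tri[np.lexsort((tri[:, 2], tri[:, 1], tri[:, 0]))])


class TestBuildTarget:
    def test_single_constellation_identity(self, symmetric_face):
        t = build_target([symmetric_face.constellation])
        assert np.array_equal(t.mean_points, symmetric_face.constellation.points)
        assert t.n_reference == 1

    def test_symmetric_offsets_cancel(self, symmetric_face):
        base = symmetric_face.constellation.points
        plus = LandmarkConstellation(base + [3.0, 0.0])
        minus = LandmarkConstellation(base - [3.0, 0.0])
        t = build_target([plus, minus])
        assert np.allclose(t.mean_points, base)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_target([])


class TestFitAlignment:
    def test_identity(self, symmetric_face, roles):
        t = build_target([symmetric_face.constellation])
        tf = fit_alignment(symmetric_face.constellation, t, roles)
        assert tf.scale == pytest.approx(1.0, abs=1e-9)
        assert tf.rotation == pytest.approx(0.0, abs=1e-9)
        assert tf.translation == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_pure_shift(self, symmetric_face, roles):
        t = build_target([symmetric_face.constellation])
        shifted = LandmarkConstellation(
            symmetric_face.constellation.points + [5.0, -3.0])
        tf = fit_alignment(shifted, t, roles)
        assert tf.scale == pytest.approx(1.0, abs=1e-9)
        assert tf.rotation == pytest.approx(0.0, abs=1e-9)
        assert tf.translation[0] == pytest.approx(-5.0, abs=1e-9)
        assert tf.translation[1] == pytest.approx(3.0, abs=1e-9)

    def test_similarity_parameter_recovery(self, symmetric_face, roles):
        """A constructed 10-degree, 1.2x similarity is recovered to 1e-6."""
        c = symmetric_face.constellation
        t = build_target([c])
        true = SimilarityTransform(1.2, np.deg2rad(10.0), (4.0, -7.0))
        moved = transform_constellation(c, true.inverse())
        rec = fit_alignment(moved, t, roles)
        assert rec.scale == pytest.approx(1.2, abs=1e-6)
        assert rec.rotation == pytest.approx(np.deg2rad(10.0), abs=1e-6)
        inv = true.inverse()
        recovered = rec.apply(inv.apply(c.points))
        assert np.abs(recovered - c.points).max() < 1e-6

    def test_coincident_midline_unsolvable(self, roles):
        pts = face_landmarks(FaceParams())
        pts[roles.midline] = pts[roles.midline][0]
        t = build_target([face_landmarks(FaceParams())])
        with pytest.raises(ValueError, match="coincident"):
            fit_alignment(LandmarkConstellation(pts), t, roles)

    def test_apply_then_inverse_recovers_landmarks(self, symmetric_face):
        tf = SimilarityTransform(1.1, 0.3, (2.0, 5.0))
        fwd = apply_alignment(symmetric_face, tf)
        back = apply_alignment(fwd, tf.inverse())
        assert np.abs(back.constellation.points
                      - symmetric_face.constellation.points).max() < 1e-9


class TestDeviationsAndAsymmetry:
    def test_zero_deviations_at_target(self, symmetric_face):
        t = build_target([symmetric_face.constellation])
        assert np.all(point_deviations(symmetric_face.constellation, t) == 0)

    def test_three_four_five(self, symmetric_face):
        t = build_target([symmetric_face.constellation])
        pts = symmetric_face.constellation.points.copy()
        pts[10] += [3.0, 4.0]
        devs = point_deviations(LandmarkConstellation(pts), t)
        assert devs[10] == pytest.approx(5.0)
        assert np.count_nonzero(devs) == 1

    def test_random_deviations_match_brute_force(self, symmetric_face):
        rng = np.random.default_rng(4)
        t = build_target([symmetric_face.constellation])
        pts = symmetric_face.constellation.points + rng.normal(0, 2, (36, 2))
        devs = point_deviations(LandmarkConstellation(pts), t)
        brute = [np.hypot(*(pts[i] - t.mean_points[i])) for i in range(36)]
        assert np.allclose(devs, brute)

    def test_score_formula(self, roles):
        devs = np.zeros(36)
        devs[roles.left_indices[0]] = 2.0
        devs[roles.right_indices[0]] = 1.0
        assert asymmetry_score(devs, roles).score == pytest.approx(1 / 3)

    def test_all_zero_deviations_guarded(self, roles):
        report = asymmetry_score(np.zeros(36), roles)
        assert report.score == 0.0

    def test_antisymmetric_under_role_swap(self, roles):
        rng = np.random.default_rng(5)
        devs = rng.uniform(0, 3, 36)
        swapped = RoleMap(roles.midline,
                          [(r, l) for l, r in roles.pairs], roles.names)
        assert asymmetry_score(devs, swapped).score == pytest.approx(
            -asymmetry_score(devs, roles).score)

    def test_symmetric_render_scores_zero(self, symmetric_face, roles):
        """Perfectly symmetric noiseless render has exactly zero asymmetry
        against its own symmetrized constellation."""
        pts = symmetric_face.constellation.points
        sym = symmetrize_constellation(pts, roles)
        devs = point_deviations(pts, TargetMesh(sym, 1))
        assert asymmetry_score(devs, roles).score == 0.0


class TestMirror:
    def test_involution_on_landmarks_and_raster(self, bumpy_face, roles):
        axis = float(bumpy_face.constellation.points[roles.midline, 0].mean())
        once = mirror_face(bumpy_face, roles, axis)
        twice = mirror_face(once, roles, axis)
        assert np.abs(twice.constellation.points
                      - bumpy_face.constellation.points).max() < 1e-9
        # integer-pixel reflection axes resample exactly; allow interpolation
        assert np.abs(twice.pixels - bumpy_face.pixels).mean() < 1.0

    def test_symmetric_face_invariant_as_set(self, symmetric_face, roles):
        pts = symmetric_face.constellation.points
        axis = float(pts[roles.midline, 0].mean())
        mirrored = mirror_points(pts, roles, axis)
        assert np.abs(mirrored - pts).max() < 1e-9

    def test_shifted_corner_flips_score_sign(self, roles):
        pts = face_landmarks(FaceParams())
        target = TargetMesh(pts.copy(), 1)
        moved = pts.copy()
        moved[16, 0] -= 4.0  # left mouth corner pushed leftward
        axis = float(moved[roles.midline, 0].mean())
        before = asymmetry_score(point_deviations(moved, target), roles)
        mirrored = mirror_points(moved, roles, axis)
        after = asymmetry_score(point_deviations(mirrored, target), roles)
        assert before.score > 0
        assert after.score == pytest.approx(-before.score, rel=1e-6)
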