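"""Group-average face construction.

Pipeline order: align each face to the population target (similarity over
midline points), mirror so the more deviant side is canonical (right),
compute the group's mean constellation (per-subject means first, then an
unweighted mean over subjects), piecewise-affine warp every image onto that
mean mesh, normalize in-hull illumination to the grand mean, average each
subject's images, then average the personal averages.  The per-subject-first
ordering makes the composite exactly invariant to duplicating any subject's
images, which is the point of the design: no individual with many photographs
can dominate the composite.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import ConvexHull, Delaunay
from skimage.draw import polygon2mask

from .face_geometry import (
    FaceMesh,
    LandmarkConstellation,
    RoleMap,
    TargetMesh,
    asymmetry_score,
    build_mesh,
    fit_alignment,
    point_deviations,
)
from .image import FaceImage, apply_alignment, border_fill_value, mirror_face

BACKGROUND_FILL = 128.0  # neutral gray outside the face hull


@dataclass
class GroupAverage:
    group_label: str
    mean_points: np.ndarray
    mesh: FaceMesh
    average_image: np.ndarray
    n_subjects: int
    n_images: int
    normalization_reference: float


# ---------------------------------------------------------------------------


def average_constellation(cs: list[LandmarkConstellation]) -> np.ndarray:
    """Mean constellation: per-subject mean first, then unweighted mean over
    subjects (mirrors the image-compositing order)."""
    if not cs:
        raise ValueError("empty group")
    by_subject: dict[str, list[np.ndarray]] = defaultdict(list)
    for c in cs:
        by_subject[c.subject_id].append(c.points)
    subject_means = [np.mean(np.stack(pts), axis=0)
                     for pts in by_subject.values()]
    return np.mean(np.stack(subject_means), axis=0)


def _triangle_areas(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a, b, c = (points[triangles[:, i]] for i in range(3))
    u, v = b - a, c - a
    return 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])


def warp_image(img: FaceImage, dst_points: np.ndarray,
               out_shape: tuple[int, int] | None = None,
               fill: float | None = None) -> np.ndarray:
    """Piecewise-affine warp of a face onto a destination constellation.

    For each output pixel inside the destination hull, the containing
    destination triangle's barycentric coordinates are applied to the
    corresponding source triangle (the per-triangle affine map), and the
    source is sampled bilinearly.  Pixels outside the hull get the fill
    value.
    """
    src_points = img.constellation.points
    dst_points = np.asarray(dst_points, dtype=float)
    if src_points.shape != dst_points.shape:
        raise ValueError("source and destination point counts differ")
    tri = Delaunay(dst_points)
    areas = _triangle_areas(dst_points, tri.simplices)
    if np.any(areas <= 1e-12):
        bad = tri.simplices[int(np.argmin(areas))]
        raise ValueError(f"degenerate destination triangle {tuple(bad)}")
    if out_shape is None:
        out_shape = img.pixels.shape[:2]
    if fill is None:
        fill = BACKGROUND_FILL
    h, w = out_shape
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    simplex = tri.find_simplex(pix)
    inside = simplex >= 0
    # barycentric coordinates of each inside pixel in its destination triangle
    trans = tri.transform[simplex[inside]]
    bary2 = np.einsum("ijk,ik->ij", trans[:, :2, :],
                      pix[inside] - trans[:, 2, :])
    bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
    verts = tri.simplices[simplex[inside]]
    src_xy = np.einsum("ij,ijk->ik", bary, src_points[verts])

    def sample(channel: np.ndarray) -> np.ndarray:
        out = np.full(h * w, float(fill))
        out[inside] = map_coordinates(channel,
                                      [src_xy[:, 1], src_xy[:, 0]],
                                      order=1, mode="constant", cval=fill)
        return out.reshape(h, w)

    if img.pixels.ndim == 2:
        return sample(img.pixels)
    return np.stack([sample(img.pixels[..., c])
                     for c in range(img.pixels.shape[2])], axis=-1)


def hull_mask(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the convex hull of a constellation."""
    hull = ConvexHull(points)
    poly_xy = points[hull.vertices]
    return polygon2mask(shape, np.column_stack([poly_xy[:, 1], poly_xy[:, 0]]))


def normalize_illumination(rasters: list[np.ndarray], mask: np.ndarray,
                           reference: float | None = None
                           ) -> tuple[list[np.ndarray], float, list[float]]:
    """Rescale each raster so its in-hull mean equals the reference value
    (by default the grand mean of in-hull means); returns (normalized
    rasters, reference value, per-image clip fractions)."""
    if not rasters:
        raise ValueError("no images to normalize")
    if not mask.any():
        raise ValueError("empty face hull")
    means = []
    for r in rasters:
        m = float(r[mask].mean())
        if m == 0:
            raise ValueError("in-hull mean of zero; cannot normalize")
        means.append(m)
    ref = float(np.mean(means)) if reference is None else float(reference)
    normalized, clip_fractions = [], []
    for r, m in zip(rasters, means):
        scaled = r * (ref / m)
        clipped = np.clip(scaled, 0.0, 255.0)
        clip_fractions.append(float(np.mean(clipped != scaled)))
        normalized.append(clipped)
    return normalized, ref, clip_fractions


def subject_average(warped: list[np.ndarray]) -> np.ndarray:
    """Pixel-wise mean of one subject's warped images."""
    if not warped:
        raise ValueError("no images for subject")
    shapes = {w.shape for w in warped}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch among subject images: {shapes}")
    return np.mean(np.stack(warped), axis=0)


def group_average(subject_avgs: list[np.ndarray], mean_points: np.ndarray,
                  group_label: str = "", n_images: int = 0,
                  normalization_reference: float = float("nan")
                  ) -> GroupAverage:
    """Pixel-wise mean of the personal averages — the final composite."""
    if not subject_avgs:
        raise ValueError("empty group")
    avg = np.mean(np.stack(subject_avgs), axis=0)
    return GroupAverage(
        group_label=group_label,
        mean_points=np.asarray(mean_points, dtype=float),
        mesh=build_mesh(mean_points),
        average_image=avg,
        n_subjects=len(subject_avgs),
        n_images=n_images,
        normalization_reference=normalization_reference,
    )


# ---------------------------------------------------------------------------
# end-to-end composite


def canonicalize_side(face: FaceImage, target: TargetMesh, roles: RoleMap
                      ) -> tuple[FaceImage, bool]:
    """Mirror a face if its left side deviates more from the target than its
    right, so the greater-deviance side is canonical (right).  Ties (score
    exactly 0) are not mirrored."""
    devs = point_deviations(face.constellation, target)
    report = asymmetry_score(devs, roles)
    if report.score > 0:
        axis_x = float(face.constellation.points[roles.midline, 0].mean())
        return mirror_face(face, roles, axis_x), True
    return face, False


def compose_group(faces: list[FaceImage], target: TargetMesh, roles: RoleMap,
                  group_label: str = "", normalize: bool = True
                  ) -> GroupAverage:
    """Full averaging pipeline for one group of faces.

    align -> mirror (canonical deviance side) -> group mean constellation ->
    warp -> illumination-normalize -> subject mean -> group mean.
    """
    if not faces:
        raise ValueError("empty group")
    processed = []
    for face in faces:
        tf = fit_alignment(face.constellation, target, roles)
        aligned = apply_alignment(face, tf)
        canonical, _ = canonicalize_side(aligned, target, roles)
        processed.append(canonical)
    mean_points = average_constellation([f.constellation for f in processed])
    warped = [warp_image(f, mean_points) for f in processed]
    shape = warped[0].shape[:2]
    ref = float("nan")
    if normalize:
        mask = hull_mask(mean_points, shape)
        # subject-weighted reference: grand mean over subjects of each
        # subject's mean in-hull brightness, so duplicating a subject's
        # images cannot move the reference (exact composite invariance)
        per_subject_means: dict[str, list[float]] = defaultdict(list)
        for f, w in zip(processed, warped):
            per_subject_means[f.constellation.subject_id].append(
                float(w[mask].mean()))
        ref = float(np.mean([np.mean(v) for v in per_subject_means.values()]))
        warped, ref, _ = normalize_illumination(warped, mask, reference=ref)
    by_subject: dict[str, list[np.ndarray]] = defaultdict(list)
    for f, w in zip(processed, warped):
        by_subject[f.constellation.subject_id].append(w)
    subject_avgs = [subject_average(ws) for ws in by_subject.values()]
    return group_average(subject_avgs, mean_points, group_label,
                         n_images=len(faces), normalization_reference=ref)
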