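"""Landmark constellations, face meshes, alignment, asymmetry scoring, mirroring.

A face is represented by an ordered constellation of 36 anatomical feature
points (8 midline points from forehead to chin plus 14 left/right pairs; see
``data/role_map.json``).  This module provides the geometric machinery of the
averaging pipeline: Delaunay meshing of a constellation, construction of a
population target mesh, least-squares similarity alignment of a face to that
target using the midline points, per-point deviation and left/right asymmetry
scoring, and mirroring so that each face's more deviant side ends up on a
canonical side (the right).

Coordinates follow the image convention: origin top-left, x rightward,
y downward, continuous 0-based values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay
from skimage import transform as sktransform

N_POINTS = 36
_EPS = 1e-12


# ---------------------------------------------------------------------------
# types


@dataclass
class LandmarkConstellation:
    """Ordered 36-point landmark set for one face image."""

    points: np.ndarray  # (36, 2) float, columns (x, y)
    subject_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_POINTS, 2):
            raise ValueError(
                f"constellation must have exactly {N_POINTS} (x, y) points, "
                f"got shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("constellation contains non-finite coordinates")

    def copy(self) -> "LandmarkConstellation":
        return LandmarkConstellation(self.points.copy(), self.subject_id, self.image_id)


@dataclass
class RoleMap:
    """Midline/pair semantics of the 36-point scheme.

    ``pairs`` lists ``(left_index, right_index)`` tuples where *left* is the
    smaller-x side of the image.  Midline and pair indices must partition
    0..35 with no repeats.
    """

    midline: list[int]
    pairs: list[tuple[int, int]]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = [tuple(p) for p in self.pairs]
        flat = list(self.midline) + [i for p in self.pairs for i in p]
        if sorted(flat) != list(range(N_POINTS)):
            raise ValueError("midline and pair indices must partition 0..35")

    @property
    def left_indices(self) -> list[int]:
        return [l for l, _ in self.pairs]

    @property
    def right_indices(self) -> list[int]:
        return [r for _, r in self.pairs]

    def swap_permutation(self) -> np.ndarray:
        """Index permutation exchanging each left landmark with its right mate."""
        perm = np.arange(N_POINTS)
        for l, r in self.pairs:
            perm[l], perm[r] = r, l
        return perm


@dataclass
class FaceMesh:
    points: np.ndarray  # (n, 2)
    triangles: np.ndarray  # (m, 3) int, each row ascending, rows lexicographic


@dataclass
class TargetMesh:
    """Coordinate-wise mean constellation over a reference population."""

    mean_points: np.ndarray  # (36, 2)
    n_reference: int
    mesh: FaceMesh | None = None


@dataclass
class SimilarityTransform:
    """Orientation-preserving similarity: x' = s·R(theta)·x + t."""

    scale: float
    rotation: float  # radians
    translation: tuple[float, float]
    residual: float = 0.0  # RMS residual of the fit over the midline points

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        m = np.eye(3)
        m[:2, :2] = self.scale * np.array([[c, -s], [s, c]])
        m[:2, 2] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        r_inv = inv_scale * np.array([[c, -s], [s, c]])
        t = -r_inv @ np.asarray(self.translation)
        return SimilarityTransform(inv_scale, -self.rotation, (t[0], t[1]))


@dataclass
class AsymmetryReport:
    per_point_deviation: np.ndarray  # (36,) nonnegative distances
    left_total: float
    right_total: float
    score: float  # (L - R) / max(L + R, eps), in [-1, 1]
    mirrored: bool = False


# ---------------------------------------------------------------------------
# role map loading


def load_role_map() -> RoleMap:
    """Load the packaged canonical 36-point role map."""
    raw = json.loads(
        resources.files("satb2phenomics.data").joinpath("role_map.json").read_text()
    )
    return RoleMap(midline=raw["midline"], pairs=raw["pairs"], names=raw["names"])


def load_template() -> np.ndarray:
    """Template constellation of the canonical layout (200x200 frame)."""
    raw = json.loads(
        resources.files("satb2phenomics.data").joinpath("role_map.json").read_text()
    )
    return np.asarray(raw["template"], dtype=float)


# ---------------------------------------------------------------------------
# meshing


def _as_points(c) -> np.ndarray:
    pts = c.points if isinstance(c, LandmarkConstellation) else np.asarray(c, float)
    return pts


def build_mesh(c) -> FaceMesh:
    """Delaunay-triangulate a constellation (or raw point array).

    Triangles are normalized for reproducibility: vertex indices ascending
    within each triangle, triangles sorted lexicographically.
    """
    pts = _as_points(c)
    if len(pts) < 3:
        raise ValueError("need at least 3 points to triangulate")
    # coincident points make the triangulation ill-defined; report which
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(len(pts), k=1)
    dup = np.argwhere(d2[iu] < _EPS)
    if len(dup):
        i, j = iu[0][dup[0][0]], iu[1][dup[0][0]]
        raise ValueError(f"coincident landmark points: indices {i} and {j}")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # all-collinear degenerate set
        raise ValueError(f"degenerate point set, cannot triangulate: {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("degenerate point set: all points collinear")
    triangles = np.sort(tri.simplices, axis=1)
    order = np.lexsort((triangles[:, 2], triangles[:, 1], triangles[:, 0]))
    return FaceMesh(points=pts.copy(), triangles=triangles[order])


def build_target(cs: Sequence) -> TargetMesh:
    """Coordinate-wise mean of constellations; the averaging target."""
    if len(cs) == 0:
        raise ValueError("cannot build a target mesh from zero constellations")
    stack = np.stack([_as_points(c) for c in cs])
    mean_points = stack.mean(axis=0)
    return TargetMesh(mean_points=mean_points, n_reference=len(cs),
                      mesh=build_mesh(mean_points))


# ---------------------------------------------------------------------------
# alignment


def fit_alignment(c, t: TargetMesh, roles: RoleMap) -> SimilarityTransform:
    """Least-squares orientation-preserving similarity from a face's midline
    points onto the target's midline points (Umeyama estimate).

    Only the midline points (forehead to chin) drive the fit; they are
    near-collinear but still determine scale, rotation and translation.
    """
    src = _as_points(c)[roles.midline]
    dst = t.mean_points[roles.midline]
    if len(src) < 2:
        raise ValueError("need at least 2 midline points")
    if np.max(np.ptp(src, axis=0)) < _EPS:
        raise ValueError("all midline points coincident; alignment unsolvable")
    tf = sktransform.estimate_transform("similarity", src, dst)
    m = np.asarray(tf.params)
    scale = float(np.sqrt(np.linalg.det(m[:2, :2])))
    rotation = float(np.arctan2(m[1, 0], m[0, 0]))
    out = SimilarityTransform(scale, rotation, (float(m[0, 2]), float(m[1, 2])))
    resid = out.apply(src) - dst
    out.residual = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return out


def transform_constellation(c: LandmarkConstellation, tf: SimilarityTransform
                            ) -> LandmarkConstellation:
    return LandmarkConstellation(tf.apply(c.points), c.subject_id, c.image_id)


# ---------------------------------------------------------------------------
# deviation and asymmetry


def point_deviations(aligned, t: TargetMesh) -> np.ndarray:
    """Per-point Euclidean distances between an aligned constellation and
    the target mesh."""
    pts = _as_points(aligned)
    if pts.shape != t.mean_points.shape:
        raise ValueError("constellation/target point count mismatch")
    return np.linalg.norm(pts - t.mean_points, axis=1)


def asymmetry_score(devs: np.ndarray, roles: RoleMap,
                    mirrored: bool = False) -> AsymmetryReport:
    """Signed left/right asymmetry from per-point deviations.

    score = (L - R) / max(L + R, eps) where L and R are the summed deviations
    over the left- and right-side pair indices; bounded in [-1, 1], positive
    when the left side deviates more.
    """
    devs = np.asarray(devs, dtype=float)
    if devs.shape != (N_POINTS,):
        raise ValueError(f"expected {N_POINTS} deviations, got {devs.shape}")
    left_total = float(devs[roles.left_indices].sum())
    right_total = float(devs[roles.right_indices].sum())
    total = left_total + right_total
    # totals at floating-point dust level are symmetric by construction
    score = 0.0 if total < _EPS else (left_total - right_total) / total
    return AsymmetryReport(devs, left_total, right_total, score, mirrored)


def symmetrize_constellation(points: np.ndarray, roles: RoleMap,
                             axis_x: float | None = None) -> np.ndarray:
    """Bilaterally symmetric version of a constellation.

    Midline points are projected onto the axis; each left/right pair is
    replaced by the mirror-symmetric average of the two members.  The axis
    defaults to the mean x of the midline points.
    """
    pts = np.asarray(points, dtype=float).copy()
    if axis_x is None:
        axis_x = float(pts[roles.midline, 0].mean())
    pts[roles.midline, 0] = axis_x
    for l, r in roles.pairs:
        xl, yl = pts[l]
        xr, yr = pts[r]
        half = ((axis_x - xl) + (xr - axis_x)) / 2.0
        y = (yl + yr) / 2.0
        pts[l] = (axis_x - half, y)
        pts[r] = (axis_x + half, y)
    return pts


def mirror_points(points: np.ndarray, roles: RoleMap, axis_x: float) -> np.ndarray:
    """Reflect landmark x about the vertical line x = axis_x and swap the
    left/right indices so point semantics are preserved."""
    pts = np.asarray(points, dtype=float).copy()
    pts[:, 0] = 2.0 * axis_x - pts[:, 0]
    return pts[roles.swap_permutation()]
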