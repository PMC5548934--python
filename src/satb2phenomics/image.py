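"""Face image container and raster-level alignment/mirroring.

Rasters are float arrays in [0, 255], grayscale ``(H, W)`` or RGB
``(H, W, 3)``.  All resampling is bilinear; pixels that fall outside the
source image are filled with the median of the source's border pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from .face_geometry import (
    LandmarkConstellation,
    RoleMap,
    SimilarityTransform,
    mirror_points,
)


@dataclass
class FaceImage:
    pixels: np.ndarray  # (H, W) or (H, W, 3) float in [0, 255]
    constellation: LandmarkConstellation

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be (H, W) or (H, W, C)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def copy(self) -> "FaceImage":
        return FaceImage(self.pixels.copy(), self.constellation.copy())


def border_fill_value(pixels: np.ndarray) -> float:
    """Median of the image border pixels, used as background fill."""
    border = np.concatenate([
        pixels[0].ravel(), pixels[-1].ravel(),
        pixels[:, 0].ravel(), pixels[:, -1].ravel(),
    ])
    return float(np.median(border))


def _warp_raster(pixels: np.ndarray, inverse_matrix: np.ndarray,
                 fill: float) -> np.ndarray:
    # skimage transforms operate on (x, y) = (col, row), matching landmarks
    tf = sktransform.ProjectiveTransform(matrix=inverse_matrix)
    return sktransform.warp(pixels, tf, order=1, cval=fill,
                            preserve_range=True, mode="constant")


def apply_alignment(face: FaceImage, tf: SimilarityTransform) -> FaceImage:
    """Apply a similarity transform to a face: landmarks exactly, raster by
    bilinear resampling (output pixel sampled at the inverse-mapped source
    location)."""
    fill = border_fill_value(face.pixels)
    warped = _warp_raster(face.pixels, tf.inverse().matrix, fill)
    c = face.constellation
    return FaceImage(warped, LandmarkConstellation(tf.apply(c.points),
                                                   c.subject_id, c.image_id))


def mirror_face(face: FaceImage, roles: RoleMap, axis_x: float) -> FaceImage:
    """Flip a face about the vertical line x = axis_x.

    The raster is resampled bilinearly; landmark x-coordinates are reflected
    exactly and left/right indices swapped so each index keeps its semantics.
    """
    fill = border_fill_value(face.pixels)
    # reflection is its own inverse
    m = np.array([[-1.0, 0.0, 2.0 * axis_x], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    flipped = _warp_raster(face.pixels, m, fill)
    c = face.constellation
    new_pts = mirror_points(c.points, roles, axis_x)
    return FaceImage(flipped, LandmarkConstellation(new_pts, c.subject_id, c.image_id))
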