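"""Rasterize a posture into a binary worm silhouette.

From the 24 inter-segment angles and the fixed segment-length table the 26
midline points are computed; combined with the fixed table of 26
cross-sectional widths they define a filled 2-D polygonal model of the worm
made of 50 quadrilaterals plus 2 triangles (the width vanishes at head and
tail tips). The polygon is filled with a scan-line rasterizer.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import polygon as _fill_polygon

from .core import WormImage
from .geometry import WIDTH_PROFILE_MM, points_from_angles


def _outline_from_midline(points: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Closed polygon outline: midline offset by ±width/2 along local normals."""
    tang = np.gradient(points, axis=0)
    norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    norm /= np.linalg.norm(norm, axis=1, keepdims=True)
    left = points + 0.5 * widths[:, None] * norm
    right = points - 0.5 * widths[:, None] * norm
    return np.concatenate([left, right[::-1]], axis=0)


def render_worm(
    angles: np.ndarray,
    scale: float = 0.0129,
    orientation: float = 0.0,
    centroid: tuple[float, float] | None = None,
    image_shape: tuple[int, int] | None = None,
    timestamp: float = 0.0,
) -> WormImage:
    """Render the filled worm silhouette for one posture frame.

    Parameters
    ----------
    angles
        24 finite inter-segment angles (rad).
    scale
        mm per pixel; must be positive.
    orientation
        Heading of the first (head) segment, rad.
    centroid
        Worm centroid in mm, in image coordinates (x = column·scale,
        y = row·scale). If None the worm is centered in the image.
    image_shape
        (rows, cols); sized automatically with a margin if omitted.
    """
    if scale <= 0:
        raise ValueError("scale must be positive (mm/pixel)")
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (24,) or not np.all(np.isfinite(angles)):
        raise ValueError("expected 24 finite angles")

    mid = points_from_angles(angles, orientation=orientation, centroid=(0.0, 0.0))
    outline = _outline_from_midline(mid, WIDTH_PROFILE_MM)

    if image_shape is None:
        span = outline.max(axis=0) - outline.min(axis=0)
        margin_px = 8
        cols = int(np.ceil(span[0] / scale)) + 2 * margin_px
        rows = int(np.ceil(span[1] / scale)) + 2 * margin_px
        image_shape = (rows, cols)
    if centroid is None:
        centroid = (image_shape[1] * scale / 2.0, image_shape[0] * scale / 2.0)

    outline = outline + np.asarray(centroid)
    cc = outline[:, 0] / scale
    rr = outline[:, 1] / scale
    img = np.zeros(image_shape, dtype=bool)
    fr, fc = _fill_polygon(rr, cc, shape=image_shape)
    img[fr, fc] = True
    return WormImage(img, scale=scale, timestamp=timestamp)
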