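"""Midline geometry shared by the renderer and the skeleton analysis.

A worm posture is represented by 24 signed inter-segment angles (head to
tail).  Together with 25 fixed end-to-end segment lengths this defines 26
ordered midline points; a fixed table of 26 cross-sectional widths turns the
midline into a filled 2-D silhouette.  The length and width tables are scaled
to a 1 mm adult animal; widths taper smoothly, widest near 40% body length,
and vanish at both tips so the head- and tail-most pieces of the polygonal
model are triangles.
"""

from __future__ import annotations

import numpy as np

N_POINTS = 26
N_SEGMENTS = 25
N_ANGLES = 24

#: Total midline length of the model worm, mm.
BODY_LENGTH_MM = 1.0

#: 25 equal end-to-end segment lengths (mm).
SEGMENT_LENGTHS_MM = np.full(N_SEGMENTS, BODY_LENGTH_MM / N_SEGMENTS)


def _width_profile() -> np.ndarray:
    # Smooth taper, widest at 40% body length, zero exactly at both tips so
    # the end pieces of the polygonal model are triangles. The exponents are
    # small so head and tail stay blunt enough to survive rasterization at
    # typical camera resolutions (~0.013 mm/px).
    s = np.linspace(0.0, 1.0, N_POINTS)
    # beta-like bump with mode at 0.4: s^a (1-s)^b with a/(a+b) = 0.4
    a, b = 0.45, 0.675
    w = s**a * (1.0 - s) ** b
    w /= w.max()
    return 0.08 * w  # max width 0.08 mm for a 1 mm worm


#: 26 cross-sectional widths head -> tail (mm).
WIDTH_PROFILE_MM = _width_profile()


def points_from_angles(
    angles: np.ndarray,
    scale: float = 1.0,
    orientation: float = 0.0,
    centroid: tuple[float, float] = (0.0, 0.0),
    segment_lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Build the 26 ordered midline points from 24 inter-segment angles.

    The first segment points along ``orientation``; each subsequent segment
    heading is the previous heading plus the corresponding signed angle.
    ``scale`` multiplies the segment-length table (use it to change body
    length), and the point cloud is translated so its centroid (mean of the
    26 points) lands on ``centroid``.

    Returns an array of shape (26, 2), units of the segment-length table.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (N_ANGLES,):
        raise ValueError(f"expected {N_ANGLES} angles, got shape {angles.shape}")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    seg = SEGMENT_LENGTHS_MM if segment_lengths is None else np.asarray(segment_lengths)
    headings = orientation + np.concatenate([[0.0], np.cumsum(angles)])
    steps = scale * seg[:, None] * np.stack([np.cos(headings), np.sin(headings)], axis=1)
    pts = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)], axis=0)
    pts += np.asarray(centroid, dtype=float) - pts.mean(axis=0)
    return pts


def angles_from_points(points: np.ndarray) -> np.ndarray:
    """Signed turn angles between consecutive segments of an ordered polyline.

    For 26 points (25 segments) this yields the 24 inter-segment angles.
    Positive sign follows the right-hand convention of the point coordinates;
    the dorsoventral meaning of the sign is fixed only once a head assignment
    and recording-level convention exist.
    """
    points = np.asarray(points, dtype=float)
    vec = np.diff(points, axis=0)
    cross = vec[:-1, 0] * vec[1:, 1] - vec[:-1, 1] * vec[1:, 0]
    dot = (vec[:-1] * vec[1:]).sum(axis=1)
    return np.arctan2(cross, dot)


def arc_resample(points: np.ndarray, n: int = N_POINTS) -> np.ndarray:
    """Resample an ordered polyline to ``n`` points equally spaced in arc length."""
    points = np.asarray(points, dtype=float)
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] <= 0:
        raise ValueError("degenerate polyline")
    t = np.linspace(0.0, s[-1], n)
    x = np.interp(t, s, points[:, 0])
    y = np.interp(t, s, points[:, 1])
    return np.stack([x, y], axis=1)


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def eccentricity(points: np.ndarray) -> float:
    """Eccentricity of a 2-D point cloud from its second moments.

    1 for a collinear cloud, towards 0 for an isotropic (coiled) one.
    """
    pts = np.asarray(points, dtype=float)
    c = pts - pts.mean(axis=0)
    cov = c.T @ c / len(pts)
    ev = np.linalg.eigvalsh(cov)
    if ev[1] <= 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - ev[0] / ev[1])))
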