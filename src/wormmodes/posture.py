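"""Binary worm images → ordered 26-point skeletons → 24 inter-segment angles.

The midline is obtained by morphological skeletonization of the cleaned
binary silhouette, reduced to a single path by branch trimming on the
skeleton-pixel graph, smoothed with a spline, and resampled to 26 points
equally spaced in arc length. Self-touching (coiled) shapes — typical of
deep omega bends — cannot be skeletonized into a simple path and are marked
invalid rather than guessed at. The pointy tail tip is handled implicitly
by the resampling of the trimmed midline; no separate tail clipping exists.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage import morphology

from .core import PostureFrame, PostureSeries, Skeleton, Track, WormImage
from .geometry import (
    N_POINTS,
    angles_from_points,
    arc_resample,
    polyline_length,
)

#: Frames whose skeleton is shorter than this fraction of the running-median
#: skeleton length are treated as segmentation failures.
SHORT_SKELETON_FRACTION = 0.6


def clean_binarize(
    raw_image: np.ndarray,
    threshold: float | None = None,
    dilate_px: int = 1,
    erode_px: int = 1,
    min_size_px: int = 30,
    scale: float = 0.0129,
    timestamp: float = 0.0,
) -> WormImage:
    """Threshold and morphologically clean a raw frame.

    Grayscale input is thresholded at ``threshold`` (required unless the
    input is already boolean); the mask is closed (dilation then erosion),
    small specks removed and holes filled. The result must contain exactly
    one connected foreground component, else the frame is marked invalid.
    """
    raw = np.asarray(raw_image)
    if raw.size == 0:
        raise ValueError("empty image")
    if raw.dtype == bool:
        mask = raw.copy()
    else:
        if threshold is None:
            raise ValueError("threshold required for grayscale input")
        mask = raw > threshold
    if dilate_px > 0:
        mask = morphology.dilation(mask, morphology.disk(dilate_px))
    if erode_px > 0:
        mask = morphology.erosion(mask, morphology.disk(erode_px))
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=min_size_px - 1)
    n_comp = ndimage.label(mask)[1]
    img = WormImage(mask, scale=scale, timestamp=timestamp)
    img.valid = n_comp == 1
    return img


def _skeleton_graph(skel_px: np.ndarray) -> nx.Graph:
    """8-connected graph over skeleton pixels, edges weighted by distance."""
    g = nx.Graph()
    rows, cols = np.nonzero(skel_px)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pix:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                nb = (r + dr, c + dc)
                if nb in pix:
                    g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def _longest_endpoint_path(g: nx.Graph) -> list[tuple[int, int]] | None:
    """Longest weighted shortest-path between degree-1 nodes (branch trimming)."""
    ends = [n for n in g.nodes if g.degree(n) == 1]
    if len(ends) < 2:
        return None
    best, best_len = None, -1.0
    # distances from each endpoint; graphs are tiny (worm-midline sized)
    for i, a in enumerate(ends):
        dist, paths = nx.single_source_dijkstra(g, a)
        for b in ends[i + 1:]:
            if b in dist and dist[b] > best_len:
                best_len = dist[b]
                best = paths[b]
    return best


#: Savitzky-Golay smoothing passes applied to the traced midline:
#: (window in mm of arc length, polynomial order). Two passes — a broad one
#: to suppress medial-axis jitter, a narrow one after re-parametrisation.
MIDLINE_SMOOTHING = ((0.12, 2), (0.06, 2))


def extract_skeleton(
    image: WormImage,
    smoothing: tuple[tuple[float, int], ...] = MIDLINE_SMOOTHING,
    min_path_px: int = 10,
    n_dense: int = 400,
) -> Skeleton:
    """Trace the midline of a cleaned worm image.

    Skeletonizes the silhouette, trims branches by keeping the longest
    endpoint-to-endpoint path on the skeleton graph, smooths the ordered
    pixel path with Savitzky-Golay passes whose windows are fixed in
    physical units (mm of arc length), and resamples to 26 points equally
    spaced in arc length, in mm coordinates (x = column·scale,
    y = row·scale).

    Coiled shapes whose skeleton contains a cycle — the head touching the
    tail during deep omega bends — are returned invalid.
    """
    if not image.valid:
        return Skeleton(None, valid=False)
    skel_px = morphology.skeletonize(image.pixels)
    if skel_px.sum() < min_path_px:
        return Skeleton(None, valid=False)
    g = _skeleton_graph(skel_px)
    # a cycle means the midline branches are irreducible (coiled posture)
    if len(g.edges) >= len(g.nodes):
        return Skeleton(None, valid=False)
    path = _longest_endpoint_path(g)
    if path is None or len(path) < min_path_px:
        return Skeleton(None, valid=False)
    # (row, col) -> (x, y) in mm
    pts = np.array([(c * image.scale, r * image.scale) for r, c in path])
    mid = arc_resample(pts, n_dense)
    length = polyline_length(mid)
    if length <= 0:
        return Skeleton(None, valid=False)
    for window_mm, polyorder in smoothing:
        w = int(round(window_mm / (length / n_dense))) | 1
        if w >= polyorder + 2:
            mid[:, 0] = savgol_filter(mid[:, 0], w, polyorder, mode="interp")
            mid[:, 1] = savgol_filter(mid[:, 1], w, polyorder, mode="interp")
            mid = arc_resample(mid, n_dense)
    return Skeleton(arc_resample(mid, N_POINTS), valid=True)


def orient_head(
    skeletons: list[Skeleton],
    centroid_track: Track,
    omega_flags: np.ndarray | None = None,
) -> list[Skeleton]:
    """Assign a consistent head end across a skeleton sequence.

    The head is initialised as the endpoint leading in the direction of
    centroid movement at the start of the track, then propagated frame to
    frame by endpoint proximity (the head can only move a limited distance
    between adjacent frames). During flagged omega frames, when head and tail
    are close, the proximity rule is suspended and the movement-direction
    rule is used instead.
    """
    n = len(skeletons)
    if omega_flags is None:
        omega_flags = np.zeros(n, dtype=bool)
    valid_idx = [i for i, s in enumerate(skeletons) if s.valid]
    if len(valid_idx) < 2:
        warnings.warn("fewer than 2 valid skeletons; head orientation skipped")
        return [Skeleton(None, valid=False) for _ in skeletons]

    c = centroid_track.centroid

    def movement_dir(i: int) -> np.ndarray:
        w = max(1, int(round(centroid_track.frame_rate)))  # ~1 s window
        j0, j1 = max(0, i - w), min(len(c) - 1, i + w)
        d = c[j1] - c[j0]
        nrm = np.linalg.norm(d)
        return d / nrm if nrm > 0 else np.array([1.0, 0.0])

    def leading_end_first(sk: Skeleton, i: int) -> bool:
        """True if point 0 is the leading endpoint along the movement direction."""
        d = movement_dir(i)
        return float((sk.points[0] - sk.points[-1]) @ d) >= 0.0

    out: list[Skeleton] = []
    prev_head: np.ndarray | None = None
    for i, sk in enumerate(skeletons):
        if not sk.valid:
            out.append(Skeleton(None, valid=False))
            continue
        pts = sk.points
        if prev_head is None or omega_flags[i]:
            head_first = leading_end_first(sk, i)
        else:
            d0 = np.linalg.norm(pts[0] - prev_head)
            d1 = np.linalg.norm(pts[-1] - prev_head)
            head_first = d0 <= d1
        if not head_first:
            pts = pts[::-1].copy()
        prev_head = pts[0]
        out.append(Skeleton(pts, valid=True))
    return out


def angles_from_skeleton(skeleton: Skeleton) -> PostureFrame:
    """24 signed inter-segment angles of an oriented skeleton (head → tail).

    Positive sign means a bend toward the side defined as dorsal at head
    assignment; the dorsoventral identity of that side is arbitrary per
    recording, so downstream statistics use absolute values or are
    sign-symmetric.
    """
    if not skeleton.valid:
        return PostureFrame(np.full(24, np.nan), valid=False)
    return PostureFrame(angles_from_points(skeleton.points), valid=True)


def extract_posture_series(
    images: list[WormImage],
    frame_rate: float,
    smoothing: tuple[tuple[float, int], ...] = MIDLINE_SMOOTHING,
) -> tuple[PostureSeries, list[Skeleton]]:
    """Full image-stack → posture pipeline for one animal.

    Applies the running-median short-skeleton rule (frames shorter than 60%
    of the running median length are invalidated), orients heads from the
    centroid track, and returns the angle series plus the oriented skeletons.
    """
    skeletons = [extract_skeleton(im, smoothing=smoothing) for im in images]
    lengths = np.array([polyline_length(s.points) if s.valid else np.nan
                        for s in skeletons])
    med = np.nanmedian(lengths) if np.isfinite(lengths).any() else np.nan
    for i, s in enumerate(skeletons):
        if s.valid and np.isfinite(med) and lengths[i] < SHORT_SKELETON_FRACTION * med:
            skeletons[i] = Skeleton(None, valid=False)
    centroids = np.array([
        np.argwhere(im.pixels).mean(axis=0)[::-1] * im.scale if im.pixels.any()
        else (np.nan, np.nan)
        for im in images
    ])
    track = Track(np.nan_to_num(centroids), frame_rate=frame_rate)
    oriented = orient_head(skeletons, track)
    frames = [angles_from_skeleton(s) for s in oriented]
    angles = np.stack([f.angles for f in frames])
    valid = np.array([f.valid for f in frames])
    return PostureSeries(angles, frame_rate=frame_rate, valid=valid), oriented
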