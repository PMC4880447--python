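"""Centroid-track metrics and behavioral-state detection.

Speed, track curvature and displacement follow the conventions of multi-worm
tracking: symmetric-difference speed over a ~1 s window on the smoothed
trajectory, heading from the four-quadrant inverse tangent of the
displacement over the same window, and curvature as absolute heading change
per distance crawled. Reversals are detected primarily from the sign of the
undulation phase velocity (the wave direction defines the crawl direction),
with a centroid angular-velocity heuristic as fallback; omega turns from
silhouette eccentricity plus angular speed; pauses from a speed threshold
with gap tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import FORWARD, INVALID, OMEGA, PAUSE, REVERSE, StateLabels, Track
from .eigenmodes import ModeDecomposition, _moving_average
from .geometry import eccentricity, points_from_angles

#: Centroid speeds above this are tracking artifacts and masked (mm/s).
SPEED_ARTIFACT_MM_S = 0.6

#: Below this speed, centroid wobble dominates and curvature is masked (mm/s).
CURVATURE_SPEED_FLOOR_MM_S = 0.03

#: Curvature values above this are removed as artifacts (rad/mm).
CURVATURE_CEILING_RAD_MM = 31.0

#: Pause definition: below this speed for at least MIN_PAUSE_S, tolerating
#: gaps up to PAUSE_GAP_S.
PAUSE_SPEED_MM_S = 0.05
MIN_PAUSE_S = 2.0
PAUSE_GAP_S = 1.0

#: Omega-turn detector defaults, calibrated on synthetic injected events:
#: only full-circle curls push the midline point-cloud eccentricity below
#: ~0.6, and the body axis swings faster than 2.5 rad/s while the posture
#: morphs through the curl.
OMEGA_ECC_MAX = 0.6
OMEGA_ANGSPEED_MIN = 2.5   # rad/s
OMEGA_MIN_DUR_S = 0.3
OMEGA_COWINDOW_S = 0.7

#: Minimum sustained negative-phase-velocity duration to call a reversal,
#: and the velocity the wave must reverse beyond (cycles/s) — phase noise
#: during pauses stays well above this.
REVERSAL_MIN_DUR_S = 0.3
REVERSAL_PV_THRESHOLD = -0.1

MIN_TRACK_DURATION_S = 20.0


@dataclass
class EventList:
    """Detected events as (onset_s, duration_s) pairs plus binned rates."""

    onsets: np.ndarray       # s
    durations: np.ndarray    # s
    bin_edges: np.ndarray    # s
    rate_per_min: np.ndarray  # events/min per bin

    @property
    def n_events(self) -> int:
        return len(self.onsets)


def _smooth_track(track: Track, window_s: float = 0.5) -> np.ndarray:
    w = max(1, int(round(window_s * track.frame_rate)))
    out = np.empty_like(track.centroid)
    out[:, 0] = _moving_average(track.centroid[:, 0], w)
    out[:, 1] = _moving_average(track.centroid[:, 1], w)
    return out


def centroid_speed(track: Track, half_window: int | None = None) -> np.ndarray:
    """Symmetric-difference speed on the smoothed trajectory (mm/s).

    Speed at frame i is the distance between positions at frames i−h and i+h
    divided by the elapsed time, with h spanning half a second (±5 frames at
    10 frames/s behavioral data, ±15 frames at 30 frames/s imaging data).
    Edges and artifact values (> 0.6 mm/s) are NaN.
    """
    h = half_window if half_window is not None else max(1, int(round(track.frame_rate / 2)))
    pos = _smooth_track(track)
    n = track.n_frames
    speed = np.full(n, np.nan)
    if n > 2 * h:
        d = np.linalg.norm(pos[2 * h:] - pos[:-2 * h], axis=1)
        speed[h:n - h] = d / (2 * h / track.frame_rate)
    speed[speed > SPEED_ARTIFACT_MM_S] = np.nan
    return speed


def heading_series(track: Track, half_window: int | None = None) -> np.ndarray:
    """Heading (rad) from the displacement between frames i−h and i+h."""
    h = half_window if half_window is not None else max(1, int(round(track.frame_rate / 2)))
    pos = _smooth_track(track)
    n = track.n_frames
    heading = np.full(n, np.nan)
    if n > 2 * h:
        d = pos[2 * h:] - pos[:-2 * h]
        hd = np.arctan2(d[:, 1], d[:, 0])
        hd[np.linalg.norm(d, axis=1) == 0] = np.nan
        heading[h:n - h] = hd
    return heading


def track_curvature(track: Track, speed: np.ndarray | None = None) -> np.ndarray:
    """Absolute heading change per distance crawled (rad/mm).

    The per-frame heading change (between adjacent frames, headings computed
    over ±0.5 s) is divided by the mean distance crossed per frame in the
    same window. Frames slower than 0.03 mm/s are masked (centroid wobble)
    and values above 31 rad/mm removed.
    """
    if speed is None:
        speed = centroid_speed(track)
    heading = heading_series(track)
    n = track.n_frames
    dhead = np.full(n, np.nan)
    dhead[1:] = np.abs(np.angle(np.exp(1j * np.diff(heading))))
    dist_per_frame = speed / track.frame_rate
    with np.errstate(invalid="ignore", divide="ignore"):
        curv = dhead / dist_per_frame
    curv[~np.isfinite(curv)] = np.nan
    curv[speed < CURVATURE_SPEED_FLOOR_MM_S] = np.nan
    curv[curv > CURVATURE_CEILING_RAD_MM] = np.nan
    return curv


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of maximal True runs."""
    m = np.asarray(mask, bool).astype(int)
    d = np.diff(np.concatenate([[0], m, [0]]))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    out = mask.copy()
    runs = _runs_of(~mask)
    for a, b in runs:
        if a == 0 or b == len(mask):
            continue
        if b - a <= max_gap:
            out[a:b] = True
    return out


def _binned_rate(onsets_s: np.ndarray, duration_s: float,
                 bin_s: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(0.0, duration_s + bin_s, bin_s)
    counts, _ = np.histogram(onsets_s, bins=edges)
    return edges, counts / bin_s * 60.0


def detect_reversals(
    track: Track,
    decomp: ModeDecomposition | None = None,
    bin_s: float = 10.0,
    fallback_angvel_rad_s: float = 4.0,
) -> tuple[StateLabels, EventList]:
    """Detect periods of backward locomotion.

    Primary detector (posture available): sustained negative phase velocity
    of the undulation projection for at least 0.3 s — the direction of wave
    propagation defines the crawl direction. Fallback (centroid only):
    large angular-velocity discontinuities of the heading, which accompany
    the entry and exit of a reversal; labels from the fallback are flagged
    low-confidence.
    """
    if track.duration < MIN_TRACK_DURATION_S:
        raise ValueError("track shorter than 20 s")
    fr = track.frame_rate
    n = track.n_frames
    min_len = max(1, int(round(REVERSAL_MIN_DUR_S * fr)))
    low_conf = False
    if decomp is not None:
        pv = _moving_average(decomp.phase_velocity, max(1, int(round(0.3 * fr))))
        neg = np.where(np.isfinite(pv), pv < REVERSAL_PV_THRESHOLD, False)
    else:
        low_conf = True
        heading = heading_series(track)
        dhead = np.full(n, np.nan)
        dhead[1:] = np.abs(np.angle(np.exp(1j * np.diff(heading)))) * fr
        neg = np.where(np.isfinite(dhead), dhead > fallback_angvel_rad_s, False)
    state = np.full(n, FORWARD, dtype=np.int8)
    onsets, durations = [], []
    for a, b in _runs_of(neg):
        if b - a >= min_len:
            state[a:b] = REVERSE
            onsets.append(a / fr)
            durations.append((b - a) / fr)
    edges, rate = _binned_rate(np.array(onsets), track.duration, bin_s)
    return (StateLabels(state, low_confidence=low_conf),
            EventList(np.array(onsets), np.array(durations), edges, rate))


def detect_omega_turns(
    track: Track,
    bin_s: float = 10.0,
    ecc_max: float = OMEGA_ECC_MAX,
    angspeed_min: float = OMEGA_ANGSPEED_MIN,
) -> EventList:
    """Detect omega turns from object eccentricity and angular speed.

    An event requires posture point-cloud eccentricity below ``ecc_max``
    together with body-axis angular speed above ``angspeed_min`` (rad/s),
    co-occurring within ``OMEGA_COWINDOW_S`` and sustained for at least
    0.3 s. An empty event list is a valid outcome.
    """
    if track.posture is None:
        raise ValueError("omega detection requires posture data")
    fr = track.frame_rate
    n = track.n_frames
    ecc = np.full(n, np.nan)
    orient = np.full(n, np.nan)
    for i in range(n):
        if track.posture.valid[i]:
            pts = points_from_angles(track.posture.angles[i])
            ecc[i] = eccentricity(pts)
            c = pts - pts.mean(axis=0)
            cov = c.T @ c
            # body-axis orientation (pi-periodic): the object rotates fast
            # during a reorientation even when the centroid barely moves
            vec = np.linalg.eigh(cov)[1][:, -1]
            orient[i] = np.arctan2(vec[1], vec[0])
    angspeed = np.full(n, np.nan)
    angspeed[1:] = np.abs(np.angle(np.exp(2j * np.diff(orient)))) / 2.0 * fr
    # the deep bend and the fast reorientation need not peak on the same
    # frame; require co-occurrence within a +-OMEGA_COWINDOW_S window
    w = 2 * int(round(OMEGA_COWINDOW_S * fr)) + 1
    ecc_env = ndimage.minimum_filter1d(np.nan_to_num(ecc, nan=1.0), w)
    ang_env = ndimage.maximum_filter1d(np.nan_to_num(angspeed, nan=0.0), w)
    hit = (ecc_env < ecc_max) & (ang_env > angspeed_min)
    hit = _merge_gaps(hit, max_gap=int(round(0.5 * fr)))
    min_len = max(1, int(round(OMEGA_MIN_DUR_S * fr)))
    onsets, durations = [], []
    for a, b in _runs_of(hit):
        if b - a >= min_len:
            onsets.append(a / fr)
            durations.append((b - a) / fr)
    edges, rate = _binned_rate(np.array(onsets), track.duration, bin_s)
    return EventList(np.array(onsets), np.array(durations), edges, rate)


def detect_pauses(speed: np.ndarray, frame_rate: float) -> StateLabels:
    """Pauses: below 0.05 mm/s for at least 2 s, tolerating gaps up to 1 s."""
    below = np.where(np.isfinite(speed), speed < PAUSE_SPEED_MM_S, False)
    below = _merge_gaps(below, max_gap=int(round(PAUSE_GAP_S * frame_rate)))
    min_len = int(round(MIN_PAUSE_S * frame_rate))
    state = np.full(len(speed), FORWARD, dtype=np.int8)
    for a, b in _runs_of(below):
        if b - a >= min_len:
            state[a:b] = PAUSE
    return StateLabels(state)


def classify_states(track: Track, decomp: ModeDecomposition | None = None) -> StateLabels:
    """Combine the detectors into one exclusive per-frame state label.

    Priority omega > reverse > pause > forward; frames with no valid posture
    and no valid speed are invalid.
    """
    speed = centroid_speed(track)
    state = detect_pauses(speed, track.frame_rate).state.copy()
    rev, _ = detect_reversals(track, decomp)
    state[rev.state == REVERSE] = REVERSE
    if track.posture is not None:
        om = detect_omega_turns(track)
        fr = track.frame_rate
        for onset, dur in zip(om.onsets, om.durations):
            a = int(round(onset * fr))
            b = a + int(round(dur * fr))
            state[a:b] = OMEGA
        state[~track.posture.valid & ~np.isfinite(speed)] = INVALID
    return StateLabels(state, low_confidence=rev.low_confidence)


def displacement_binned(track: Track, bin_s: float = 30.0) -> np.ndarray:
    """Straight-line start-to-end centroid distance per time bin (mm).

    Reverse movement is included; a closed loop within a bin yields zero.
    """
    if bin_s > track.duration:
        raise ValueError("bin longer than track")
    per_bin = int(round(bin_s * track.frame_rate))
    n_bins = track.n_frames // per_bin
    out = np.empty(n_bins)
    for k in range(n_bins):
        a, b = k * per_bin, min(track.n_frames - 1, (k + 1) * per_bin)
        out[k] = float(np.linalg.norm(track.centroid[b] - track.centroid[a]))
    return out
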