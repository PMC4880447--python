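"""O₂-gradient chemotaxis analysis.

The arena maps position linearly onto ambient O₂ along its length; worms
prefer an intermediate concentration (16% for 1 hr food-deprived animals).
Bearing B folds the angle between the smoothed centroid heading and the
direction toward the preferred isoline into [0°, 180°] (left/right are
equivalent because the gradient is one-dimensional). Weathervaning is read
out as the curving bias dB/dX (rad/mm) during forward runs — negative means
steering toward the optimum — the biased random walk as the bearing
dependence of reversal rate, and area-restricted-search coupling as the
bearing dependence of speed and turning amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

from .core import FORWARD, OMEGA, REVERSE, StateLabels, Track, sem
from .eigenmodes import ModeDecomposition
from .locomotion import centroid_speed, heading_series, _runs_of

#: Trajectory sections closer than this to the arena edge are excluded (mm).
EDGE_MARGIN_MM = 0.55

#: Weathervaning statistics are restricted to O₂ below the optimum and to
#: times after gradient equilibration.
WEATHERVANE_O2_MAX = 16.0
FLOW_SETTLE_S = 120.0

#: Curving-bias summary scalar averages over this bearing range (deg).
CURVING_SUMMARY_RANGE_DEG = (40.0, 150.0)

#: Run-segmentation thresholds.
MIN_RUN_S = 3.0
MIN_RUN_DISPLACEMENT_MM = 1.0

N_PROFILE_BINS = 13


@dataclass(frozen=True)
class GradientArena:
    """Linear O₂ gradient arena geometry (mm and % O₂)."""

    length: float = 33.0
    width: float = 15.0
    inlet_margin: float = 3.0
    o2_low: float = 4.0
    o2_high: float = 21.0
    optimum: float = 16.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("arena dimensions must be positive")
        if not (self.o2_low < self.optimum <= self.o2_high):
            raise ValueError("require o2_low < optimum <= o2_high")

    def o2_at(self, x: np.ndarray | float) -> np.ndarray | float:
        """Linear position→O₂ map; x in [0, length] mm."""
        x_arr = np.asarray(x, dtype=float)
        if np.any((x_arr < 0) | (x_arr > self.length)):
            raise ValueError("position outside arena")
        out = self.o2_low + (self.o2_high - self.o2_low) * x_arr / self.length
        return float(out) if np.isscalar(x) else out

    def position_of(self, o2: float) -> float:
        """Inverse of the position→O₂ map (mm)."""
        return (o2 - self.o2_low) / (self.o2_high - self.o2_low) * self.length

    def profile_bin_edges(self) -> np.ndarray:
        """Edges of the 13 equal population-profile bins along the length."""
        return np.linspace(0.0, self.length, N_PROFILE_BINS + 1)

    def profile_bin_o2_centers(self) -> np.ndarray:
        edges = self.profile_bin_edges()
        centers = 0.5 * (edges[:-1] + edges[1:])
        return self.o2_low + (self.o2_high - self.o2_low) * centers / self.length

    @property
    def o2_bin_width(self) -> float:
        """O₂ width of one profile bin (≈1.3% for the 4–21% default)."""
        return (self.o2_high - self.o2_low) / N_PROFILE_BINS

    def edge_margin_mask(self, positions: np.ndarray,
                         margin: float = EDGE_MARGIN_MM) -> np.ndarray:
        """True for positions within ``margin`` of any arena edge."""
        p = np.asarray(positions, dtype=float)
        return ((p[:, 0] < margin) | (p[:, 0] > self.length - margin)
                | (p[:, 1] < margin) | (p[:, 1] > self.width - margin))


def o2_at_position(arena: GradientArena, x: np.ndarray | float):
    """Ambient O₂ (%) at position ``x`` mm along the gradient axis."""
    return arena.o2_at(x)


@dataclass
class BearingSeries:
    """Folded bearing (deg, 0 = toward the optimum isoline) and dB/dX."""

    bearing: np.ndarray          # deg in [0, 180]; NaN where undefined
    d_bearing_d_x: np.ndarray    # rad/mm per frame; NaN where undefined
    restricted: np.ndarray       # True where the <16% / post-settle rule holds


def bearing(track: Track, arena: GradientArena,
            speed_floor: float = 0.01) -> BearingSeries:
    """Per-frame bearing of a track in the gradient arena.

    Heading is smoothed over ±0.5 s; frames with near-zero displacement,
    within the edge margin, or outside the arena have NaN bearing. The
    ``restricted`` mask marks frames passing the weathervaning restriction
    (O₂ below the optimum region boundary and after flow settling).
    """
    x = track.centroid[:, 0]
    heading = heading_series(track)
    speed = centroid_speed(track)
    x_opt = arena.position_of(min(arena.optimum, arena.o2_high))
    toward = np.sign(x_opt - x)
    toward[toward == 0] = 1.0
    target_angle = np.where(toward > 0, 0.0, np.pi)
    diff = np.angle(np.exp(1j * (heading - target_angle)))
    b = np.degrees(np.abs(diff))
    bad = (~np.isfinite(heading)) | (speed < speed_floor) | ~np.isfinite(speed)
    bad |= arena.edge_margin_mask(track.centroid)
    b[bad] = np.nan

    # dB/dX: per-frame bearing change over per-frame path length
    db = np.full(track.n_frames, np.nan)
    db[1:] = np.diff(np.radians(b))
    step = np.full(track.n_frames, np.nan)
    step[1:] = np.linalg.norm(np.diff(track.centroid, axis=0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dbdx = db / step
    dbdx[~np.isfinite(dbdx)] = np.nan

    o2 = arena.o2_at(np.clip(x, 0, arena.length))
    restricted = (o2 < WEATHERVANE_O2_MAX) & (track.timestamps >= FLOW_SETTLE_S)
    return BearingSeries(bearing=b, d_bearing_d_x=dbdx, restricted=restricted)


@dataclass
class RunSegment:
    """A maximal forward phase, [start, stop) in frames."""

    start: int
    stop: int
    duration_s: float
    displacement_mm: float


def segment_runs(track: Track, labels: StateLabels) -> list[RunSegment]:
    """Maximal forward phases, dropping runs <3 s or displacing <1 mm."""
    fr = track.frame_rate
    out: list[RunSegment] = []
    for a, b in _runs_of(labels.state == FORWARD):
        dur = (b - a) / fr
        disp = float(np.linalg.norm(track.centroid[b - 1] - track.centroid[a]))
        if dur >= MIN_RUN_S and disp >= MIN_RUN_DISPLACEMENT_MM:
            out.append(RunSegment(a, b, dur, disp))
    return out


@dataclass
class NavigationSummary:
    """Bearing-binned navigation statistics for one trial (or pooled)."""

    bin_edges_deg: np.ndarray
    curving_bias_mean: np.ndarray | None = None       # rad/mm per bin
    curving_bias_sem: np.ndarray | None = None
    curving_bias_counts: np.ndarray | None = None
    curving_bias_summary: float = np.nan              # mean over 40°–150°
    binned_means: dict = field(default_factory=dict)  # name -> per-bin means
    contrasts: dict = field(default_factory=dict)     # name -> above-below 90°


def forward_mask(labels: StateLabels, frame_rate: float,
                 trim_s: float = 1.0) -> np.ndarray:
    """Forward frames at least ``trim_s`` away from any state transition.

    Centroid heading (and hence bearing and chord speed) is computed over a
    ~1 s window, so frames adjacent to reversals, pauses or omega turns carry
    contaminated values and are excluded from bearing-binned statistics.
    """
    fwd = labels.state == FORWARD
    w = max(1, int(round(trim_s * frame_rate)))
    from scipy.ndimage import minimum_filter1d

    return minimum_filter1d(fwd.astype(np.uint8), 2 * w + 1).astype(bool)


def curving_bias(
    runs: list[RunSegment],
    bearings: BearingSeries,
    bin_deg: float = 20.0,
    apply_restriction: bool = True,
    edge_trim: int = 10,
) -> NavigationSummary:
    """Weathervaning read-out: mean dB/dX per 20° bearing bin.

    Frames are pooled across the given forward runs (optionally restricted
    to the sub-16% / post-settle region); ``edge_trim`` frames are dropped at
    both ends of each run because the smoothed heading spans the run
    boundary there. The summary scalar averages the per-frame bias over the
    40°–150° bearing range. Negative values mean steering toward the optimum
    isoline.
    """
    if not runs:
        raise ValueError("no runs supplied")
    mask = np.zeros(len(bearings.bearing), dtype=bool)
    for r in runs:
        a, b = r.start + edge_trim, r.stop - edge_trim
        if b > a:
            mask[a:b] = True
    if apply_restriction:
        mask &= bearings.restricted
    # each step d_bearing_d_x[t] spans frames t-1..t; attribute it to BOTH
    # endpoint bearings with half weight. Endpoint-only attribution has a
    # spurious drift away from the fold boundaries for a diffusing heading
    # (conditioning on where the step ends); symmetric attribution cancels
    # it while leaving genuine steering untouched.
    b_end = bearings.bearing
    b_start = np.concatenate([[np.nan], bearings.bearing[:-1]])
    d_step = bearings.d_bearing_d_x
    b = np.concatenate([b_end[mask], b_start[mask]])
    d = np.concatenate([d_step[mask], d_step[mask]])
    ok = np.isfinite(b) & np.isfinite(d)
    b, d = b[ok], d[ok]
    edges = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    means = np.full(len(edges) - 1, np.nan)
    errs = np.full(len(edges) - 1, np.nan)
    counts = np.zeros(len(edges) - 1, dtype=int)
    idx = np.digitize(b, edges) - 1
    for k in range(len(edges) - 1):
        sel = d[idx == k]
        counts[k] = len(sel)
        if len(sel):
            means[k] = sel.mean()
            errs[k] = sem(sel)
    lo, hi = CURVING_SUMMARY_RANGE_DEG
    in_range = (b >= lo) & (b <= hi)
    # too few frames in the summary range -> unreliable trial, report missing
    summary = float(d[in_range].mean()) if in_range.sum() >= 100 else np.nan
    return NavigationSummary(bin_edges_deg=edges, curving_bias_mean=means,
                             curving_bias_sem=errs, curving_bias_counts=counts,
                             curving_bias_summary=summary)


def binned_vs_bearing(
    values: np.ndarray,
    bearings: BearingSeries,
    bin_deg: float = 20.0,
    apply_restriction: bool = True,
    valid_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Mean of a per-frame series per bearing bin, plus the 90° contrast.

    ``valid_mask`` restricts the statistic to selected frames (typically
    :func:`forward_mask` output). Returns ``(bin_edges, means, sems,
    contrast)`` where contrast is mean(value | B > 90°) − mean(value |
    B < 90°).
    """
    b = bearings.bearing.copy()
    if apply_restriction:
        b[~bearings.restricted] = np.nan
    if valid_mask is not None:
        b[~np.asarray(valid_mask, bool)] = np.nan
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(b) & np.isfinite(v)
    b, v = b[ok], v[ok]
    edges = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    means = np.full(len(edges) - 1, np.nan)
    errs = np.full(len(edges) - 1, np.nan)
    idx = np.digitize(b, edges) - 1
    for k in range(len(edges) - 1):
        sel = v[idx == k]
        if len(sel):
            means[k] = sel.mean()
            errs[k] = sem(sel)
    above = v[b > 90.0]
    below = v[b < 90.0]
    # both sides need real occupancy for a meaningful contrast
    contrast = (float(above.mean()) - float(below.mean())
                if len(above) >= 100 and len(below) >= 100 else np.nan)
    return edges, means, errs, contrast


def reversal_rate_series(labels: StateLabels, frame_rate: float,
                         window_s: float = 10.0) -> np.ndarray:
    """Per-frame local reversal rate (events/min) in a centred window."""
    n = len(labels.state)
    onsets = np.zeros(n)
    rev = labels.state == REVERSE
    d = np.diff(rev.astype(int), prepend=0)
    onsets[d == 1] = 1.0
    w = max(1, int(round(window_s * frame_rate)))
    kernel = np.ones(w)
    local = np.convolve(onsets, kernel, mode="same")
    return local / (w / frame_rate) * 60.0


def reversal_rate_by_bearing(
    labels: StateLabels,
    bearings: BearingSeries,
    frame_rate: float,
    bin_deg: float = 20.0,
    pre_s: float = 1.0,
    apply_restriction: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Reversal initiation rate (events/min) as a function of bearing.

    Each reversal onset is assigned the bearing measured ``pre_s`` seconds
    before onset (bearing during and right after the reversal reflects the
    flipped movement direction, not the decision context), and rates are
    normalised by the forward time spent per bearing bin. Returns
    ``(bin_edges, rate_per_min, contrast)`` with the contrast =
    rate(B > 90°) − rate(B < 90°).
    """
    b = bearings.bearing.copy()
    if apply_restriction:
        b[~bearings.restricted] = np.nan
    fwd = forward_mask(labels, frame_rate, trim_s=pre_s)
    occupancy_b = np.where(fwd, b, np.nan)
    d = np.diff((labels.state == REVERSE).astype(int), prepend=0)
    onset_idx = np.flatnonzero(d == 1)
    pre = max(1, int(round(pre_s * frame_rate)))
    onset_b = np.array([b[i - pre] for i in onset_idx if i - pre >= 0])
    onset_b = onset_b[np.isfinite(onset_b)]
    edges = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(onset_b, bins=edges)
    occ_counts, _ = np.histogram(occupancy_b[np.isfinite(occupancy_b)], bins=edges)
    occ_min = occ_counts / frame_rate / 60.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_min > 0, counts / occ_min, np.nan)

    def _rate(sel_onsets, sel_occ, min_occupancy_s: float = 30.0):
        t = sel_occ.sum() / frame_rate / 60.0
        return sel_onsets.sum() / t if t >= min_occupancy_s / 60.0 else np.nan

    above = _rate(counts[edges[:-1] >= 90.0],
                  occ_counts[edges[:-1] >= 90.0])
    below = _rate(counts[edges[1:] <= 90.0], occ_counts[edges[1:] <= 90.0])
    contrast = above - below if np.isfinite(above) and np.isfinite(below) else np.nan
    return edges, rate, contrast


def detect_shallow_turn_events(
    decomp: ModeDecomposition,
    labels: StateLabels,
    bearings: BearingSeries,
    bin_deg: float = 5.0,
    min_prominence: float = 0.1,
    min_events_for_fit: int = 10,
) -> dict:
    """Peaks of the mid-body turning-mode angle (#11) versus bearing.

    Local maxima of |turning angle #11| during forward, non-omega frames are
    found with a prominence-based peak finder; peak amplitudes are averaged
    over 5° bearing bins and a linear fit across bins (slope, Pearson r) is
    reported, suppressed when fewer than ``min_events_for_fit`` events exist.
    """
    sig = np.abs(decomp.turning.angles[:, 10])
    allowed = (labels.state == FORWARD)
    sig = np.where(allowed & np.isfinite(sig), sig, 0.0)
    peaks, props = find_peaks(sig, prominence=min_prominence)
    amps = sig[peaks]
    bvals = bearings.bearing[peaks]
    ok = np.isfinite(bvals)
    peaks, amps, bvals = peaks[ok], amps[ok], bvals[ok]
    edges = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    means = np.full(len(edges) - 1, np.nan)
    idx = np.digitize(bvals, edges) - 1
    for k in range(len(edges) - 1):
        sel = amps[idx == k]
        if len(sel):
            means[k] = sel.mean()
    result = {"peak_frames": peaks, "peak_amplitudes": amps,
              "peak_bearings": bvals, "bin_edges_deg": edges,
              "bin_means": means, "slope": np.nan, "r": np.nan}
    if len(amps) >= min_events_for_fit:
        centers = 0.5 * (edges[:-1] + edges[1:])
        okb = np.isfinite(means)
        if okb.sum() >= 3:
            fit = linregress(centers[okb], means[okb])
            result["slope"] = float(fit.slope)
            result["r"] = float(fit.rvalue)
    return result


@dataclass
class DistributionProfile:
    """Population distribution over the 13 arena bins, plus chemotaxis index."""

    bin_fractions: np.ndarray
    bin_centers_o2: np.ndarray
    index: np.ndarray | None = None
    cumulative_low_o2_index: float = np.nan

    def __post_init__(self) -> None:
        self.bin_fractions = np.asarray(self.bin_fractions, dtype=float)
        if len(self.bin_fractions) != N_PROFILE_BINS:
            raise ValueError(f"expected {N_PROFILE_BINS} bins")
        if np.any(self.bin_fractions < 0):
            raise ValueError("fractions must be >= 0")
        if abs(self.bin_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def population_profile(
    positions_or_counts,
    arena: GradientArena,
    control: DistributionProfile | None = None,
    zero_crossing_o2: float = 13.8,
) -> DistributionProfile:
    """Fraction of animals per 2-mm arena bin, with chemotaxis index.

    ``positions_or_counts`` is either an (n, 2)/(n,) array of animal
    positions (mm along the gradient axis) or precomputed integer counts per
    bin. When a paired ``control`` profile is given, the per-bin index is
    gradient fraction − control fraction, and the cumulative low-O₂ index
    sums the index over all bins strictly below the bin whose center is
    nearest ``zero_crossing_o2`` (the empirical zero-crossing bin).
    """
    arr = np.asarray(positions_or_counts, dtype=float)
    edges = arena.profile_bin_edges()
    if arr.ndim == 1 and len(arr) == N_PROFILE_BINS and np.allclose(arr, np.round(arr)):
        counts = arr
    else:
        x = arr[:, 0] if arr.ndim == 2 else arr
        counts, _ = np.histogram(x, bins=edges)
    total = counts.sum()
    if total < 1:
        raise ValueError("need at least one animal")
    fractions = counts / total
    centers_o2 = arena.profile_bin_o2_centers()
    prof = DistributionProfile(bin_fractions=fractions, bin_centers_o2=centers_o2)
    if control is not None:
        if len(control.bin_fractions) != N_PROFILE_BINS or not np.allclose(
                control.bin_centers_o2, centers_o2):
            raise ValueError("control profile has different bin geometry")
        prof.index = fractions - control.bin_fractions
        zero_bin = int(np.argmin(np.abs(centers_o2 - zero_crossing_o2)))
        prof.cumulative_low_o2_index = float(prof.index[:zero_bin].sum())
    return prof
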