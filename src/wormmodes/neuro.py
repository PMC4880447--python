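"""Ratiometric calcium-trace processing and activity/behavior coupling.

Two-channel (signal/reference, e.g. GCaMP/mCherry) traces are reduced to the
ratio R and normalized as dR/R (%) = (R − mean R)/mean R over the valid
frames, so the valid-frame mean of dR/R is zero by construction. Artifact
frames (reference drops, extreme ratios, sudden jumps) are invalidated
before normalization, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import PAUSE, StateLabels, sem
from .eigenmodes import _moving_average, mode_crosscorrelation


@dataclass
class CalciumTrace:
    """Two-channel fluorescence trace on a uniform clock (default 30 fps)."""

    timestamps: np.ndarray
    signal_channel: np.ndarray
    reference_channel: np.ndarray
    frame_rate: float = 30.0
    valid: np.ndarray | None = None
    ratio: np.ndarray | None = None
    dR_over_R: np.ndarray | None = None   # percent

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.signal_channel = np.asarray(self.signal_channel, dtype=float)
        self.reference_channel = np.asarray(self.reference_channel, dtype=float)
        n = len(self.timestamps)
        if not (len(self.signal_channel) == len(self.reference_channel) == n):
            raise ValueError("channel lengths must match timestamps")
        if self.valid is None:
            self.valid = (np.isfinite(self.signal_channel)
                          & np.isfinite(self.reference_channel)
                          & (self.reference_channel > 0))
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)


@dataclass
class ArtifactRules:
    """Thresholds for artifact exclusion.

    reference_drop_fraction: a reference-channel sample more than this
    fraction below its 1 s rolling median is an out-of-focus artifact.
    ratio_mad_limit: |R − median R| beyond this many MADs is an extreme
    ratio. jump_mad_limit: a frame-to-frame ratio change beyond this many
    MADs of the typical change is a spike.
    """

    reference_drop_fraction: float = 0.3
    rolling_window_s: float = 1.0
    ratio_mad_limit: float = 5.0
    jump_mad_limit: float = 8.0


def normalize_ratio(trace: CalciumTrace) -> CalciumTrace:
    """Compute R and dR/R (%) over valid frames.

    dR/R = (R − mean R)/mean R with the mean taken over valid frames only,
    so the valid-frame mean of dR/R is zero by construction. Invalid frames
    are NaN. An all-invalid trace is rejected.
    """
    if not trace.valid.any():
        raise ValueError("trace has no valid frames")
    ratio = np.full(trace.n_frames, np.nan)
    v = trace.valid
    ratio[v] = trace.signal_channel[v] / trace.reference_channel[v]
    mean_r = np.nanmean(ratio[v])
    if not (np.isfinite(mean_r) and mean_r > 0):
        raise ValueError("mean ratio must be positive")
    trace.ratio = ratio
    trace.dR_over_R = (ratio - mean_r) / mean_r * 100.0
    return trace


def _mad(x: np.ndarray) -> float:
    med = np.nanmedian(x)
    return float(np.nanmedian(np.abs(x - med)))


def exclude_artifacts(trace: CalciumTrace,
                      rules: ArtifactRules | None = None) -> CalciumTrace:
    """Invalidate artifact frames; never creates new valid frames.

    Applies the reference-drop, extreme-ratio and relative-jump rules, then
    recomputes the normalization on the surviving frames.
    """
    rules = rules or ArtifactRules()
    valid = trace.valid.copy()
    ref = trace.reference_channel
    w = max(1, int(round(rules.rolling_window_s * trace.frame_rate)))
    rolling_med = np.array([
        np.nanmedian(ref[max(0, i - w):i + w + 1]) for i in range(trace.n_frames)
    ])
    with np.errstate(invalid="ignore"):
        drop = ref < (1.0 - rules.reference_drop_fraction) * rolling_med
    valid &= ~drop

    ratio = np.full(trace.n_frames, np.nan)
    ratio[valid] = trace.signal_channel[valid] / ref[valid]
    mad = _mad(ratio[valid])
    if mad > 0:
        med = np.nanmedian(ratio[valid])
        with np.errstate(invalid="ignore"):
            extreme = np.abs(ratio - med) > rules.ratio_mad_limit * mad
        valid &= ~np.where(np.isfinite(ratio), extreme, False)
        jumps = np.abs(np.diff(ratio, prepend=ratio[:1]))
        jmad = _mad(jumps[valid])
        if jmad > 0:
            spike = jumps > rules.jump_mad_limit * jmad
            valid &= ~np.where(np.isfinite(jumps), spike, False)
    trace.valid = valid
    return normalize_ratio(trace)


def event_triggered_average(
    series: np.ndarray,
    events_s: np.ndarray,
    window_s: tuple[float, float],
    frame_rate: float,
) -> dict:
    """Event-aligned mean ± SEM with per-event pre/post interval means.

    ``window_s`` is (pre, post) in seconds (default convention ±8 s); events
    whose full window falls outside the recording are dropped. The per-event
    pre/post means support paired testing.
    """
    series = np.asarray(series, dtype=float)
    pre, post = window_s
    a = int(round(pre * frame_rate))
    b = int(round(post * frame_rate))
    rows, pre_means, post_means = [], [], []
    for t in np.atleast_1d(events_s):
        i = int(round(t * frame_rate))
        if i - a < 0 or i + b + 1 > len(series):
            continue
        seg = series[i - a: i + b + 1]
        rows.append(seg)
        pre_means.append(np.nanmean(seg[:a]))
        post_means.append(np.nanmean(seg[a + 1:]))
    if not rows:
        raise ValueError("no usable events with a full window")
    rows = np.array(rows)
    return {
        "lags_s": (np.arange(-a, b + 1)) / frame_rate,
        "mean": np.nanmean(rows, axis=0),
        "sem": sem(rows, axis=0),
        "pre_means": np.array(pre_means),
        "post_means": np.array(post_means),
        "n_events": len(rows),
    }


def moving_pausing_means(
    trace: CalciumTrace,
    labels: StateLabels,
    min_pausing_s: float = 60.0,
) -> tuple[float, float]:
    """Mean dR/R during moving versus pausing phases.

    Animals pausing less than ``min_pausing_s`` in total are excluded from
    the cohort (raises with a flag message). Labels must be on the trace
    clock.
    """
    if trace.dR_over_R is None:
        raise ValueError("normalize the trace first")
    if len(labels.state) != trace.n_frames:
        raise ValueError("labels must be aligned to the trace")
    pausing = labels.state == PAUSE
    total_pause_s = pausing.sum() / trace.frame_rate
    if total_pause_s < min_pausing_s:
        raise ValueError(
            f"insufficient pausing ({total_pause_s:.1f} s < {min_pausing_s} s): "
            "worm excluded from cohort")
    moving = ~pausing
    return (float(np.nanmean(trace.dR_over_R[moving])),
            float(np.nanmean(trace.dR_over_R[pausing])))


def lag_estimate(
    activity: np.ndarray,
    behavior: np.ndarray,
    max_lag: float,
    frame_rate: float,
) -> tuple[float, bool]:
    """Lag of the peak activity/behavior cross-correlation (s).

    Positive lag means activity lags behind behavior. Returns
    ``(lag_s, at_boundary)``; the boundary flag is raised when the peak sits
    at ±max_lag, meaning the true lag may lie beyond the searched range.
    """
    lags, corr, _, peak_lag = mode_crosscorrelation(behavior, activity,
                                                    max_lag, frame_rate)
    at_boundary = abs(abs(peak_lag) - max_lag) < 0.5 / frame_rate
    return peak_lag, at_boundary


def binned_activity_vs_behavior(
    trace: CalciumTrace,
    behavior: np.ndarray,
    bin_width: float,
    block_s: float = 0.5,
) -> dict:
    """Median ± IQR of dR/R per behavior bin, plus the per-recording r.

    Both series are first averaged in 0.5 s blocks, then dR/R values are
    sorted into equal-width bins of the behavior feature (e.g. 0.01 mm/s for
    speed, 0.2 rad for amplitude).
    """
    if trace.dR_over_R is None:
        raise ValueError("normalize the trace first")
    behavior = np.asarray(behavior, dtype=float)
    if len(behavior) != trace.n_frames:
        raise ValueError("behavior must be aligned to the trace")
    block = max(1, int(round(block_s * trace.frame_rate)))
    n_blocks = trace.n_frames // block
    act = np.nanmean(trace.dR_over_R[:n_blocks * block].reshape(n_blocks, block), axis=1)
    beh = np.nanmean(behavior[:n_blocks * block].reshape(n_blocks, block), axis=1)
    ok = np.isfinite(act) & np.isfinite(beh)
    act, beh = act[ok], beh[ok]
    if len(act) < 3 or beh.std() == 0 or act.std() == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(beh, act)[0, 1])
    lo = np.floor(beh.min() / bin_width) * bin_width if len(beh) else 0.0
    hi = np.ceil(beh.max() / bin_width) * bin_width if len(beh) else bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    med = np.full(max(len(edges) - 1, 0), np.nan)
    q1 = med.copy()
    q3 = med.copy()
    idx = np.digitize(beh, edges) - 1
    for k in range(len(med)):
        sel = act[idx == k]
        if len(sel):
            med[k] = np.median(sel)
            q1[k], q3[k] = np.percentile(sel, [25, 75])
    return {"bin_edges": edges, "median": med, "iqr_low": q1, "iqr_high": q3,
            "r": r, "n_blocks": len(act)}


def activity_peaks(trace: CalciumTrace, mad_factor: float = 2.0,
                   smooth_s: float = 0.5) -> np.ndarray:
    """Activity event times (s): dR/R peaks with prominence ≥ 2× trace MAD.

    The trace is smoothed over ``smooth_s`` (0.5 s, i.e. 15 frames at
    30 frames/s) before peak finding, as is conventional when peak
    detection is involved.
    """
    if trace.dR_over_R is None:
        raise ValueError("normalize the trace first")
    x = np.where(np.isfinite(trace.dR_over_R), trace.dR_over_R, 0.0)
    # prominence referenced to the raw-trace MAD, peaks found on the
    # smoothed trace — frame noise must not set the event scale
    prom = mad_factor * max(_mad(trace.dR_over_R), 1e-12)
    x = _moving_average(x, max(1, int(round(smooth_s * trace.frame_rate))))
    x = np.nan_to_num(x)
    peaks, _ = find_peaks(x, prominence=prom)
    return trace.timestamps[peaks]
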