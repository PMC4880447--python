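"""Trial-level aggregation: fractional distributions, 2-D density maps,
feature-vs-feature binned curves and trial-mean time profiles.

Histograms are normalized per trial before averaging; binned relations pool
0.5 s pre-binned frames across tracks and report medians with interquartile
ranges per x-bin, dropping sparse bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import sem

#: Bins with fewer pooled samples than this are suppressed as sparse.
SPARSE_BIN_MIN_COUNT = 20

PREBIN_S = 0.5


@dataclass
class BinnedRelation:
    """Median/IQR of y per equal-width bin of x."""

    x_bin_medians: np.ndarray
    y_median: np.ndarray
    y_iqr_low: np.ndarray
    y_iqr_high: np.ndarray
    counts: np.ndarray
    bin_width: float


def _block_mean(x: np.ndarray, block: int) -> np.ndarray:
    n = len(x) // block
    if n == 0:
        return np.array([])
    return np.nanmean(np.asarray(x, float)[:n * block].reshape(n, block), axis=1)


def fractional_distribution(
    per_trial_values: list[np.ndarray],
    bin_width: float,
    interval: tuple[float, float] | None = None,
    frame_rate: float | None = None,
    bin_range: tuple[float, float] | None = None,
) -> dict:
    """Trial-mean ± SEM fractional distribution of a per-frame feature.

    Each trial's values (optionally cut to ``interval`` seconds, requiring
    ``frame_rate``) are histogrammed with ``bin_width`` and normalized to
    sum to 1 per trial before averaging across trials.
    """
    if interval is not None:
        if frame_rate is None:
            raise ValueError("interval requires frame_rate")
        a = int(round(interval[0] * frame_rate))
        b = int(round(interval[1] * frame_rate))
        if b <= a:
            raise ValueError("empty interval")
        per_trial_values = [v[a:b] for v in per_trial_values]
    finite = [v[np.isfinite(v)] for v in per_trial_values]
    finite = [v for v in finite if len(v)]
    if not finite:
        raise ValueError("no finite data")
    if bin_range is None:
        lo = min(v.min() for v in finite)
        hi = max(v.max() for v in finite)
    else:
        lo, hi = bin_range
    edges = np.arange(np.floor(lo / bin_width) * bin_width,
                      np.ceil(hi / bin_width) * bin_width + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    fracs = []
    for v in finite:
        h, _ = np.histogram(v, bins=edges)
        fracs.append(h / h.sum() if h.sum() else np.full(len(edges) - 1, np.nan))
    fracs = np.array(fracs)
    return {"bin_edges": edges, "fractions": np.nanmean(fracs, axis=0),
            "sem": sem(fracs, axis=0), "per_trial": fracs}


def density_map_2d(
    x: np.ndarray,
    y: np.ndarray,
    bin_widths: tuple[float, float],
    mass_level: float = 0.99,
) -> dict:
    """Normalized 2-D histogram with an iso-mass boundary.

    The boundary is the union of bins ranked by density until the cumulative
    mass reaches ``mass_level``. Use :func:`fraction_within_boundary` to ask
    how much of a second dataset falls inside it.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    bx, by = bin_widths
    xe = np.arange(np.floor(x.min() / bx) * bx, np.ceil(x.max() / bx) * bx + bx, bx)
    ye = np.arange(np.floor(y.min() / by) * by, np.ceil(y.max() / by) * by + by, by)
    h, xe, ye = np.histogram2d(x, y, bins=[xe, ye])
    h = h / h.sum()
    order = np.argsort(h, axis=None)[::-1]
    cum = np.cumsum(h.ravel()[order])
    k = int(np.searchsorted(cum, mass_level)) + 1
    boundary = np.zeros(h.shape, dtype=bool)
    boundary.ravel()[order[:k]] = True
    return {"density": h, "x_edges": xe, "y_edges": ye,
            "boundary": boundary, "mass_level": mass_level}


def fraction_within_boundary(dmap: dict, x: np.ndarray, y: np.ndarray) -> float:
    """Fraction of (x, y) samples falling inside the iso-mass boundary."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    xi = np.digitize(x, dmap["x_edges"]) - 1
    yi = np.digitize(y, dmap["y_edges"]) - 1
    nb = dmap["boundary"]
    inside = ((xi >= 0) & (xi < nb.shape[0]) & (yi >= 0) & (yi < nb.shape[1]))
    hits = nb[xi[inside], yi[inside]]
    return float(hits.sum() / len(x)) if len(x) else np.nan


def binned_relation(
    x: np.ndarray | list[np.ndarray],
    y: np.ndarray | list[np.ndarray],
    bin_width_x: float,
    frame_rate: float | None = None,
    min_count: int = SPARSE_BIN_MIN_COUNT,
) -> BinnedRelation:
    """Median/IQR of y per x bin, on 0.5 s pre-binned pooled frames.

    ``x`` and ``y`` may be single aligned series or lists of per-track
    series; with ``frame_rate`` given, each track is averaged in 0.5 s
    blocks before pooling. Bins with fewer than ``min_count`` samples are
    dropped.
    """
    xs = x if isinstance(x, list) else [x]
    ys = y if isinstance(y, list) else [y]
    if frame_rate is not None:
        block = max(1, int(round(PREBIN_S * frame_rate)))
        xs = [_block_mean(v, block) for v in xs]
        ys = [_block_mean(v, block) for v in ys]
    xcat = np.concatenate([np.asarray(v, float) for v in xs])
    ycat = np.concatenate([np.asarray(v, float) for v in ys])
    ok = np.isfinite(xcat) & np.isfinite(ycat)
    xcat, ycat = xcat[ok], ycat[ok]
    edges = np.arange(np.floor(xcat.min() / bin_width_x) * bin_width_x,
                      np.ceil(xcat.max() / bin_width_x) * bin_width_x + bin_width_x,
                      bin_width_x)
    idx = np.digitize(xcat, edges) - 1
    med_x, med_y, q1, q3, cnt = [], [], [], [], []
    for k in range(len(edges) - 1):
        sel = idx == k
        if sel.sum() < min_count:
            continue
        med_x.append(np.median(xcat[sel]))
        med_y.append(np.median(ycat[sel]))
        lo, hi = np.percentile(ycat[sel], [25, 75])
        q1.append(lo)
        q3.append(hi)
        cnt.append(int(sel.sum()))
    return BinnedRelation(np.array(med_x), np.array(med_y), np.array(q1),
                          np.array(q3), np.array(cnt), bin_width_x)


def trial_mean_profile(
    per_trial_series: list[np.ndarray],
    frame_rate: float,
    bin_s: float = 1.0,
) -> dict:
    """Frame-wise mean ± SEM across trials, then display-binned.

    Trials of unequal length contribute wherever they have data; the
    per-frame n reflects availability. The frame-wise curves are finally
    averaged in ``bin_s`` bins (1 s default) for display.
    """
    n_max = max(len(s) for s in per_trial_series)
    stack = np.full((len(per_trial_series), n_max), np.nan)
    for i, s in enumerate(per_trial_series):
        stack[i, :len(s)] = s
    n_per_frame = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_per_frame > 0, np.nanmean(stack, axis=0), np.nan)
        err = sem(stack, axis=0)
    block = max(1, int(round(bin_s * frame_rate)))
    return {
        "time_s": _block_mean(np.arange(n_max) / frame_rate, block),
        "mean": _block_mean(mean, block),
        "sem": _block_mean(err, block),
        "n_per_frame": n_per_frame,
        "frame_mean": mean,
    }
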