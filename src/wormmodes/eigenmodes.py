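"""Eigenworm basis fitting and undulation/turning mode decomposition.

Eigenworms (EWs) are the eigenvectors of the covariance matrix of the 24
inter-segment angles over many concatenated posture time series, ordered by
decreasing explained variance. The first two EWs span the regular traveling
wave; reconstructing posture from EW1–2 yields the *undulation mode*, and
the residual (equivalently the EW3–24 reconstruction) is the *turning mode*::

    undulation = mean + EW12 @ (EW12.T @ (angles - mean))
    turning    = angles - undulation

The per-angle means are added back to the undulation mode only, so that
``undulation + turning == angles`` holds exactly for every frame.

The projection pair (a1, a2) onto EW1–2 oscillates in quadrature during
crawling; the rotation rate of the gently smoothed (a1, a2) vector is the
phase velocity (cycles/s) whose magnitude is the undulation frequency and
whose sign encodes the wave (crawl) direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PostureSeries, sem
from .geometry import N_ANGLES

MIN_FIT_FRAMES = 1000

#: Moving-average window (s) applied to (a1, a2) before phase computation.
PHASE_SMOOTH_S = 0.5

#: Frames whose projection magnitude is below this fraction of the series
#: median are masked in the phase-velocity series — the wave phase is
#: undefined there (deep coils suspend the undulation).
PHASE_MIN_PROJ_FRACTION = 0.2


@dataclass
class EigenwormBasis:
    """Orthonormal 24×24 postural basis with means and variance fractions."""

    vectors: np.ndarray            # (24, 24), rows EW1..EW24
    means: np.ndarray              # (24,) per-angle time means, rad
    variance_fractions: np.ndarray  # (24,), non-increasing, sums to 1
    n_frames: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variance_fractions = np.asarray(self.variance_fractions, dtype=float)
        if self.vectors.shape != (N_ANGLES, N_ANGLES):
            raise ValueError("vectors must be 24x24")
        if not np.allclose(self.vectors @ self.vectors.T, np.eye(N_ANGLES), atol=1e-8):
            raise ValueError("vectors must be orthonormal")
        if np.any(np.diff(self.variance_fractions) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        if abs(self.variance_fractions.sum() - 1.0) > 1e-8:
            raise ValueError("variance fractions must sum to 1")

    def cumulative_variance(self, k: int) -> float:
        """Cumulative variance fraction of the first ``k`` eigenworms."""
        return float(self.variance_fractions[:k].sum())

    def save(self, path) -> None:
        """Persist as a plain-text matrix with a header.

        Column order of the vectors is head→tail (angle #1 … #24); rows are
        EW1…EW24 by decreasing variance.
        """
        header = (
            f"wormmodes eigenworm basis v1\n"
            f"n_frames {self.n_frames}\n"
            f"means " + " ".join(f"{m:.10g}" for m in self.means) + "\n"
            f"variance_fractions " + " ".join(f"{v:.10g}" for v in self.variance_fractions)
        )
        np.savetxt(path, self.vectors, header=header)

    @classmethod
    def load(cls, path) -> "EigenwormBasis":
        with open(path) as fh:
            return cls.from_text(fh.read())

    @classmethod
    def from_text(cls, text: str) -> "EigenwormBasis":
        import io as _io

        lines = [ln[2:].rstrip("\n") for ln in text.splitlines()
                 if ln.startswith("# ")]
        meta = {}
        for ln in lines[1:]:
            key, _, rest = ln.partition(" ")
            meta[key] = rest
        vectors = np.loadtxt(_io.StringIO(text))
        return cls(
            vectors=vectors,
            means=np.fromstring(meta["means"], sep=" "),
            variance_fractions=np.fromstring(meta["variance_fractions"], sep=" "),
            n_frames=int(meta["n_frames"]),
        )


@dataclass
class ModeDecomposition:
    """Posture split into undulation (EW1–2) and turning (EW3–24) modes."""

    undulation: PostureSeries
    turning: PostureSeries
    undulation_amp: np.ndarray
    turning_amp: np.ndarray
    body_amp: np.ndarray
    proj: np.ndarray               # (n, 2) projections (a1, a2)
    phase: np.ndarray              # rad, unwrapped; NaN where masked
    phase_velocity: np.ndarray     # cycles/s; NaN where masked
    frame_rate: float


def fit_eigenworms(series: list[PostureSeries]) -> EigenwormBasis:
    """Fit the eigenworm basis by PCA on concatenated valid frames.

    Angles are centered per segment before the covariance (centering is also
    applied in the projection step of :func:`decompose`). Eigenvector sign is
    fixed by making the first nonzero component positive. At least 1000
    valid frames are required.
    """
    frames = [s.valid_angles() for s in series]
    data = np.concatenate([f for f in frames if len(f)], axis=0) if frames else np.empty((0, N_ANGLES))
    if len(data) < MIN_FIT_FRAMES:
        raise ValueError(
            f"insufficient sampling: {len(data)} valid frames < {MIN_FIT_FRAMES}")
    means = data.mean(axis=0)
    centered = data - means
    cov = centered.T @ centered / len(data)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    vectors = evecs[:, order].T
    # deterministic sign: first component of each EW exceeding tolerance positive
    for v in vectors:
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if len(nz) and v[nz[0]] < 0:
            v *= -1.0
    total = evals.sum()
    fractions = evals / total if total > 0 else np.full(N_ANGLES, 1.0 / N_ANGLES)
    return EigenwormBasis(vectors=vectors, means=means,
                          variance_fractions=fractions, n_frames=len(data))


def amplitude(frame_angles: np.ndarray) -> np.ndarray:
    """Mode amplitude: sum of absolute inter-segment angles per frame (rad).

    Accepts a single frame (24,) or a series (n, 24); invalid (NaN) frames
    yield NaN.
    """
    a = np.asarray(frame_angles, dtype=float)
    return np.abs(a).sum(axis=-1)


def decompose(series: PostureSeries, basis: EigenwormBasis) -> ModeDecomposition:
    """Decompose a posture series into undulation and turning modes.

    The undulation mode is the per-angle means plus the projection of the
    centered angles onto EW1–2; the turning mode is the residual, identically
    equal to the EW3–24 reconstruction. Additivity
    ``undulation + turning == posture`` is exact by construction.
    """
    if series.angles.shape[1] != basis.vectors.shape[1]:
        raise ValueError("dimension mismatch between series and basis")
    if not series.valid.any():
        raise ValueError("series has no valid frames")
    ew12 = basis.vectors[:2]                     # (2, 24)
    centered = series.angles - basis.means
    proj = centered @ ew12.T                     # (n, 2)
    undul = basis.means + proj @ ew12
    turn = series.angles - undul
    undulation = PostureSeries(undul, frame_rate=series.frame_rate,
                               valid=series.valid.copy(), t0=series.t0)
    turning = PostureSeries(turn, frame_rate=series.frame_rate,
                            valid=series.valid.copy(), t0=series.t0)
    phase, pvel = _phase_and_velocity(proj, series.frame_rate, series.valid)
    pvel = orient_forward(pvel)
    return ModeDecomposition(
        undulation=undulation,
        turning=turning,
        undulation_amp=amplitude(undulation.angles),
        turning_amp=amplitude(turning.angles),
        body_amp=amplitude(series.angles),
        proj=proj,
        phase=phase,
        phase_velocity=pvel,
        frame_rate=series.frame_rate,
    )


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.copy()
    kernel = np.ones(w) / w
    out = np.full_like(x, np.nan)
    finite = np.isfinite(x)
    xf = np.where(finite, x, 0.0)
    num = np.convolve(xf, kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.5, num / den, np.nan)
    return out


def _phase_and_velocity(proj: np.ndarray, frame_rate: float,
                        valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(proj)
    w = max(1, int(round(PHASE_SMOOTH_S * frame_rate)))
    a1 = _moving_average(np.where(valid, proj[:, 0], np.nan), w)
    a2 = _moving_average(np.where(valid, proj[:, 1], np.nan), w)
    mag = np.hypot(a1, a2)
    med = np.nanmedian(mag)
    mask = np.isfinite(mag) & (mag >= PHASE_MIN_PROJ_FRACTION * med) & (mag > 0)
    raw_phase = np.arctan2(a2, a1)
    # per-step smallest-angle increments; steps through masked frames are NaN
    dphi = np.full(n, np.nan)
    dphi[1:] = np.angle(np.exp(1j * (raw_phase[1:] - raw_phase[:-1])))
    dphi[1:][~(mask[1:] & mask[:-1])] = np.nan
    phase = np.full(n, np.nan)
    if mask.any():
        start = int(np.argmax(mask))
        phase[start] = raw_phase[start]
        inc = np.where(np.isnan(dphi), 0.0, dphi)
        acc = np.cumsum(inc[start + 1:]) if start + 1 <= n else np.array([])
        phase[start + 1:] = phase[start] + acc
        phase[~mask] = np.nan
    pvel = np.full(n, np.nan)
    pvel[:-1] = dphi[1:] * frame_rate / (2.0 * np.pi)
    pvel[~mask] = np.nan
    return phase, pvel


def phase_velocity(proj: np.ndarray, frame_rate: float,
                   valid: np.ndarray | None = None) -> np.ndarray:
    """Signed rotation rate of the (a1, a2) projection pair, cycles/s.

    This is the raw rotation rate (antisymmetric under time reversal); its
    magnitude is the undulation frequency. The recording-level convention
    that positive means a forward-propagating wave is applied separately by
    :func:`orient_forward` (and inside :func:`decompose`). Frames with
    near-zero projection magnitude are NaN.
    """
    proj = np.asarray(proj, dtype=float)
    if len(proj) < 2:
        raise ValueError("need at least 2 frames")
    if valid is None:
        valid = np.all(np.isfinite(proj), axis=1)
    _, pvel = _phase_and_velocity(proj, frame_rate, np.asarray(valid, bool))
    return pvel


def orient_forward(pvel: np.ndarray) -> np.ndarray:
    """Fix the sign convention of a phase-velocity series.

    The rotation sense of (a1, a2) for forward crawling depends on arbitrary
    eigenvector signs; since animals move forward most of the time, the sign
    is chosen per series so the median velocity is non-negative.
    """
    med = np.nanmedian(pvel)
    if np.isfinite(med) and med < 0:
        return -pvel
    return pvel


def mode_crosscorrelation(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: float,
    frame_rate: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Normalized cross-correlation of two per-frame signals.

    Returns ``(lags_s, corr, peak_corr, peak_lag_s)`` where ``corr[k]`` is the
    Pearson correlation between ``x(t)`` and ``y(t + lag_k)`` over the frames
    where both are valid, for lags in [−max_lag, +max_lag]. A positive peak
    lag therefore means ``y`` lags behind ``x``. The reported peak is the
    maximum *absolute* correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must share length")
    max_shift = int(round(max_lag * frame_rate))
    both = np.isfinite(x) & np.isfinite(y)
    if both.sum() < 10 * max_shift:
        raise ValueError("insufficient overlapping valid samples for max_lag")
    lags = np.arange(-max_shift, max_shift + 1)
    corr = np.full(len(lags), np.nan)
    for i, k in enumerate(lags):
        if k >= 0:
            xs, ys = x[: len(x) - k], y[k:]
        else:
            xs, ys = x[-k:], y[: len(y) + k]
        m = np.isfinite(xs) & np.isfinite(ys)
        if m.sum() < 3:
            continue
        xs, ys = xs[m], ys[m]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            raise ValueError("constant signal: correlation undefined")
        corr[i] = float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))
    ipk = int(np.nanargmax(np.abs(corr)))
    return lags / frame_rate, corr, float(corr[ipk]), float(lags[ipk] / frame_rate)


def average_crosscorrelation(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    max_lag: float,
    frame_rate: float,
    min_duration: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Per-track cross-correlations averaged over tracks.

    Tracks shorter than ``min_duration`` seconds are discarded. Returns
    ``(lags_s, mean_corr, sem_corr, peak_corr, peak_lag_s)`` of the averaged
    curve.
    """
    min_frames = int(round(min_duration * frame_rate))
    curves = []
    lags = None
    for x, y in pairs:
        if len(x) < min_frames:
            continue
        lags, corr, _, _ = mode_crosscorrelation(x, y, max_lag, frame_rate)
        curves.append(corr)
    if not curves:
        raise ValueError("no track long enough for cross-correlation")
    curves = np.array(curves)
    mean = np.nanmean(curves, axis=0)
    err = sem(curves, axis=0)
    ipk = int(np.nanargmax(np.abs(mean)))
    return lags, mean, err, float(mean[ipk]), float(lags[ipk])


def turn_onset_lag_estimate(decomp: ModeDecomposition, max_lag: float = 2.0) -> float:
    """Lag of turning-amplitude transients behind the undulation cycle (s).

    The undulation cycle is referenced by an observable event — the positive
    maxima of the mid-body undulation-mode angle (#11) — whose impulse train
    is cross-correlated with the turning-amplitude series; the peak lag
    within [0, max_lag] is returned. On data where turn onsets are
    phase-locked to the cycle this recovers the onset lag. ``max_lag`` must
    stay below the undulation period to avoid cycle aliasing.
    """
    from scipy.signal import find_peaks

    u11 = decomp.undulation.angles[:, 10]
    peaks, _ = find_peaks(np.where(np.isfinite(u11), u11, 0.0),
                          height=0.5 * np.nanmax(u11))
    train = np.zeros(len(u11))
    train[peaks] = 1.0
    lags, corr, _, _ = mode_crosscorrelation(train, decomp.turning_amp,
                                             max_lag, decomp.frame_rate)
    pos = lags >= 0
    ipk = int(np.nanargmax(corr[pos]))
    return float(lags[pos][ipk])


def canonical_basis() -> EigenwormBasis:
    """The canonical eigenworm basis shipped with the package.

    Fitted once on a 50-recording default-parameter synthetic wild-type
    ensemble (50 × 60 s at 10 frames/s); use it for cross-condition
    comparisons so that all groups are decomposed in the same shape space.
    """
    from importlib.resources import files

    text = files("wormmodes").joinpath("data/canonical_basis.txt").read_text()
    return EigenwormBasis.from_text(text)


def resampling_p_upper_bound(exceedances: int, n_iter: int) -> float:
    """Upper-bound p-value of the resampling test.

    ``max(exceedances, 1) / n_iter``: with zero exceedances the bound is the
    resolution limit 1/n_iter (e.g. 10⁻⁶ at one million iterations).
    """
    return max(exceedances, 1) / n_iter


def variance_resampling_test(
    group_a: list[PostureSeries],
    group_b: list[PostureSeries],
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for a difference between variance spectra.

    The statistic is the cumulative difference between the two groups'
    cumulative variance-fraction curves (per-group PCA on concatenated valid
    frames), taken in absolute value so it is symmetric in group order. The
    null is built by shuffling series-level group labels, preserving the
    group sizes. The returned p-value is the upper bound
    ``max(#(null >= observed), 1) / n_iter`` — with zero exceedances at the
    configured iteration count the bound is ``1/n_iter``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 series")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = np.random.default_rng(seed)

    def stat(ga: list[PostureSeries], gb: list[PostureSeries]) -> float:
        ca = _cumvar(ga)
        cb = _cumvar(gb)
        return float(np.abs(np.sum(ca - cb)))

    observed = stat(group_a, group_b)
    pooled = list(group_a) + list(group_b)
    na = len(group_a)
    exceed = 0
    for _ in range(n_iter):
        idx = rng.permutation(len(pooled))
        ga = [pooled[i] for i in idx[:na]]
        gb = [pooled[i] for i in idx[na:]]
        if stat(ga, gb) >= observed:
            exceed += 1
    return observed, resampling_p_upper_bound(exceed, n_iter)


def _cumvar(group: list[PostureSeries]) -> np.ndarray:
    data = np.concatenate([s.valid_angles() for s in group], axis=0)
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered / len(data)
    evals = np.sort(np.maximum(np.linalg.eigvalsh(cov), 0.0))[::-1]
    total = evals.sum()
    frac = evals / total if total > 0 else np.full(N_ANGLES, 1.0 / N_ANGLES)
    return np.cumsum(frac)
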