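"""Synthetic worm data with known ground truth.

The generator emulates the statistical structure the analysis assumes for a
crawling *C. elegans*: a traveling-wave undulation across 24 inter-segment
angles, sparse smooth turning transients confined to the spatial subspace
orthogonal to the two leading undulation shapes, interleaved reversals,
pauses and omega turns, and reciprocal stimulus coupling (an O₂ downshift
up-regulates turning and down-regulates undulation, each monophasically,
returning to baseline with a configurable time constant).

Angle model for segment ``k`` at time ``t``::

    theta_k(t) = A(t) * sin(phi(t) - k * phase_per_segment)
                 + turning_transient(t, k) + noise

``phi`` advances at ``2*pi*f(t)`` during forward crawling, reverses sign
during reversals and freezes during pauses. Turning transients are raised-
cosine bumps (default width 1 s) whose peak is lagged ``turn_onset_lag``
behind an undulation phase zero-crossing, reproducing the phase-locking of
turn onsets to the undulation cycle.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import FORWARD, OMEGA, PAUSE, REVERSE, PostureSeries, StateLabels, Track
from .geometry import N_ANGLES

__all__ = [
    "KinematicParams",
    "StimulusProtocol",
    "CouplingModel",
    "NavigationGains",
    "SyntheticRecording",
    "generate_posture_series",
    "generate_gradient_population",
    "generate_calcium_trace",
    "render_worm",
]

#: O₂ drop (percentage points) that normalizes the coupling drive to 1.
#: A standard 21→10% downshift therefore drives a unit response.
SHIFT_NORM_O2 = 11.0

#: Total bend (sum of |angles|) at the peak of an omega turn (rad) — about a
#: full circle, so the silhouette coils — and the event length (s).
OMEGA_SUM_RAD = 6.5
OMEGA_DUR_S = 1.0

#: Centroid path length per undulation cycle (mm/cycle) at full amplitude.
STRIDE_MM_PER_CYCLE = 1.0 / 3.0


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class KinematicParams:
    """Ground-truth kinematic parameters of the synthetic worm.

    Rates are events/min, durations seconds, amplitudes radians. Defaults
    describe an unstimulated, food-deprived adult crawling at 10 frames/s.
    """

    frame_rate: float = 10.0
    undulation_amp: float = 0.35        # peak angle per segment, rad
    undulation_freq: float = 0.45       # cycles/s
    phase_per_segment: float = 0.4      # rad of spatial wave per segment (~1.5 wavelengths)
    turn_event_rate: float = 6.0        # shallow turns, events/min
    turn_amp_scale: float = 2.0         # summed bend of a turn bump at peak, rad
    turn_width: float = 1.0             # raised-cosine bump full width, s
    turn_onset_lag: float = 0.6         # s behind undulation phase zero-crossing
    reversal_rate: float = 2.0          # events/min
    reversal_dur: float = 2.0           # s
    pause_rate: float = 1.0             # events/min
    pause_dur: float = 2.5              # s
    omega_rate: float = 1.0             # events/min
    steer_wobble_sd: float = 0.3        # rad summed bend, continuous steering
    steer_wobble_tau: float = 1.0       # s, steering-wobble correlation time
    angle_noise_sd: float = 0.03        # rad
    heading_noise_sd: float = 0.03      # rad/sqrt(s), centroid-tracking jitter
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.frame_rate > 0 and math.isfinite(self.frame_rate),
                 "frame_rate", "must be positive and finite")
        for name in ("undulation_amp", "undulation_freq", "phase_per_segment",
                     "turn_event_rate", "turn_amp_scale", "turn_width",
                     "turn_onset_lag", "reversal_rate", "reversal_dur",
                     "pause_rate", "pause_dur", "omega_rate",
                     "steer_wobble_sd", "steer_wobble_tau",
                     "angle_noise_sd", "heading_noise_sd"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, name, "must be finite and >= 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-linear ambient O₂ time course.

    ``breakpoints`` is a sequence of (time s, O₂ %) with strictly increasing
    times; concentration is held constant before the first and after the last
    breakpoint and interpolated linearly in between.
    """

    breakpoints: tuple[tuple[float, float], ...]
    kind: str = "constant"

    def __post_init__(self) -> None:
        times = [b[0] for b in self.breakpoints]
        o2s = [b[1] for b in self.breakpoints]
        _require(len(self.breakpoints) >= 1, "breakpoints", "need at least one")
        _require(all(t2 > t1 for t1, t2 in zip(times, times[1:])),
                 "breakpoints", "times must be strictly increasing")
        _require(all(0.0 <= o <= 21.0 for o in o2s),
                 "breakpoints", "O2 must lie in [0, 21]%")

    @classmethod
    def constant(cls, o2: float = 21.0) -> "StimulusProtocol":
        return cls(((0.0, o2),), kind="constant")

    @classmethod
    def shift(cls, t_shift: float = 0.0, o2_from: float = 21.0,
              o2_to: float = 10.0, transition: float = 12.0) -> "StimulusProtocol":
        """Step between two levels; the arena equilibrates over ``transition`` s."""
        return cls(((t_shift, o2_from), (t_shift + transition, o2_to)), kind="shift")

    @classmethod
    def ramp(cls, t_start: float = 0.0, o2_from: float = 21.0,
             o2_to: float = 4.0, duration: float = 180.0) -> "StimulusProtocol":
        """Linear ramp, by default 21→4% O₂ over three minutes (0.094 %/s)."""
        return cls(((t_start, o2_from), (t_start + duration, o2_to)), kind="ramp")

    @property
    def rate(self) -> float:
        """Mean |dO₂/dt| between the first and last breakpoint (%/s)."""
        (t0, o0), (t1, o1) = self.breakpoints[0], self.breakpoints[-1]
        if t1 == t0:
            return 0.0
        return abs(o1 - o0) / (t1 - t0)

    def o2_at(self, t: np.ndarray | float) -> np.ndarray | float:
        times = np.array([b[0] for b in self.breakpoints])
        o2s = np.array([b[1] for b in self.breakpoints])
        return np.interp(t, times, o2s)


@dataclass(frozen=True)
class CouplingModel:
    """Reciprocal stimulus coupling of turning and undulation.

    A downshift drives a response ``r(t)`` (unit jump for a 21→10% shift)
    decaying with ``recovery_tau``; turning rate and amplitude scale by
    ``1 + turn_gain*r`` while undulation amplitude and frequency scale by
    ``1 / (1 + und_gain*r)`` — monophasic in opposite directions.
    """

    turn_gain: float = 1.0
    und_gain: float = 0.5
    recovery_tau: float = 90.0

    def __post_init__(self) -> None:
        _require(self.turn_gain >= 0, "turn_gain", "must be >= 0")
        _require(self.und_gain >= 0, "und_gain", "must be >= 0")
        _require(self.recovery_tau > 0, "recovery_tau", "must be > 0")

    def drive(self, o2: np.ndarray, frame_rate: float) -> np.ndarray:
        """Leaky-integrated downshift drive, sampled on the recording clock."""
        o2 = np.asarray(o2, dtype=float)
        inc = np.maximum(-np.diff(o2, prepend=o2[:1]), 0.0) / SHIFT_NORM_O2
        decay = math.exp(-1.0 / (frame_rate * self.recovery_tau))
        return lfilter([1.0], [1.0, -decay], inc)


@dataclass
class SyntheticRecording:
    """One synthetic recording with its full ground truth."""

    posture: PostureSeries
    track: Track
    truth_labels: StateLabels
    truth_params: KinematicParams
    stimulus: StimulusProtocol
    coupling: CouplingModel
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.posture.n_frames
        if not (self.track.n_frames == n == len(self.truth_labels.state)):
            raise ValueError("posture, track and labels must share frame count")


def _undulation_subspace(phase_per_segment: float) -> np.ndarray:
    """Orthonormal basis (2, 24) of the traveling-wave spatial subspace."""
    k = np.arange(N_ANGLES)
    u1 = np.cos(k * phase_per_segment)
    u2 = np.sin(k * phase_per_segment)
    u1 /= np.linalg.norm(u1)
    u2 -= u1 * (u1 @ u2)
    u2 /= np.linalg.norm(u2)
    return np.stack([u1, u2])


def _turn_shape(rng: np.random.Generator,
                center_lo: int = 9, center_hi: int = 14, sd: float = 2.5) -> np.ndarray:
    """Smooth single-lobed spatial bump (a C-bend), summed |bend| = 1.

    Real shallow turns are single-lobed bends; they project partly onto the
    two leading wave shapes, as real turns do, and the rest falls in the
    turning subspace.
    """
    c = rng.integers(center_lo, center_hi + 1)
    k = np.arange(N_ANGLES)
    shape = np.exp(-0.5 * ((k - c) / sd) ** 2)
    return shape / shape.sum()


def _schedule_events(rng: np.random.Generator, n: int, dt: float,
                     rev_rate: np.ndarray, pause_rate: float, omega_rate: float,
                     rev_dur: float, pause_dur: float) -> np.ndarray:
    """Draw mutually exclusive reversal/pause/omega intervals by thinning."""
    state = np.full(n, FORWARD, dtype=np.int8)
    p_rev = rev_rate / 60.0 * dt
    p_pause = pause_rate / 60.0 * dt
    p_omega = omega_rate / 60.0 * dt
    durs = {REVERSE: rev_dur, PAUSE: pause_dur, OMEGA: OMEGA_DUR_S}
    i = 0
    while i < n:
        u = rng.random()
        pr = p_rev[i] if np.ndim(p_rev) else p_rev
        if u < pr:
            code = REVERSE
        elif u < pr + p_pause:
            code = PAUSE
        elif u < pr + p_pause + p_omega:
            code = OMEGA
        else:
            i += 1
            continue
        length = max(1, int(round(durs[code] / dt)))
        state[i:i + length] = code
        i += length + 1
    return state


def generate_posture_series(
    params: KinematicParams | None = None,
    stimulus: StimulusProtocol | None = None,
    coupling: CouplingModel | None = None,
    duration: float = 360.0,
) -> SyntheticRecording:
    """Generate one synthetic recording (posture + track + ground truth).

    Parameters
    ----------
    params
        Kinematic ground truth; defaults describe an unstimulated worm.
    stimulus
        Ambient O₂ protocol; default constant 21%.
    coupling
        Stimulus coupling of the two motor modes; default reciprocal.
    duration
        Recording length in seconds, at least 10 s.
    """
    params = params or KinematicParams()
    stimulus = stimulus or StimulusProtocol.constant()
    coupling = coupling or CouplingModel()
    if not (math.isfinite(duration) and duration >= 10.0):
        raise ValueError("duration: must be finite and >= 10 s")

    fr = params.frame_rate
    dt = 1.0 / fr
    n = int(round(duration * fr))
    t = np.arange(n) * dt
    rng = np.random.default_rng(params.seed)

    # --- stimulus-coupled instantaneous parameters ------------------------
    o2 = np.asarray(stimulus.o2_at(t), dtype=float)
    r = coupling.drive(o2, fr)
    amp_t = params.undulation_amp / (1.0 + coupling.und_gain * r)
    freq_t = params.undulation_freq / (1.0 + coupling.und_gain * r)
    turn_rate_t = params.turn_event_rate * (1.0 + coupling.turn_gain * r)
    turn_amp_t = params.turn_amp_scale * (1.0 + coupling.turn_gain * r)

    # --- behavioral state schedule ---------------------------------------
    state = _schedule_events(rng, n, dt, np.full(n, params.reversal_rate),
                             params.pause_rate, params.omega_rate,
                             params.reversal_dur, params.pause_dur)

    # --- undulation phase -------------------------------------------------
    direction = np.where(state == REVERSE, -1.0, np.where(state == PAUSE, 0.0, 1.0))
    phi = np.cumsum(2.0 * np.pi * freq_t * direction * dt)
    k = np.arange(N_ANGLES)
    # the undulatory wave is suspended while the body curls through an
    # omega turn
    amp_eff = np.where(state == OMEGA, 0.0, amp_t)
    angles = amp_eff[:, None] * np.sin(phi[:, None] - k[None, :] * params.phase_per_segment)

    # --- turning transients, phase-locked to the undulation cycle --------
    ubasis = _undulation_subspace(params.phase_per_segment)
    # lock events to the positive maxima of the mid-body undulation angle
    # (#11): theta_11(t) = phi(t) - 10*phase_per_segment passing pi/2 mod 2pi.
    theta11 = phi - 10 * params.phase_per_segment
    cyc = np.floor((theta11 - np.pi / 2.0) / (2.0 * np.pi))
    crossings = np.flatnonzero(np.diff(cyc) != 0) + 1
    turning = np.zeros_like(angles)
    turn_truth = np.zeros(n)
    half_w = int(round(params.turn_width / 2.0 * fr))
    p_turn = turn_rate_t / 60.0 * dt
    candidates = np.flatnonzero((rng.random(n) < p_turn) & (state == FORWARD))
    events = []
    for c in candidates:
        nxt = crossings[np.searchsorted(crossings, c)] if np.searchsorted(crossings, c) < len(crossings) else None
        if nxt is None:
            continue
        peak = nxt + int(round(params.turn_onset_lag * fr))
        if peak - half_w < 0 or peak + half_w >= n:
            continue
        shape = _turn_shape(rng) * turn_amp_t[c] * rng.choice([-1.0, 1.0])
        idx = np.arange(peak - half_w, peak + half_w + 1)
        env = 0.5 * (1.0 + np.cos(np.pi * (idx - peak) / max(half_w, 1)))
        turning[idx] += env[:, None] * shape[None, :]
        turn_truth[idx] += env * np.abs(shape).sum()
        events.append((peak, float(shape[10])))
    # omega turns: deep bends with a wider spatial bump
    omega_onsets = np.flatnonzero(np.diff((state == OMEGA).astype(int)) == 1) + 1
    if state[0] == OMEGA:
        omega_onsets = np.concatenate([[0], omega_onsets])
    for onset in omega_onsets:
        length = int(round(OMEGA_DUR_S * fr))
        peak = min(onset + length // 2, n - 1)
        # a broad near-uniform curl: in a deep omega bend the whole body
        # participates and the net turn reaches a full circle
        shape = np.hanning(30)[3:27].copy()
        shape = shape / shape.sum() * OMEGA_SUM_RAD * rng.choice([-1.0, 1.0])
        idx = np.arange(max(0, peak - length), min(n, peak + length + 1))
        env = 0.5 * (1.0 + np.cos(np.pi * (idx - peak) / max(length, 1)))
        turning[idx] += env[:, None] * shape[None, :]
        turn_truth[idx] += env * np.abs(shape).sum()

    # continuous low-amplitude steering wobble: an Ornstein-Uhlenbeck
    # modulated mid-body shape, the graded counterpart of discrete turn
    # events — real animals micro-steer constantly, so small turning
    # amplitudes correspond to small real bends, not just sensor noise
    if params.steer_wobble_sd > 0 and params.steer_wobble_tau > 0:
        decay_w = math.exp(-dt / params.steer_wobble_tau)
        drive_sd = params.steer_wobble_sd * math.sqrt(1.0 - decay_w**2)
        ou = lfilter([1.0], [1.0, -decay_w], rng.normal(0.0, drive_sd, n))
        wobble_shape = _turn_shape(rng, center_lo=11, center_hi=11)
        turning = turning + ou[:, None] * wobble_shape[None, :]
        turn_truth = turn_truth + np.abs(ou) * np.abs(wobble_shape).sum()

    angles = angles + turning
    if params.angle_noise_sd > 0:
        angles = angles + rng.normal(0.0, params.angle_noise_sd, size=angles.shape)

    # --- centroid track ---------------------------------------------------
    speed = STRIDE_MM_PER_CYCLE * freq_t * (amp_t / params.undulation_amp)
    speed = np.where(state == PAUSE, 0.0, speed)
    speed = np.where(state == OMEGA, 0.3 * speed, speed)
    # Path curvature is caused by asymmetric mid-body bending: the heading
    # is steered by the (smoothed) turning-mode content of the mid-body
    # segments, so track curvature and turning amplitude are graded with
    # each other as in real crawling. A small independent jitter emulates
    # centroid tracking noise.
    wave = amp_eff[:, None] * np.sin(phi[:, None] - k[None, :] * params.phase_per_segment)
    resid_mid = (angles - wave)[:, 9:14].mean(axis=1)
    w_sm = max(1, int(round(0.5 * fr)))
    resid_mid = np.convolve(resid_mid, np.ones(w_sm) / w_sm, mode="same")
    turn_steer = 8.0  # rad/s of heading change per rad of mid-body turning
    dpsi = turn_steer * resid_mid * dt
    dpsi += rng.normal(0.0, params.heading_noise_sd * math.sqrt(dt), size=n)
    # deep omega bends steer more strongly than their mid-body angle alone
    # suggests (the whole body participates in the reorientation)
    omega_frames = state == OMEGA
    dpsi[omega_frames] *= 2.0
    heading = np.cumsum(dpsi)
    vel = (direction * speed)[:, None] * np.stack([np.cos(heading), np.sin(heading)], axis=1)
    centroid = np.cumsum(vel * dt, axis=0)

    posture = PostureSeries(angles, frame_rate=fr)
    track = Track(centroid, frame_rate=fr, posture=posture)
    labels = StateLabels(state.copy())
    truth = {
        "o2": o2,
        "drive": r,
        "undulation_amp": amp_t,
        "undulation_freq": freq_t,
        "turning_amp": turn_truth,
        "speed": speed * np.abs(direction),
        "heading": heading,
        "phase": phi,
        "phase_crossings": crossings,
        "turn_events": events,
    }
    return SyntheticRecording(posture, track, labels, params, stimulus, coupling, truth)


# ---------------------------------------------------------------------------
# gradient-arena population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NavigationGains:
    """Independently switchable O₂-gradient navigation strategies.

    weathervane_gain
        Steering rate toward the preferred isoline (rad/s at 90° bearing);
        produces a negative curving bias.
    reversal_bias_gain
        Fractional up/down modulation of reversal rate with bearing
        (biased random walk): rate × (1 + g·(B−90°)/90°).
    ars_gain
        Fractional slowing plus extra turning when heading away from the
        preferred isoline (area-restricted-search coupling).
    """

    weathervane_gain: float = 0.0
    reversal_bias_gain: float = 0.0
    ars_gain: float = 0.0

    def __post_init__(self) -> None:
        _require(self.weathervane_gain >= 0, "weathervane_gain", "must be >= 0")
        _require(self.reversal_bias_gain >= 0, "reversal_bias_gain", "must be >= 0")
        _require(self.ars_gain >= 0, "ars_gain", "must be >= 0")


def generate_gradient_population(
    arena,
    n_worms: int,
    gains: NavigationGains | None = None,
    duration: float = 600.0,
    seed: int = 0,
    frame_rate: float = 10.0,
    base_speed: float = 0.15,
    base_reversal_rate: float = 2.0,
    heading_noise_sd: float = 0.15,
    sensory_tau: float = 8.0,
) -> list[Track]:
    """Run-and-turn agents in a linear O₂ gradient arena.

    Each worm crawls at ``base_speed`` (mm/s) with rotational diffusion
    (0.15 rad/√s default, giving the ~1 min heading persistence of
    dispersing food-deprived animals), reverses at a Poisson rate (a
    reversal lasts 2 s and ends in a ~180° reorientation), and reflects off
    the arena walls. The three navigation gains couple bearing to steering,
    reversal rate and speed/turning independently; with all gains zero the
    walker is unbiased. The reversal-rate (biased-random-walk) coupling acts
    through an integrated sensory history — bearing low-pass filtered with
    time constant ``sensory_tau`` — reflecting that reorientation
    probability follows sensory history rather than the instantaneous
    heading.
    """
    from .navigation import GradientArena  # local import to avoid a cycle

    if n_worms < 1:
        raise ValueError("n_worms must be >= 1")
    if arena.length <= 0:
        raise ValueError("arena length must be positive")
    rng = np.random.default_rng(seed)
    gains = gains or NavigationGains()
    dt = 1.0 / frame_rate
    n = int(round(duration * frame_rate))
    rev_len = max(1, int(round(2.0 * frame_rate)))
    x_opt = arena.position_of(arena.optimum)

    ema_alpha = dt / max(sensory_tau, dt)
    tracks: list[Track] = []
    for w in range(n_worms):
        pos = np.empty((n, 2))
        state = np.full(n, FORWARD, dtype=np.int8)
        p = np.array([rng.uniform(0, arena.length), rng.uniform(0, arena.width)])
        psi = rng.uniform(-np.pi, np.pi)
        rev_left = 0
        b_sensed = 90.0
        for i in range(n):
            toward = 0.0 if p[0] == x_opt else math.copysign(1.0, x_opt - p[0])
            # folded bearing in degrees; 0 = toward the optimum isoline
            b = math.degrees(abs(math.atan2(math.sin(psi), math.cos(psi)))) if toward > 0 \
                else math.degrees(abs(math.atan2(math.sin(psi - math.pi), math.cos(psi - math.pi))))
            b_sensed += ema_alpha * (b - b_sensed)
            away = max(0.0, (b - 90.0) / 90.0)
            if rev_left > 0:
                rev_left -= 1
                state[i] = REVERSE
                step_dir = -1.0
                if rev_left == 0:
                    psi += math.pi + rng.normal(0.0, 0.5)
            else:
                rate = base_reversal_rate * (
                    1.0 + gains.reversal_bias_gain * (b_sensed - 90.0) / 90.0)
                if rng.random() < max(rate, 0.0) / 60.0 * dt:
                    rev_left = rev_len
                step_dir = 1.0
                noise_sd = heading_noise_sd * (1.0 + 2.0 * gains.ars_gain * away)
                dpsi = rng.normal(0.0, noise_sd * math.sqrt(dt))
                if gains.weathervane_gain > 0:
                    target = 0.0 if toward > 0 else math.pi
                    dpsi += -gains.weathervane_gain * math.sin(psi - target) * dt
                psi += dpsi
            v = base_speed * (1.0 - 0.5 * gains.ars_gain * away)
            p = p + step_dir * v * dt * np.array([math.cos(psi), math.sin(psi)])
            # reflecting walls
            if p[0] < 0:
                p[0] = -p[0]
                psi = math.pi - psi
            elif p[0] > arena.length:
                p[0] = 2 * arena.length - p[0]
                psi = math.pi - psi
            if p[1] < 0:
                p[1] = -p[1]
                psi = -psi
            elif p[1] > arena.width:
                p[1] = 2 * arena.width - p[1]
                psi = -psi
            pos[i] = p
        margin = arena.edge_margin_mask(pos)
        tracks.append(Track(pos, frame_rate=frame_rate, track_id=w,
                            arena_margin_mask=margin,
                            state_truth=StateLabels(state)))
    return tracks


# ---------------------------------------------------------------------------
# two-channel calcium traces
# ---------------------------------------------------------------------------

def generate_calcium_trace(
    track: Track,
    gain_speed: float = 0.0,
    gain_turn: float = 0.0,
    lag: float = 1.67,
    noise_sd: float = 0.5,
    seed: int = 0,
    frame_rate: float = 30.0,
    turning_amp: np.ndarray | None = None,
    baseline: float = 100.0,
    ref_baseline: float = 50.0,
):
    """Two-channel fluorescence trace coupled to behavior with a fixed lag.

    The reference channel is constant plus noise; the signal channel is
    ``baseline * (1 + gain_speed*speed(t-lag) + gain_turn*turn(t-lag))`` plus
    noise. ``speed`` is taken from the track centroid; ``turning_amp`` may be
    supplied explicitly (e.g. the generator ground truth), else zero.
    """
    from .neuro import CalciumTrace  # local import to avoid a cycle

    if lag < 0:
        raise ValueError("lag must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    tt = track.timestamps
    d = np.linalg.norm(np.diff(track.centroid, axis=0), axis=1)
    speed_track = np.concatenate([d, d[-1:]]) * track.frame_rate
    if turning_amp is None:
        turning_amp = np.zeros(track.n_frames)
    t = np.arange(track.t0, tt[-1], 1.0 / frame_rate)
    sp = np.interp(t - lag, tt, speed_track)
    ta = np.interp(t - lag, tt, turning_amp)
    signal = baseline * (1.0 + gain_speed * sp + gain_turn * ta)
    signal = signal + rng.normal(0.0, noise_sd, size=len(t))
    reference = ref_baseline + rng.normal(0.0, noise_sd, size=len(t))
    return CalciumTrace(timestamps=t, signal_channel=signal,
                        reference_channel=reference, frame_rate=frame_rate)


# the renderer is part of the generator's public surface
from .render import render_worm  # noqa: E402
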