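"""Core data containers shared across the pipeline.

The universal currency is the :class:`PostureSeries` — per-frame 24
inter-segment angles (radians, head to tail) with a validity mask — together
with the :class:`Track` holding the centroid trajectory. Invalid frames carry
NaN angles and are never silently interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import N_ANGLES

# Behavioral-state codes. Exactly one state per frame.
FORWARD, REVERSE, PAUSE, OMEGA, INVALID = 0, 1, 2, 3, 4
STATE_NAMES = {FORWARD: "forward", REVERSE: "reverse", PAUSE: "pause",
               OMEGA: "omega", INVALID: "invalid"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}


@dataclass
class PostureFrame:
    """24 signed inter-segment angles for a single frame (rad, head→tail)."""

    angles: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (N_ANGLES,):
            raise ValueError(f"expected {N_ANGLES} angles, got {self.angles.shape}")
        if self.valid and not np.all(np.isfinite(self.angles)):
            raise ValueError("valid frame must have finite angles")


@dataclass
class PostureSeries:
    """Time series of posture frames on a uniform clock.

    ``angles`` has shape (n_frames, 24); rows where ``valid`` is False are
    NaN. ``timestamps`` are uniform at 1/frame_rate.
    """

    angles: np.ndarray
    frame_rate: float
    valid: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != N_ANGLES:
            raise ValueError(f"angles must be (n, {N_ANGLES}), got {self.angles.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.angles), axis=1)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (len(self.angles),):
                raise ValueError("valid mask length mismatch")
        self.angles = self.angles.copy()
        self.angles[~self.valid] = np.nan

    @property
    def n_frames(self) -> int:
        return len(self.angles)

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate

    def valid_angles(self) -> np.ndarray:
        """Only the valid rows, as a dense (m, 24) array."""
        return self.angles[self.valid]


@dataclass
class StateLabels:
    """Per-frame behavioral state: forward / reverse / pause / omega / invalid."""

    state: np.ndarray
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.int8)
        if not np.all(np.isin(self.state, list(STATE_NAMES))):
            raise ValueError("unknown state code")

    def __len__(self) -> int:
        return len(self.state)

    def as_strings(self) -> np.ndarray:
        return np.array([STATE_NAMES[s] for s in self.state])

    def mask(self, code: int) -> np.ndarray:
        return self.state == code

    def fraction(self, code: int) -> float:
        ok = self.state != INVALID
        if not ok.any():
            return np.nan
        return float((self.state[ok] == code).mean())


@dataclass
class Track:
    """Centroid trajectory of one animal (or track fragment).

    Coordinates in mm, time in seconds. ``arena_margin_mask`` flags frames
    within the configured distance of the arena boundary; such frames are
    excluded from population statistics.
    """

    centroid: np.ndarray
    frame_rate: float
    posture: PostureSeries | None = None
    t0: float = 0.0
    arena_margin_mask: np.ndarray | None = None
    track_id: int = 0
    state_truth: "StateLabels | None" = None

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.ndim != 2 or self.centroid.shape[1] != 2:
            raise ValueError("centroid must be (n, 2)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.arena_margin_mask is None:
            self.arena_margin_mask = np.zeros(len(self.centroid), dtype=bool)
        else:
            self.arena_margin_mask = np.asarray(self.arena_margin_mask, dtype=bool)
        if self.posture is not None and self.posture.n_frames != len(self.centroid):
            raise ValueError("posture and centroid frame counts differ")

    @property
    def n_frames(self) -> int:
        return len(self.centroid)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


@dataclass
class WormImage:
    """A cleaned binary frame containing (at most) one worm."""

    pixels: np.ndarray
    scale: float  # mm per pixel
    timestamp: float = 0.0
    valid: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.scale <= 0:
            raise ValueError("scale must be positive (mm/pixel)")


@dataclass
class Skeleton:
    """26 ordered midline points (mm); index 0 is the head once oriented."""

    points: np.ndarray | None
    valid: bool = True

    def __post_init__(self) -> None:
        if self.points is not None:
            self.points = np.asarray(self.points, dtype=float)
            if self.points.shape != (26, 2):
                raise ValueError("skeleton must have 26 points")
        elif self.valid:
            raise ValueError("valid skeleton requires points")


def sem(values: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Standard error of the mean, ignoring NaNs."""
    values = np.asarray(values, dtype=float)
    n = np.sum(np.isfinite(values), axis=axis)
    sd = np.nanstd(values, axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 1, sd / np.sqrt(n), np.nan)
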