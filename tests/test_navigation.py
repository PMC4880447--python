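"""O₂-gradient chemotaxis: arena geometry, bearing, runs, navigation
statistics and population profiles."""

import numpy as np
import pytest

import wormmodes as wm
from wormmodes.core import FORWARD, REVERSE, StateLabels, Track
from wormmodes.navigation import (
    DistributionProfile,
    GradientArena,
    bearing,
    curving_bias,
    binned_vs_bearing,
    detect_shallow_turn_events,
    o2_at_position,
    population_profile,
    segment_runs,
)


@pytest.fixture(scope="module")
def arena():
    return GradientArena()


# ---------------------------------------------------------------------------
# arena geometry
# ---------------------------------------------------------------------------

def test_o2_map_endpoints_and_midpoint(arena):
    assert o2_at_position(arena, 0.0) == 4.0
    assert o2_at_position(arena, arena.length) == 21.0
    assert o2_at_position(arena, arena.length / 2) == pytest.approx(12.5)
    with pytest.raises(ValueError):
        o2_at_position(arena, -1.0)


def test_profile_bin_width_is_1p3_percent(arena):
    assert arena.o2_bin_width == pytest.approx((21 - 4) / 13)
    assert arena.o2_bin_width == pytest.approx(1.3, abs=0.01)


def test_edge_margin_at_camera_resolution():
    # 20 pixels at 0.0276 mm/px is the 0.55 mm exclusion margin
    assert 20 * 0.0276 == pytest.approx(0.55, abs=0.003)


def test_invalid_arena_rejected():
    with pytest.raises(ValueError):
        GradientArena(length=0.0)
    with pytest.raises(ValueError):
        GradientArena(o2_low=18.0, optimum=16.0)


# ---------------------------------------------------------------------------
# bearing
# ---------------------------------------------------------------------------

def _straight_track(arena, heading_rad, start=(5.0, 7.5), n=300, v=0.15):
    t = np.arange(n) / 10.0
    xy = np.array(start) + np.outer(v * t, [np.cos(heading_rad),
                                            np.sin(heading_rad)])
    return Track(xy, frame_rate=10.0)


@pytest.mark.parametrize("heading,expected", [
    (0.0, 0.0),       # toward the optimum isoline (up-gradient from low side)
    (np.pi, 180.0),   # straight away
    (np.pi / 2, 90.0),  # parallel to isolines
    (-np.pi / 2, 90.0),  # left/right fold
])
def test_bearing_cardinal_directions(arena, heading, expected):
    tr = _straight_track(arena, heading)
    b = bearing(tr, arena)
    mid = b.bearing[50:150]
    assert np.nanmedian(mid) == pytest.approx(expected, abs=2.0)


def test_bearing_reflection_invariance(arena):
    """Mirroring the track across the gradient axis leaves bearing unchanged."""
    rng = np.random.default_rng(0)
    steps = rng.normal(0, 0.02, size=(400, 2)) + [0.01, 0.005]
    xy = np.array([8.0, 7.5]) + np.cumsum(steps, axis=0)
    tr = Track(xy, frame_rate=10.0)
    mirrored = xy.copy()
    mirrored[:, 1] = 15.0 - mirrored[:, 1]
    tr2 = Track(mirrored, frame_rate=10.0)
    b1 = bearing(tr, arena).bearing
    b2 = bearing(tr2, arena).bearing
    m = np.isfinite(b1) & np.isfinite(b2)
    assert np.allclose(b1[m], b2[m], atol=1e-6)


# ---------------------------------------------------------------------------
# run segmentation
# ---------------------------------------------------------------------------

def test_run_filters():
    fr = 10.0
    n = 400
    t = np.arange(n) / fr
    xy = np.stack([0.2 * t, np.zeros(n)], 1)
    tr = Track(xy, frame_rate=fr)
    state = np.full(n, FORWARD, dtype=np.int8)
    # carve out runs: [0,100) 10 s x 2 mm (kept), [110,135) 2.5 s (too short),
    # [150, 400) long (kept)
    state[100:110] = REVERSE
    state[135:150] = REVERSE
    state[110:135] = FORWARD
    runs = segment_runs(tr, StateLabels(state))
    durations = sorted(r.duration_s for r in runs)
    assert len(runs) == 2
    assert durations[0] == pytest.approx(10.0)
    # a slow run displacing < 1 mm is dropped
    xy_slow = np.stack([0.05 * t, np.zeros(n)], 1)  # 5 s fwd = 0.25 mm
    state2 = np.full(n, REVERSE, dtype=np.int8)
    state2[:50] = FORWARD
    assert segment_runs(Track(xy_slow, frame_rate=fr), StateLabels(state2)) == []


# ---------------------------------------------------------------------------
# curving bias
# ---------------------------------------------------------------------------

def test_straight_run_has_zero_bias(arena):
    tr = _straight_track(arena, 0.7, n=600)
    labels = StateLabels(np.zeros(600, dtype=np.int8))
    b = bearing(tr, arena)
    b.restricted[:] = True
    runs = segment_runs(tr, labels)
    s = curving_bias(runs, b, apply_restriction=False)
    assert abs(np.nansum(s.curving_bias_mean)) < 1e-6


def test_arc_toward_optimum_gives_negative_bias(arena):
    """A circular arc steering toward the optimum isoline → negative dB/dX."""
    fr, v, R = 10.0, 0.15, 8.0
    n = 500
    t = np.arange(n) / fr
    # start heading away-ish from optimum on the low side, curving toward it
    theta0 = 2.4  # initial heading (bearing ~ 137 deg)
    theta = theta0 - v * t / R  # turning clockwise toward bearing 0
    xy = np.array([8.0, 7.0]) + np.cumsum(
        v / fr * np.stack([np.cos(theta), np.sin(theta)], 1), axis=0)
    tr = Track(xy, frame_rate=fr)
    labels = StateLabels(np.zeros(n, dtype=np.int8))
    b = bearing(tr, arena)
    b.restricted[:] = True
    s = curving_bias(segment_runs(tr, labels), b)
    assert s.curving_bias_summary < -0.05


# ---------------------------------------------------------------------------
# binned statistics / contrasts
# ---------------------------------------------------------------------------

def test_constant_series_gives_zero_contrast(arena):
    rng = np.random.default_rng(1)
    steps = rng.normal(0, 0.03, size=(3000, 2))
    xy = np.clip(np.array([16, 7.5]) + np.cumsum(steps, 0), 0.6, None)
    xy[:, 0] = np.clip(xy[:, 0], 0.6, 32.4)
    xy[:, 1] = np.clip(xy[:, 1], 0.6, 14.4)
    tr = Track(xy, frame_rate=10.0)
    b = bearing(tr, arena)
    b.restricted[:] = True
    vals = np.full(3000, 3.7)
    edges, means, sems, contrast = binned_vs_bearing(vals, b,
                                                     apply_restriction=False)
    finite = np.isfinite(means)
    assert np.allclose(means[finite], 3.7)
    assert contrast == pytest.approx(0.0, abs=1e-12)


def test_navigation_gains_separate(navigation_matrix):
    """Null within 2 SE; each gain moves its own statistic beyond 3 SE and
    dominates its cross effects (each cross < 25% of the own effect)."""
    own = {"weathervane": "curving_bias",
           "reversal_bias": "reversal_contrast",
           "ars": "speed_contrast"}
    # null ensemble: everything within 2 SE of zero
    for stat, (m, s) in navigation_matrix["null"].items():
        assert abs(m) < 2 * s, f"null {stat} = {m:.4f} ± {s:.4f}"
    own_effect = {}
    for cond, stat in own.items():
        m, s = navigation_matrix[cond][stat]
        assert abs(m) > 3 * s, f"{cond} own effect {stat} only {m / s:.1f} SE"
        own_effect[stat] = abs(m)
    # expected signs: steering toward the optimum, more reversals when
    # heading away, slower when heading away
    assert navigation_matrix["weathervane"]["curving_bias"][0] < 0
    assert navigation_matrix["reversal_bias"]["reversal_contrast"][0] > 0
    assert navigation_matrix["ars"]["speed_contrast"][0] < 0
    # exclusivity: cross effects stay small relative to the dedicated effect
    for cond, own_stat in own.items():
        for stat, (m, s) in navigation_matrix[cond].items():
            if stat == own_stat:
                continue
            assert abs(m) < 0.25 * own_effect[stat], (
                f"{cond} leaks into {stat}: {m:.4f} vs own {own_effect[stat]:.4f}")


def test_uniform_occupancy_without_gains(arena):
    """Gain-0 walkers spread uniformly away from the edges.

    Positions within one track are strongly autocorrelated, so the χ²
    statistic is built from the across-track variability of the per-track
    bin fractions rather than from pooled frame counts.
    """
    from scipy.stats import chi2

    tracks = wm.generate_gradient_population(arena, 20, duration=1000.0,
                                             seed=5)
    nb = 6
    fracs = []
    for t in tracks:
        xs = t.centroid[~t.arena_margin_mask, 0]
        xs = xs[(xs > 3.0) & (xs < 30.0)]
        h, _ = np.histogram(xs, bins=nb, range=(3.0, 30.0))
        fracs.append(h / h.sum())
    fracs = np.array(fracs)
    mean = fracs.mean(axis=0)
    se = fracs.std(axis=0, ddof=1) / np.sqrt(len(fracs))
    stat = float(np.sum(((mean - 1.0 / nb) / se) ** 2))
    p = chi2.sf(stat, df=nb - 1)
    assert p > 0.001


def test_weathervaning_population_approaches_optimum(arena):
    """With only the steering gain on, worms end nearer the 16% isoline."""
    x_opt = arena.position_of(arena.optimum)
    out = {}
    for name, g in [("off", wm.NavigationGains()),
                    ("on", wm.NavigationGains(weathervane_gain=0.15))]:
        tracks = wm.generate_gradient_population(arena, 25, g,
                                                 duration=500.0, seed=8)
        out[name] = np.median([abs(t.centroid[-1, 0] - x_opt) for t in tracks])
    assert out["on"] < out["off"]


# ---------------------------------------------------------------------------
# shallow-turn events vs bearing
# ---------------------------------------------------------------------------

def test_no_events_for_zero_turning(arena, fitted_basis):
    n = 600
    angles = np.tile(fitted_basis.means, (n, 1))
    series = wm.PostureSeries(angles, frame_rate=10.0)
    d = wm.decompose(series, fitted_basis)
    tr = _straight_track(arena, 0.5, n=n)
    b = bearing(tr, arena)
    labels = StateLabels(np.zeros(n, dtype=np.int8))
    res = detect_shallow_turn_events(d, labels, b)
    assert len(res["peak_amplitudes"]) == 0
    assert np.isnan(res["slope"])


def test_injected_turn_peaks_recovered(arena, fitted_basis):
    """Injected mid-body turn bumps of 0.5 rad are found at 0.5 ± 0.05.

    The bump lives in the turning subspace (orthogonal to EW1-2) and is
    scaled so the turning-mode angle #11 peaks at exactly 0.5 rad.
    """
    ew12 = fitted_basis.vectors[:2]
    e11 = np.zeros(24)
    e11[10] = 1.0
    u = e11 - ew12.T @ (ew12 @ e11)
    u *= 0.5 / u[10]
    n = 2000
    angles = np.tile(fitted_basis.means, (n, 1))
    for start in range(100, n - 20, 100):
        env = np.sin(np.linspace(0, np.pi, 11))
        angles[start:start + 11] += np.outer(env, u)
    d = wm.decompose(wm.PostureSeries(angles, frame_rate=10.0), fitted_basis)
    tr = _straight_track(arena, 0.5, n=n, v=0.04)  # stays inside the arena
    b = bearing(tr, arena)
    b.restricted[:] = True
    labels = StateLabels(np.zeros(n, dtype=np.int8))
    res = detect_shallow_turn_events(d, labels, b)
    assert len(res["peak_amplitudes"]) >= 15
    assert np.median(res["peak_amplitudes"]) == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# population profile
# ---------------------------------------------------------------------------

def test_profile_identical_to_control_gives_zero_index(arena):
    counts = np.array([2, 3, 4, 5, 6, 5, 4, 3, 2, 1, 1, 1, 1])
    ctrl = population_profile(counts, arena)
    prof = population_profile(counts, arena, control=ctrl)
    assert np.allclose(prof.index, 0.0)
    assert prof.cumulative_low_o2_index == pytest.approx(0.0)


def test_profile_single_bin():
    arena = GradientArena()
    counts = np.zeros(13)
    counts[4] = 7
    prof = population_profile(counts, arena)
    assert prof.bin_fractions[4] == 1.0
    assert prof.bin_fractions.sum() == pytest.approx(1.0)


def test_profile_index_sums_to_zero_when_complete(arena):
    rng = np.random.default_rng(3)
    ctrl = population_profile(rng.integers(1, 10, 13).astype(float), arena)
    prof = population_profile(rng.integers(1, 10, 13).astype(float), arena,
                              control=ctrl)
    assert prof.index.sum() == pytest.approx(0.0, abs=1e-12)


def test_profile_geometry_mismatch_rejected(arena):
    ctrl = population_profile(np.ones(13), arena)
    other = GradientArena(o2_low=0.0, optimum=10.0, o2_high=21.0)
    with pytest.raises(ValueError, match="geometry"):
        population_profile(np.ones(13), other, control=ctrl)


def test_avoidance_population_has_negative_low_o2_index(arena):
    """Worms steering toward 16% deplete the low-O₂ bins relative to the
    gain-0 control population."""
    ctrl_tracks = wm.generate_gradient_population(arena, 30, duration=400.0,
                                                  seed=11)
    grad_tracks = wm.generate_gradient_population(
        arena, 30, wm.NavigationGains(weathervane_gain=0.2),
        duration=400.0, seed=11)
    ctrl = population_profile(
        np.array([t.centroid[-1] for t in ctrl_tracks]), arena)
    prof = population_profile(
        np.array([t.centroid[-1] for t in grad_tracks]), arena, control=ctrl)
    assert prof.cumulative_low_o2_index < 0
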