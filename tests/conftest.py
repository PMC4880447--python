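"""Shared fixtures: small synthetic ensembles reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import wormmodes as wm
from wormmodes.geometry import N_ANGLES


def smooth_random_posture(rng: np.random.Generator) -> np.ndarray:
    """One random posture from the generator's smoothness class.

    A traveling-wave shape with random amplitude and phase plus a random
    smooth turning bump, rescaled so |angle| <= 0.4 rad. Per-segment white
    noise is deliberately absent: midline wiggles finer than the body width
    are not recoverable from a silhouette.
    """
    k = np.arange(N_ANGLES)
    amp = rng.uniform(0.1, 0.3)
    phase = rng.uniform(0, 2 * np.pi)
    ang = amp * np.sin(phase - k * 0.4)
    c = rng.integers(6, 18)
    sd = rng.uniform(2.0, 4.0)
    ang = ang + rng.uniform(-0.15, 0.15) * np.exp(-0.5 * ((k - c) / sd) ** 2)
    m = np.abs(ang).max()
    if m > 0.4:
        ang *= 0.4 / m
    return ang


@pytest.fixture(scope="session")
def default_ensemble() -> list[wm.SyntheticRecording]:
    """Six 300 s recordings with generator defaults (fixed seeds)."""
    return [wm.generate_posture_series(wm.KinematicParams(seed=i), duration=300.0)
            for i in range(6)]


@pytest.fixture(scope="session")
def fitted_basis(default_ensemble) -> wm.EigenwormBasis:
    return wm.fit_eigenworms([r.posture for r in default_ensemble])


@pytest.fixture(scope="session")
def default_decompositions(default_ensemble, fitted_basis):
    return [wm.decompose(r.posture, fitted_basis) for r in default_ensemble]


@pytest.fixture(scope="session")
def roundtrip_errors() -> np.ndarray:
    """Absolute angle errors of the render→binarize→skeleton→angles loop.

    100 random smooth postures rendered at 0.004 mm/pixel; rows are frames,
    columns the 24 angle positions.
    """
    from wormmodes.geometry import angles_from_points, points_from_angles
    from wormmodes.posture import angles_from_skeleton, clean_binarize, extract_skeleton

    rng = np.random.default_rng(7)
    scale = 0.004
    errs = []
    for _ in range(100):
        ang = smooth_random_posture(rng)
        img = wm.render_worm(ang, scale=scale)
        img = clean_binarize(img.pixels, scale=scale)
        sk = extract_skeleton(img)
        assert sk.valid, "roundtrip frame unexpectedly invalid"
        true_pts = points_from_angles(
            ang, centroid=(img.pixels.shape[1] * scale / 2,
                           img.pixels.shape[0] * scale / 2))
        pts = sk.points
        if (np.linalg.norm(pts[0] - true_pts[0])
                > np.linalg.norm(pts[-1] - true_pts[0])):
            pts = pts[::-1].copy()
        frame = angles_from_skeleton(wm.Skeleton(pts))
        assert frame.angles.shape == (24,)
        errs.append(np.abs(frame.angles - ang))
    return np.array(errs)


@pytest.fixture(scope="session")
def detector_scores(default_ensemble, default_decompositions):
    """Event-level (n_true, n_detected, n_hits) per behavioral-state detector,
    measured against the generator ground truth on the default ensemble."""
    from wormmodes import locomotion as loco
    from wormmodes.core import OMEGA, PAUSE, REVERSE

    def point_match(true_on, det_on, tol):
        used, hits = set(), 0
        for t in true_on:
            for j, d in enumerate(det_on):
                if j not in used and abs(d - t) < tol:
                    hits += 1
                    used.add(j)
                    break
        return hits

    def interval_match(true_on, events, pad=1.0, dur=1.0):
        used, hits = set(), 0
        for t in true_on:
            for j, (a, b) in enumerate(events):
                if j not in used and a - pad < t + dur and b + pad > t:
                    hits += 1
                    used.add(j)
                    break
        return hits

    scores = {"reversal": [0, 0, 0], "pause": [0, 0, 0], "omega": [0, 0, 0]}
    for rec, d in zip(default_ensemble, default_decompositions):
        fr = rec.posture.frame_rate
        ts = rec.truth_labels.state
        _, rev = loco.detect_reversals(rec.track, d)
        true_rev = np.flatnonzero(np.diff((ts == REVERSE).astype(int)) == 1) / fr
        scores["reversal"][0] += len(true_rev)
        scores["reversal"][1] += rev.n_events
        scores["reversal"][2] += point_match(true_rev, rev.onsets, 1.5)

        speed = loco.centroid_speed(rec.track)
        pl = loco.detect_pauses(speed, fr)
        true_p = np.flatnonzero(np.diff((ts == PAUSE).astype(int)) == 1) / fr
        det_p = np.flatnonzero(np.diff((pl.state == PAUSE).astype(int)) == 1) / fr
        scores["pause"][0] += len(true_p)
        scores["pause"][1] += len(det_p)
        scores["pause"][2] += point_match(true_p, det_p, 2.0)

        om = loco.detect_omega_turns(rec.track)
        events = list(zip(om.onsets, om.onsets + om.durations))
        true_o = np.flatnonzero(np.diff((ts == OMEGA).astype(int)) == 1) / fr
        scores["omega"][0] += len(true_o)
        scores["omega"][1] += len(events)
        scores["omega"][2] += interval_match(true_o, events)
    return scores


@pytest.fixture(scope="session")
def null_resampling_pvalues():
    """p-values of the resampling variance test under label exchangeability:
    200 simulated nulls at n_iter = 200."""
    from wormmodes.core import PostureSeries
    from wormmodes.eigenmodes import variance_resampling_test

    rng = np.random.default_rng(10)
    k = np.arange(N_ANGLES)
    pool = []
    for _ in range(8):
        t = np.arange(60) / 10.0
        ang = 0.3 * np.sin(2 * np.pi * 0.45 * t[:, None] - k[None, :] * 0.4
                           + rng.uniform(0, 2 * np.pi))
        ang += rng.normal(0, 0.05, ang.shape)
        pool.append(PostureSeries(ang, frame_rate=10.0))
    ps = []
    for i in range(200):
        idx = rng.permutation(8)
        ga = [pool[j] for j in idx[:4]]
        gb = [pool[j] for j in idx[4:]]
        _, p = variance_resampling_test(ga, gb, n_iter=200, seed=1000 + i)
        ps.append(p)
    return np.array(ps)


@pytest.fixture(scope="session")
def navigation_matrix():
    """Summary statistics for null/weathervane/reversal-bias/ARS ensembles.

    Returns {condition: {statistic: (mean, sem)}} for 20 tracks x 500 s per
    condition at the canonical seed.
    """
    from wormmodes import locomotion as loco
    from wormmodes import navigation as nav

    arena = nav.GradientArena()
    conditions = {
        "null": wm.NavigationGains(),
        "weathervane": wm.NavigationGains(weathervane_gain=0.15),
        "reversal_bias": wm.NavigationGains(reversal_bias_gain=1.5),
        "ars": wm.NavigationGains(ars_gain=0.8),
    }
    out = {}
    for name, gains in conditions.items():
        tracks = wm.generate_gradient_population(arena, 20, gains,
                                                 duration=500.0, seed=0)
        curving, revc, speedc = [], [], []
        for tr in tracks:
            b = nav.bearing(tr, arena)
            labels = tr.state_truth
            runs = nav.segment_runs(tr, labels)
            if runs:
                s = nav.curving_bias(runs, b)
                if np.isfinite(s.curving_bias_summary):
                    curving.append(s.curving_bias_summary)
            _, _, c1 = nav.reversal_rate_by_bearing(labels, b, tr.frame_rate)
            if np.isfinite(c1):
                revc.append(c1)
            sp = loco.centroid_speed(tr)
            fm = nav.forward_mask(labels, tr.frame_rate)
            _, _, _, c2 = nav.binned_vs_bearing(sp, b, valid_mask=fm)
            if np.isfinite(c2):
                speedc.append(c2)

        def ms(x):
            x = np.asarray(x)
            return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))

        out[name] = {"curving_bias": ms(curving),
                     "reversal_contrast": ms(revc),
                     "speed_contrast": ms(speedc)}
    return out
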