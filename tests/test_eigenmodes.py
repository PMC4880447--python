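"""Eigenworm basis, mode decomposition, phase velocity, cross-correlation
and the resampling variance test."""

import numpy as np
import pytest
from scipy.signal import periodogram
from scipy.stats import kstest

import wormmodes as wm
from wormmodes.core import PostureSeries
from wormmodes.eigenmodes import (
    EigenwormBasis,
    amplitude,
    average_crosscorrelation,
    mode_crosscorrelation,
    orient_forward,
    turn_onset_lag_estimate,
    variance_resampling_test,
)


# ---------------------------------------------------------------------------
# basis fitting
# ---------------------------------------------------------------------------

def test_fitted_vectors_are_orthonormal(fitted_basis):
    v = fitted_basis.vectors
    assert np.allclose(v @ v.T, np.eye(24), atol=1e-10)
    f = fitted_basis.variance_fractions
    assert np.all(np.diff(f) <= 1e-12)
    assert f.sum() == pytest.approx(1.0, abs=1e-9)


def test_rank_two_input_concentrates_variance():
    rng = np.random.default_rng(0)
    u = rng.normal(size=(2, 24))
    coeff = rng.normal(size=(2000, 2))
    series = PostureSeries(coeff @ u, frame_rate=10.0)
    basis = wm.fit_eigenworms([series])
    assert basis.cumulative_variance(2) == pytest.approx(1.0, abs=1e-9)


def test_insufficient_frames_rejected():
    series = PostureSeries(np.zeros((500, 24)), frame_rate=10.0)
    with pytest.raises(ValueError, match="insufficient"):
        wm.fit_eigenworms([series])


def test_basis_invariant_to_series_order(default_ensemble):
    a = wm.fit_eigenworms([r.posture for r in default_ensemble])
    b = wm.fit_eigenworms([r.posture for r in default_ensemble[::-1]])
    assert np.allclose(a.variance_fractions, b.variance_fractions, atol=1e-10)
    assert np.allclose(np.abs(a.vectors), np.abs(b.vectors), atol=1e-8)


def test_sign_flipped_basis_gives_identical_decomposition(default_ensemble,
                                                          fitted_basis):
    """Downstream results do not depend on arbitrary eigenvector signs."""
    flipped = EigenwormBasis(
        vectors=fitted_basis.vectors * np.where(np.arange(24)[:, None] % 2, -1, 1),
        means=fitted_basis.means,
        variance_fractions=fitted_basis.variance_fractions,
        n_frames=fitted_basis.n_frames)
    s = default_ensemble[0].posture
    d1 = wm.decompose(s, fitted_basis)
    d2 = wm.decompose(s, flipped)
    assert np.allclose(d1.undulation.angles[s.valid],
                       d2.undulation.angles[s.valid], atol=1e-10)
    assert np.allclose(np.abs(d1.phase_velocity[np.isfinite(d1.phase_velocity)]),
                       np.abs(d2.phase_velocity[np.isfinite(d2.phase_velocity)]),
                       atol=1e-8)


def test_basis_text_roundtrip(fitted_basis, tmp_path):
    path = tmp_path / "basis.txt"
    fitted_basis.save(path)
    loaded = EigenwormBasis.load(path)
    assert np.allclose(loaded.vectors, fitted_basis.vectors, atol=1e-9)
    assert np.allclose(loaded.means, fitted_basis.means, atol=1e-9)
    assert loaded.n_frames == fitted_basis.n_frames


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def test_additivity_exact(default_ensemble, default_decompositions):
    for rec, d in zip(default_ensemble, default_decompositions):
        v = rec.posture.valid
        resid = (d.undulation.angles[v] + d.turning.angles[v]
                 - rec.posture.angles[v])
        assert np.abs(resid).max() < 1e-10


def test_mean_posture_decomposes_to_zero_turning(fitted_basis):
    n = 50
    series = PostureSeries(np.tile(fitted_basis.means, (n, 1)), frame_rate=10.0)
    d = wm.decompose(series, fitted_basis)
    assert np.abs(d.turning.angles).max() < 1e-10
    assert np.allclose(d.undulation.angles, fitted_basis.means, atol=1e-10)


def test_posture_in_wave_subspace_has_zero_turning(fitted_basis):
    rng = np.random.default_rng(1)
    coeff = rng.normal(size=(100, 2))
    angles = fitted_basis.means + coeff @ fitted_basis.vectors[:2]
    d = wm.decompose(PostureSeries(angles, frame_rate=10.0), fitted_basis)
    assert np.nanmax(d.turning_amp) < 1e-10


def test_dimension_mismatch_rejected(fitted_basis):
    bad = PostureSeries(np.zeros((10, 24)), frame_rate=10.0)
    bad.angles = np.zeros((10, 12))
    with pytest.raises(ValueError):
        wm.decompose(bad, fitted_basis)


# ---------------------------------------------------------------------------
# amplitude
# ---------------------------------------------------------------------------

def test_amplitude_basic_values():
    assert amplitude(np.zeros(24)) == 0.0
    assert amplitude(np.full(24, 0.1)) == pytest.approx(2.4)
    assert np.isnan(amplitude(np.full(24, np.nan)))


def test_amplitude_of_traveling_wave_matches_mean_abs_sine():
    """Time-mean of sum|A sin| equals 24*A*mean|sin| (numerical oracle)."""
    A, f, fr = 0.2, 0.45, 10.0
    t = np.arange(0, 600, 1 / fr)
    k = np.arange(24)
    angles = A * np.sin(2 * np.pi * f * t[:, None] - k[None, :] * 0.4)
    measured = amplitude(angles).mean()
    oracle = 24 * A * np.abs(np.sin(np.linspace(0, 2 * np.pi, 100000))).mean()
    assert measured == pytest.approx(oracle, rel=0.02)
    assert oracle == pytest.approx(24 * A * 2 / np.pi, rel=1e-3)


# ---------------------------------------------------------------------------
# phase velocity
# ---------------------------------------------------------------------------

def test_phase_velocity_of_exact_rotation():
    f, fr = 0.3, 10.0
    t = np.arange(0, 60, 1 / fr)
    proj = np.stack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)], 1)
    pv = wm.phase_velocity(proj, fr)
    interior = pv[5:-5]
    assert np.allclose(interior[np.isfinite(interior)], f, atol=1e-6)


def test_phase_velocity_antisymmetric_under_time_reversal():
    rng = np.random.default_rng(2)
    t = np.arange(0, 60, 0.1)
    proj = np.stack([np.cos(2 * t) + 0.05 * rng.normal(size=len(t)),
                     np.sin(2 * t) + 0.05 * rng.normal(size=len(t))], 1)
    pv = wm.phase_velocity(proj, 10.0)
    pv_rev = wm.phase_velocity(proj[::-1], 10.0)
    # pv[t] is the step t -> t+1, so reversal maps step t to step n-2-t
    a, b = pv[:-1], -pv_rev[::-1][1:]
    m = np.isfinite(a) & np.isfinite(b)
    assert np.allclose(a[m], b[m], atol=1e-9)


def test_phase_velocity_recovers_generator_frequency(fitted_basis):
    params = wm.KinematicParams(seed=11, undulation_freq=0.45)
    rec = wm.generate_posture_series(params, duration=120.0)
    d = wm.decompose(rec.posture, fitted_basis)
    assert np.nanmedian(d.phase_velocity) == pytest.approx(0.45, abs=0.02)


def test_phase_velocity_matches_spectrogram_peak():
    """Dual-route check: rotation-rate magnitude vs periodogram peak."""
    params = wm.KinematicParams(seed=3, angle_noise_sd=0.0, reversal_rate=0,
                                pause_rate=0, omega_rate=0, turn_event_rate=0,
                                steer_wobble_sd=0)
    rec = wm.generate_posture_series(params, duration=120.0)
    basis = wm.fit_eigenworms([rec.posture])
    d = wm.decompose(rec.posture, basis)
    freq, power = periodogram(d.proj[:, 0], fs=params.frame_rate)
    f_peak = freq[np.argmax(power)]
    assert np.nanmedian(np.abs(d.phase_velocity)) == pytest.approx(f_peak,
                                                                   rel=0.05)


def test_orient_forward_flips_backward_dominated_series():
    pv = np.array([-0.4, -0.5, -0.45, 0.1, -0.4])
    assert np.all(orient_forward(pv)[:3] > 0)


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def test_crosscorr_identity_peaks_at_zero():
    rng = np.random.default_rng(3)
    x = rng.normal(size=2000)
    lags, corr, peak, lag = mode_crosscorrelation(x, x, max_lag=2.0,
                                                  frame_rate=10.0)
    assert peak == pytest.approx(1.0, abs=1e-9)
    assert lag == 0.0


def test_crosscorr_recovers_imposed_shift():
    rng = np.random.default_rng(4)
    x = np.convolve(rng.normal(size=3000), np.ones(5) / 5, mode="same")
    shift = 6  # 0.6 s at 10 frames/s
    y = np.roll(x, shift)
    _, _, peak, lag = mode_crosscorrelation(x, y, max_lag=2.0, frame_rate=10.0)
    assert lag == pytest.approx(0.6, abs=1e-9)
    assert peak > 0.95


def test_crosscorr_null_bound_for_independent_noise():
    rng = np.random.default_rng(5)
    x = rng.normal(size=10000)
    y = rng.normal(size=10000)
    _, _, peak, _ = mode_crosscorrelation(x, y, max_lag=2.0, frame_rate=10.0)
    assert abs(peak) < 0.1


def test_crosscorr_rejects_constant_signal():
    with pytest.raises(ValueError, match="constant"):
        mode_crosscorrelation(np.ones(1000), np.arange(1000.0), 2.0, 10.0)


def test_average_crosscorr_discards_short_tracks():
    rng = np.random.default_rng(6)
    long_pair = (rng.normal(size=500), rng.normal(size=500))
    short_pair = (rng.normal(size=50), rng.normal(size=50))
    lags, mean, err, _, _ = average_crosscorrelation(
        [long_pair, short_pair], max_lag=2.0, frame_rate=10.0)
    assert np.all(np.isnan(err))  # only one track survived the 20 s rule
    with pytest.raises(ValueError):
        average_crosscorrelation([short_pair], max_lag=2.0, frame_rate=10.0)


def test_turn_onset_lag_recovered(default_ensemble, default_decompositions):
    """Turn transients lag the undulation cycle by 0.6 s (one-frame tol)."""
    lags = [turn_onset_lag_estimate(d) for d in default_decompositions]
    assert np.all(np.abs(np.array(lags) - 0.6) <= 0.1 + 1e-9)


# ---------------------------------------------------------------------------
# resampling variance test
# ---------------------------------------------------------------------------

def _wave_series(rng, n_frames=200, turn=False):
    """Wave posture series; with ``turn`` an extra fixed third spatial mode
    oscillates, giving the group a consistently rank-3 variance spectrum."""
    k = np.arange(24)
    t = np.arange(n_frames) / 10.0
    ang = 0.3 * np.sin(2 * np.pi * 0.45 * t[:, None] - k[None, :] * 0.4
                       + rng.uniform(0, 2 * np.pi))
    if turn:
        u3 = np.exp(-0.5 * ((k - 11) / 3.0) ** 2)
        ang = ang + (0.25 * np.sin(2 * np.pi * 0.7 * t[:, None]
                                   + rng.uniform(0, 2 * np.pi)) * u3[None, :])
    ang += rng.normal(0, 0.05, ang.shape)
    return PostureSeries(ang, frame_rate=10.0)


def test_identical_groups_give_zero_statistic():
    rng = np.random.default_rng(7)
    group = [_wave_series(rng) for _ in range(4)]
    stat, p = variance_resampling_test(group, list(group), n_iter=100, seed=0)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == 1.0


def test_distinct_groups_reach_the_resolution_bound():
    """Turning-dominated vs wave-only groups: zero exceedances at 1000 iter.

    Group sizes are large enough that a random permutation essentially never
    recreates the original split, so the reported upper bound is the
    resolution limit 1/n_iter.
    """
    rng = np.random.default_rng(8)
    ga = [_wave_series(rng, n_frames=100) for _ in range(12)]
    gb = [_wave_series(rng, n_frames=100, turn=True) for _ in range(12)]
    stat, p = variance_resampling_test(ga, gb, n_iter=1000, seed=1)
    assert stat > 0
    assert p == pytest.approx(1e-3)


def test_small_groups_rejected():
    rng = np.random.default_rng(9)
    with pytest.raises(ValueError):
        variance_resampling_test([_wave_series(rng)], [_wave_series(rng)],
                                 n_iter=100)


def test_null_p_values_are_uniform(null_resampling_pvalues):
    """Under label exchangeability p is uniform on {1/n .. 1}.

    200 simulated nulls at n_iter = 200; Kolmogorov-Smirnov against the
    uniform reference (p takes values k/200, so a small shift slack is
    allowed).
    """
    stat = kstest(null_resampling_pvalues, "uniform").statistic
    assert stat < 0.12


def test_canonical_basis_ships_and_matches_defaults():
    """The packaged canonical basis loads, is orthonormal, and spans the
    same wave subspace as a freshly fitted default-ensemble basis."""
    cb = wm.canonical_basis()
    assert np.allclose(cb.vectors @ cb.vectors.T, np.eye(24), atol=1e-8)
    assert cb.cumulative_variance(4) > 0.85
    recs = [wm.generate_posture_series(wm.KinematicParams(seed=900 + i),
                                       duration=60.0) for i in range(5)]
    fresh = wm.fit_eigenworms([r.posture for r in recs])
    # overlap of the two 2-D wave subspaces
    overlap = np.linalg.svd(cb.vectors[:2] @ fresh.vectors[:2].T,
                            compute_uv=False)
    assert overlap.min() > 0.99
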