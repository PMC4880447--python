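"""Couple a ratiometric calcium trace to behavior and recover the lag.

Generates a two-channel fluorescence trace whose signal channel follows
locomotion speed with a 1.67 s lag, normalizes it to dR/R, and estimates
the lag and the activity–speed correlation back from the data.
"""

import numpy as np

import wormmodes as wm
from wormmodes.neuro import binned_activity_vs_behavior, lag_estimate, normalize_ratio

rec = wm.generate_posture_series(wm.KinematicParams(seed=4), duration=240.0)
trace = wm.generate_calcium_trace(rec.track, gain_speed=3.0, lag=1.67,
                                  noise_sd=0.3, seed=0)
# this trace is clean by construction; for contaminated recordings run
# wormmodes.neuro.exclude_artifacts with per-cell ArtifactRules first
trace = normalize_ratio(trace)

disp = np.linalg.norm(np.diff(rec.track.centroid, axis=0), axis=1)
speed = np.concatenate([disp, disp[-1:]]) * rec.track.frame_rate
speed30 = np.interp(trace.timestamps, rec.track.timestamps, speed)

lag, at_boundary = lag_estimate(trace.dR_over_R, speed30, max_lag=5.0,
                                frame_rate=trace.frame_rate)
print(f"valid frames: {int(trace.valid.sum())}/{trace.n_frames}")
print(f"recovered activity-speed lag: {lag:.2f} s (generator lag 1.67 s)")

# align the two series at the recovered lag before correlating, as one
# would when quantifying graded speed encoding
speed_aligned = np.interp(trace.timestamps - lag, trace.timestamps, speed30)
res = binned_activity_vs_behavior(trace, speed_aligned, bin_width=0.01)
print(f"per-recording correlation r = {res['r']:.2f} over "
      f"{res['n_blocks']} half-second blocks (lag-aligned)")

# dR/R = (R - mean R)/mean R with R the signal/reference ratio; the
# cross-correlation peak recovers the built-in coupling delay to within a
# frame, and the binned relation shows the graded speed encoding.
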