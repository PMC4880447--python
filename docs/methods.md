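# Methods

## Posture representation

A posture is 24 signed inter-segment angles (radians, head → tail) between
the 25 segments of a 26-point midline resampled to equal arc length. The
sign convention (which bending direction is positive) is consistent within
a recording but arbitrary across recordings — nothing in the image fixes
dorsoventral identity — so every cross-recording statistic uses absolute
values or is sign-symmetric. Invalid frames (failed segmentation, coils)
carry NaN and are never interpolated.

## Eigenworm decomposition

The eigenworm basis is the eigendecomposition of the covariance of the 24
angles over all valid frames of a set of recordings, eigenvectors ordered
by decreasing variance, signs fixed by making each vector's first non-zero
component positive. Angles are centered per segment both when fitting the
covariance and when projecting; the alternative of centering only at
projection time changes nothing material because the generator's per-angle
means are near zero, but centering in both places keeps the basis a true
PCA.

The undulation mode is the per-angle means plus the projection of the
centered angles onto EW1–2; the turning mode is the residual, which is
identically the EW3–24 reconstruction. Adding the means back to *both*
modes would double-count them and break additivity, so they are added to
the undulation mode only; `undulation + turning = posture` then holds to
machine precision and is asserted in the tests at 1e-10.

**Phase and phase velocity.** The projections (a₁, a₂) are smoothed with a
0.5 s moving average (the window is a package choice; any value well below
the ~2.2 s undulation period works), the phase is accumulated from
per-step smallest-angle increments, and the phase velocity is the step
rotation rate in cycles/s. Frames whose projection magnitude falls below
20% of the series median are masked: the wave is genuinely absent there
(deep coils suspend the undulation, so the phase would be noise — this
threshold is what keeps coiled frames from producing phantom reversals).
The rotation sense of (a₁, a₂) for forward crawling depends on arbitrary
eigenvector signs, so the per-series sign is normalized to make the median
velocity positive, which encodes the empirical fact that animals crawl
forward most of the time; the low-level `phase_velocity` function stays
raw (antisymmetric under time reversal) and the convention is applied by
`orient_forward` / `decompose`.

**Resampling variance test.** The statistic is |Σₖ (cumA_k − cumB_k)|, the
absolute summed difference of the two groups' cumulative variance-fraction
curves from per-group PCA; the null shuffles series-level group labels
preserving group sizes. The reported p is the upper bound
`max(#exceedances, 1)/n_iter`, i.e. the resolution limit 1/n_iter when no
permutation reaches the observed statistic. Under exchangeability the
p-values are uniform on {1/n … 1} (verified by simulation in the tests).
Note that with small groups a random permutation occasionally recreates
the original split exactly (probability 2/C(n, n/2) per draw), so
zero-exceedance claims need group sizes for which that is negligible.

## Image → skeleton → angles

Cleaning: threshold (if grayscale), morphological closing, speck removal,
hole filling; frames whose cleaned mask does not contain exactly one
connected component are invalid. The midline is the morphological skeleton
reduced to the longest endpoint-to-endpoint path on the 8-connected
skeleton-pixel graph (branch trimming); a cycle in that graph means the
silhouette self-touches — the coiled postures of deep omega bends — and
the frame is invalid rather than guessed. The ordered pixel path is
resampled to 400 points and smoothed with two Savitzky–Golay passes whose
windows are fixed in physical units (0.12 mm then 0.06 mm of arc length,
order 2), then resampled to the 26 points. Frames whose skeleton is
shorter than 60% of the running-median length are segmentation failures
and invalidated. Head assignment starts from the movement direction at the
track start and is propagated by endpoint proximity, falling back to the
direction rule during flagged omega frames.

**Validated accuracy.** On 100 random smooth postures (random wave phase
and amplitude plus a random smooth turning bump, |angle| ≤ 0.4 rad)
rendered at 0.004 mm/px, the render → binarize → skeleton → angles loop
recovers angles with RMS error ≈ 0.03 rad and worst-case single-angle
error ≈ 0.11–0.15 rad; at the 0.0129 mm/px of typical multi-worm cameras
the RMS is ≈ 0.06 rad. Two limits are worth knowing. First, a silhouette
cannot encode midline wiggles finer than the body width: per-segment
white-noise angles are unrecoverable *at any resolution* (the medial axis
low-passes them), so the accuracy statement applies to the smoothness
class real worms and the generator produce. Second, the worst-case error
is boundary-noise limited: the medial axis jitters with structure at the
width scale, which cannot be smoothed away without biasing genuine bends.
The tests assert the validated bounds (RMS < 0.05, max < 0.2).

## The synthetic generator

The generator defines the study conditions; its defaults are fixed once
and describe an unstimulated, 1 hr food-deprived adult at 10 frames/s:

| parameter | default | why |
|---|---|---|
| undulation amplitude | 0.35 rad/segment | mean body amplitude ≈ 5.3 rad |
| undulation frequency | 0.45 cycles/s | crawl frequency off food |
| spatial phase/segment | 0.4 rad | ≈1.5 body wavelengths |
| shallow-turn rate / bend | 6 min⁻¹ / 2.0 rad summed | frequent micro-reorientation |
| turn-onset lag | 0.6 s | turns phase-locked behind the undulation cycle |
| reversal rate / duration | 2 min⁻¹ / 2 s | sparse spontaneous reversals |
| pause rate / duration | 1 min⁻¹ / 2.5 s | above the 2 s pause-detection floor |
| omega rate / bend | 1 min⁻¹ / 6.5 rad summed | full-circle coils |
| steering wobble | OU, sd 0.3 rad, τ 1 s | continuous micro-steering |
| angle noise | 0.03 rad | segmentation noise |
| coupling | turn ×(1+r), undulation ÷(1+0.5 r), τ 90 s | reciprocal O₂ response |

Design points that were genuinely open:

- **Turn shapes.** Shallow turns and the steering wobble are single-lobed
  Gaussian bumps (sd 2.5 segments) normalized by summed bend; omegas are
  broad near-uniform curls (Hann profile over the whole body, 6.5 rad ≈ a
  full circle) with the wave suspended for the event's second. Single
  lobes were chosen over bumps orthogonalized against the wave subspace:
  orthogonalization manufactures two-lobed S-curls that are geometrically
  confusable with omega coils, whereas real shallow turns are C-bends that
  project partly onto EW1–2 — as the decomposition of real data also
  shows. Only omegas therefore coil (midline-cloud eccentricity < ~0.5
  versus > ~0.55 for everything else), which is what makes
  eccentricity-based omega detection work.
- **Turn phase-locking.** Bump peaks are placed a fixed 0.6 s after the
  nearest positive maximum of the mid-body undulation angle — an
  *observable* reference event, so the lag can be measured back by
  cross-correlating the detected undulation-peak train with the turning
  amplitude (the raw wave phase has an arbitrary offset in any fitted
  basis and would not support a defined lag).
- **Track coupling.** The heading is steered by the smoothed mid-body
  turning residual (path curvature is *caused* by asymmetric bending),
  plus a small independent jitter for centroid-tracking noise; speed is
  proportional to frequency × amplitude. This produces the graded
  curvature-vs-turning-amplitude and speed-vs-frequency relations (rank
  correlation ≈ 0.7 and r > 0.9 on 0.5–2 s blocks).
- **Stimulus response.** The O₂ drive is a leaky integrator of downshifts
  (unit jump for 21→10%, decay τ = 90 s), giving monophasic, reciprocal,
  gradually recovering modulation of the two modes. Under the 21→4% ramp
  the drive equilibrates near 0.77 rather than the step value, so
  ramp-evoked changes are gradual and moderate — the turning-amplitude
  distribution skews right by tail growth (mass above 1 rad roughly
  doubles) while its median barely moves. Third-moment skewness is not a
  monotone readout for such event mixtures (it scales like p^(−1/2) once
  events dominate the variance), so the tests track the tail quantile.
- **Gradient-arena agents** are centroid-level run-and-turn walkers
  (speed 0.15 mm/s, rotational diffusion 0.15 rad/√s ⇒ ~45 s heading
  persistence, reflecting walls). The three navigation strategies are
  independently switchable gains: steering toward the preferred isoline
  (weathervaning), bearing-modulated reversal rate acting through a
  sensed bearing integrated with τ = 8 s (reorientation follows sensory
  history, not the instantaneous heading — this also decorrelates the
  run-censoring selection effect from instantaneous bearing
  fluctuations), and bearing-modulated slowing plus extra turning (ARS).

## Behavioral-state detection

- **Reversals**: phase velocity below −0.1 cycles/s sustained ≥ 0.3 s
  (phase noise during pauses stays well above −0.1; genuine backward
  crawling sits near −0.45). A centroid-only angular-velocity fallback
  exists for tracks without posture and flags its labels low-confidence.
- **Pauses**: speed < 0.05 mm/s for ≥ 2 s, merging sub-1 s gaps.
- **Omega turns**: midline point-cloud eccentricity < 0.6 together with
  body-axis angular speed > 2.5 rad/s, co-occurring within ±0.7 s and
  sustained ≥ 0.3 s. The angular speed is the rotation rate of the point
  cloud's major axis (π-periodic), not of the centroid-path heading — the
  centroid barely moves during an omega, so path heading misses
  slow-translation reorientations. Thresholds were calibrated on
  synthetic injected events; on the default ensemble all three detectors
  reach sensitivity and precision ≥ 0.9 (reversals and pauses ≈ 1.0,
  omegas ≈ 0.98).

## Navigation statistics

Bearing folds the angle between the 1 s-smoothed centroid heading and the
direction toward the 16% isoline into [0°, 180°]; frames within 0.55 mm of
the arena edge, below the speed floor, or (by default) outside the sub-16%
post-settling region are excluded. Curving bias dB/dX pools per-frame
bearing change over path length within forward runs (≥3 s, ≥1 mm, with
1 s trimmed at each run edge because the smoothed heading spans the
boundary), and each step is attributed to *both* its endpoint bearings
with half weight: endpoint-only attribution has a spurious drift away from
the fold boundaries for a diffusing heading (verified on a pure-diffusion
simulation), which symmetric attribution cancels without touching genuine
steering. The summary scalar averages 40°–150°. Reversal rate versus
bearing uses the bearing 1 s before each onset, normalized by forward
occupancy per bin — bearing during and just after a reversal reflects the
flipped movement direction, not the decision context. Trials with under
30 s of occupancy on either side of 90°, or under 100 frames in the
summary range, report missing rather than noise.

Two weak cross-couplings between strategies are genuine physics, not
estimator defects: bearing-dependent reversal hazard censors runs in a way
that slightly inflates apparent curving bias (~20% of the weathervaning
effect at strong gain), and bearing-dependent turning noise has an Itô
drift toward the calmer side (~10%) — bearing-modulated turning *is* a
steering mechanism. The separation tests therefore require each gain's own
statistic beyond 3 SE with cross effects bounded relative to it.

## Calcium traces

dR/R (%) = (R − mean R)/mean R with R the signal/reference channel ratio
and the mean over valid frames, so the valid-frame mean of dR/R is zero by
construction. Artifact exclusion (reference drops > 30% of a 1 s rolling
median; |R − median| > 5 MAD; frame-to-frame jumps > 8 MAD of the typical
step) only ever removes frames. The MAD rules assume artifacts are rare
relative to the dynamics; on traces whose genuine behavioral modulation
spans a wide range they can clip real excursions, which is why they are
per-recording configurable rather than hard-wired. Event-triggered
averages use a ±8 s window (configurable within the conventional 6–10 s);
activity peaks are found on a 0.5 s-smoothed trace with prominence ≥ 2× the
raw-trace MAD. Lag estimation takes the peak of the activity/behavior
cross-correlation (positive = activity lags behavior) and flags peaks at
the search boundary.

## Problem sizes and determinism

Default test and acceptance problem sizes — 6 × 300 s recordings for the
ensemble fixtures, 50 × 60 s for basis-coverage runs, 20 × 500 s tracks
per navigation condition, 100 frames for the rendering roundtrip, 200
simulated nulls at 200 permutations for p-value calibration — were chosen
as the smallest ensembles at which the tested effects sit far from their
thresholds; all randomness flows from explicit integer seeds and every
generator is bit-reproducible under a fixed seed.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
a low-dimensional wave, phase-locked single-lobed turning transients,
exclusive behavioral states with Poisson scheduling, reciprocal monophasic
stimulus coupling, independently switchable navigation strategies, and
lag-coupled fluorescence. Passing tests therefore demonstrate that the
estimators recover known structure of this kind at realistic noise — they
do not demonstrate performance on real video, where segmentation faces
touching animals, uneven illumination and genuine coil-frame dropouts,
where turn shapes vary far more than a Gaussian-bump family, and where
behavioral states are not cleanly exclusive. The rendering roundtrip in
particular certifies the midline tracer only for silhouettes produced by
this package's own body model (length and width tables are package data).

## Known limitations

- No biomechanics: speed is imposed, not generated from thrust.
- No multi-animal collision handling; tracks are single fragments.
- Dorsoventral sign is arbitrary per recording; signed-bend statistics
  across recordings are meaningless by design.
- The omega detector's features (eccentricity, axis rotation) are tuned to
  this generator's coil geometry; real silhouette-based detection also
  exploits self-overlap, which midline point clouds cannot see.
- The worst-case rendering-roundtrip angle error (~0.12 rad) exceeds its
  RMS (~0.03 rad) by the boundary-noise floor discussed above.
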