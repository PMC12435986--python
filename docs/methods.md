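# Methods

This note documents the models and procedures implemented in `kinesig`, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Signal model and preprocessing

A trial is a fingertip trajectory on a table plane: x, y horizontal (mm),
z vertical, sampled nominally at 480 Hz, starting and ending at a fixed
*home point*. Preprocessing mirrors standard hand-kinematics practice:

- **Zero-lag Butterworth low-pass.** An overall fourth-order filter applied
  forward and backward (two second-order passes) at the source rate, then
  decimation to 120 Hz (every k-th sample for integer rate ratios, linear
  interpolation onto the uniform grid otherwise). The cutoff frequency is a
  mandatory analysis choice; the default of **10 Hz** is conventional for
  gross hand movement, where voluntary content lies below ~8 Hz. We use
  `scipy.signal.filtfilt` with Gustafsson edge handling, which (unlike
  default padding) makes the filter exactly time-reversal symmetric — a
  property the test suite checks at 1e-9.
- **Gap handling.** Missing samples are flagged, never silently filled:
  leading/trailing missing samples are trimmed, interior runs are linearly
  interpolated *for filtering only* and stay flagged in the output. A trial
  is excluded when any flagged run on its 120 Hz grid is strictly longer
  than 12 samples (100 ms). The inequality is strict: a 12-sample run is
  retained.
- **Displacement outliers.** Within each participant, the distribution of
  maximal horizontal displacement from home is formed over all trials
  (conditions and sessions pooled — the pooling scope is configurable), and
  trials strictly below mean − 3·SD (sample SD) are removed, each together
  with its counterpart in the other condition. Trials whose counterpart was
  already lost (e.g. to the gap rule) are removed too; this *balance
  guarantee* means the retained design is always paired, at the price of
  roughly doubling the exclusion rate.

## Speed profile and temporal features

All temporal features are computed from the horizontal 2D speed
v(t) = |d(x, y)/dt|, obtained by central differences and smoothed by a
**Kolmogorov-Zurbenko filter** (iterated centered moving average) with
window 2 and 3 iterations. For an even window the kernel sits on a
half-sample boundary; the package's normative contract is the effective
interior impulse response [1, 3, 3, 1]/8, with edges renormalized over the
overlapping kernel part so constants pass unchanged.

- **Dimensionless jerk.** `J = ∫ x‴(t)² dt · D³ / max(v)²`, where x‴ is the
  *second* time-derivative of the speed series (equivalently the third
  derivative of arc-length position), D the recording span, and the
  integral is trapezoidal. Only this reading makes J exactly unit-free; a
  component-wise position-jerk variant was considered and rejected because
  the temporal features are defined on the 1D speed profile. Smoothing is
  applied to v before differentiation. Because the raw index is long-tailed
  it is reported on the natural-log scale. Numerical care: the jerk series
  uses a three-point central second-difference with four-point second-order
  one-sided boundary stencils — naive first-order boundary formulas bias
  the integral of a short movement by several percent because jerk peaks at
  movement onset and offset. A unit minimum-jerk stroke (quintic profile,
  1 mm, 1 s) has the closed-form value 720/1.875² = 204.8; the
  implementation reproduces it to 0.03% at 120 Hz.
- **Sample entropy.** SampEn(m = 2, r = 0.2·SD, τ = 1) in nats: −log(A/B)
  with B the number of template pairs of length m within Chebyshev distance
  r (self-matches excluded), A the same for m + 1, both over the index
  range for which the longer template exists. SD is the *sample* SD
  (n − 1), matching the standard R reference implementation, against which
  the test suite checks numerical equality; an O(n²) explicit-loop oracle
  checks exactness to 1e-12.
- **Strokes, holds, rhythmicity.** Strokes are maxima of the smoothed speed
  found by `scipy.signal.find_peaks` with prominence ≥ 5% of the trial's
  peak speed and ≥ 100 ms separation (both configurable and reported);
  holds are maximal spans with v below a threshold. The threshold default
  is **15 mm/s**: the movement literature quotes "15 meters per second",
  which is physically implausible for fingertip motion recorded in
  millimeters, so the package reads it as 15 recording-units per second and
  logs the active value. Rhythmicity is −log(sample SD) of the
  inter-event intervals — stroke-peak to stroke-peak, and hold onset to
  hold onset (onsets chosen over offsets/midpoints; configurable) — so
  higher means more isochronous. A zero SD (perfect isochrony) is clamped
  at one sample period (1/120 s) and flagged. Natural logarithms
  throughout.
- **Spatial features.** Maximal covered area is the rectangle spanned by
  the maximal |x − x₀| and |y − y₀| excursions from home (mm²); degenerate
  single-axis motion gives 0.

## DTW alignment

Each communicative trial (query) is aligned onto its non-communicative
partner (reference) in home-centered x–y coordinates — positions, not
speeds, and not z-normalized, so distances stay in millimeters. The dynamic
program uses the symmetric step pattern with diagonal weight 2 (first cell
weight 1) and Euclidean local cost; the accumulated cost is normalized by
N + M, the only normalization consistent with that pattern. Backtracking
breaks ties deterministically: diagonal first, then the step that advanced
the reference. No window constraint and no endpoint relaxation. The
**warping cost** is the mean over the optimal path of (query index −
reference index), averaged over path pairs (a per-reference-sample variant
exists behind a flag for sensitivity analysis); its sign convention —
positive = query stretched — is fixed by construction and verified against
exhaustive path enumeration on small instances.

## Mixed-model inference

Per feature: fixed effects group × condition in treatment coding
(reference: speaker, non-communicative), so the interaction coefficient is
the signer-minus-speaker difference of condition shifts. Random effects are
fitted by REML over an explicit, deterministically descended ladder,
maximal first:

1. participant + item + **pair** intercepts, condition slopes over
   participants and items (independent variances);
2. drop the item condition-slope;
3. intercepts only (participant + item + pair);
4. participant + item; 5. participant only.

The **pair intercept** (participant × item × session × trial) is part of
the maximal structure because the two conditions of a trial pair share the
item's spatial path: their features are correlated beyond what participant
and item intercepts capture, and omitting the pair term grossly inflates
the SE of condition contrasts (the type-I calibration study fails without
it). A rung is abandoned only on optimizer failure; boundary (singular)
fits are kept and reported, so zero true variances are estimated as ≈ 0
rather than forcing a simpler model.

Estimation is a dense variance-components REML fit (Σ = σ²I + Σₖ σₖ²ZₖZₖᵀ,
log-variance parametrization, Nelder-Mead with a Powell fallback), suited
to the data sizes here (hundreds to a few thousand rows). Denominator
degrees of freedom use the **Satterthwaite** approximation computed from
the numerical curvature of the REML criterion; Kenward-Roger is the
preferred method in the field and every report states which was used. On
balanced designs of the sizes used here the two agree within a few percent
— the test suite verifies both the Satterthwaite df (≤ 1%) and the
Kenward-Roger df (≤ 5%) against `lmerTest`/`pbkrtest` on a reference fit,
and fixed-effect estimates against both `lme4` and `statsmodels`. p-values
are Bonferroni-multiplied by the declared family size (default 7, the
number of kinematic outcomes) and deliberately not capped at 1, so the
correction stays invertible. Post-hoc within-group condition contrasts use
the same machinery with family size 2. DTW outcomes (one value per pair)
are modeled with a group fixed effect and participant/item intercepts, plus
per-group one-sample t-tests of the warping cost against zero
(df = n − 1 over trial pairs).

## Synthetic data: what it emulates, what it does not

`kinesig.synthetic` generates trajectories as chains of planar
**minimum-jerk submovements** (quintic displacement profiles — the
canonical smooth-movement primitive, chosen for its closed-form speed bells
and jerk integrals) along a piecewise-linear path that starts and, for
chains of ≥ 2 strokes, returns to the home point. Between strokes the hand
holds still: holds are exact zero-velocity spans, so hold detection works
at any threshold once noise is filtered. Inter-stroke onset intervals are
Gaussian with configurable mean and SD; isotropic Gaussian position noise
is added in the table plane; the height channel is constant (the analyses
are table-planar). Condition pairs share geometry and interval draws: the
communicative member's timeline is scaled by a stretch factor and its
interval SD and noise SD are shifted by deltas. Cohorts apply log-normal
multiplicative participant- and item-level perturbations (positivity, and
the long right tail that motivates the log transforms) to durations and
amplitudes. Artifacts (missing-sample runs, collapsed-displacement
outliers) are injected on demand.

Defaults describe a plausible tabletop movement — 4 strokes of 120 mm and
0.35 s at one stroke per 0.7 s (interval SD 0.08 s), 0.4 mm sensor noise,
480 Hz — and the default *study conditions* give speakers stretch 1.4 with
+0.06 s interval SD and +0.3 mm noise in the communicative condition, and
signers stretch 0.8 with −0.04 s and −0.2 mm. No published per-condition
duration distributions exist to calibrate against, so these are free
parameters chosen once for qualitative realism, not calibrated claims.

The generator does **not** emulate: arm biomechanics or 3D posture,
handshape, the specific path shapes of any real stimulus set, speed-arc
coupling, or autocorrelated sensor noise. Passing tests therefore establish
that the pipeline recovers structure *of the kind the generator produces* —
signed temporal stretch, interval variability, noise-driven roughness —
with correct calibration; they do not certify effect sizes on real
recordings.

## Simulation studies and problem sizes

The validation studies run at sizes chosen to exercise the crossed design
while keeping the whole suite desk-scale: sign-pattern recovery uses 50
cohorts of 4 + 4 participants × 3 items; type-I calibration uses 500 null
cohorts of 6 + 6 × 4 (the interaction test's rejection rate at nominal 5%
must land in [3%, 7%]); CI coverage of an injected interaction (β = −2)
uses 100 simulated feature tables on the same design, since a trajectory
generator cannot inject an exact coefficient into a nonlinear feature.
These studies feed the 120 Hz generator output directly to the feature
stage (it is gap-free and uniformly sampled, i.e. already in preprocessed
form); the end-to-end pipeline runs, including filtering and exclusions,
are exercised separately.

## Known limitations

- Kenward-Roger df are approximated by Satterthwaite (reported as such);
  for the balanced synthetic designs the difference is negligible, for
  severely unbalanced real data it may not be.
- The REML fitter is dense and O(n³) in observations; it is comfortable to
  a few thousand rows but not designed for very large corpora.
- Random-effect structures are limited to independent variance components
  (no intercept-slope covariances); the ladder encodes the documented
  simplifications rather than a general formula language.
- The hold-threshold unit reading (mm/s) and the Butterworth cutoff are
  analysis choices surfaced in configuration and logs, not facts about any
  particular dataset.
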