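# Methods

This note documents the models and procedures implemented in `tugpcm`, the
assumptions behind them, the parameters that matter, and what the synthetic
cohorts do and do not establish.

## Task and signals

A Timed Up and Go (TUG) trial is represented as a bundle of synchronized
100 Hz series: three-plane joint angles for trunk, hip, knee and ankle
(degrees), whole-body centre-of-mass (CoM) position on the AP/ML/vertical
axes (m), vertical ground reaction force (GRF) from a seat plate and a
chair plate (N), heel-marker anteroposterior velocity and left/right
shoulder-marker mediolateral velocities (m/s). Angle and CoM series are
assumed to be precomputed by upstream motion-capture modelling; marker-level
processing is out of scope. The lab convention is AP = walking direction
positive, ML = leftward positive, vertical = up; sample indexing is 0-based
and time = index / rate.

## Event detection

The five subphases are delimited by six events:

* **T0 (initiation)** — first sample with seat GRF at or below
  `mean − k·SD` of the leading baseline. `baseline_window` = 0.5 s,
  `baseline_k` = 2. With a degenerate (zero-variance) baseline the
  comparison is strict, otherwise every baseline sample would satisfy it.
* **T1 (heel-off)** — global maximum of the smoothed heel AP velocity in a
  window of `heel_search_window` = 3 s after T0; the cap prevents later
  gait-cycle maxima from capturing the event. The event definition exists
  in an anteroposterior and a vertical variant in the literature; the AP
  variant is implemented (the recorded schema carries that channel).
* **T2 / T3 (turn bounds)** — first zero crossing of the smoothed CoM ML
  velocity after T1; then the next crossing at which the CoM AP position is
  within `turn_distance_threshold` = 0.7 m of the turning target. The
  "target" is taken to be the 3 m line's AP coordinate — a declared
  convention; the source procedure does not fix it.
* **T4 (gait-to-turn)** — first sample after T3 where the left/right
  shoulder ML velocity difference is within `shoulder_equalize_tol`
  (0.02 m/s) *and* changes sign within ±2 samples; the sign-change
  condition rejects grazing contact with the tolerance band.
* **T5 (end)** — first chair-plate GRF deflection beyond `mean ± k·SD` of
  that plate's own leading baseline.

Velocity channels are low-pass filtered before detection with a zero-phase
Butterworth filter (order 4, cut-off 6 Hz — the common biomechanics choice;
both configurable). Zero crossings are sign changes between consecutive
samples, reported at the first sample of the new sign; exact zeros inherit
the previous sign; all ties break to the earliest index. CoM velocity is
obtained from position with the same derivative operator used for features
(`np.gradient` × rate: central differences inside, one-sided at the edges).

Durations follow as successive event differences over the sampling rate;
the total (T5 − T0)/rate telescopes to the sum of the five phases exactly.

## Feature set

For each of the 5 phases: ROM and angular-velocity range for 4 joints × 3
planes (120 variables) and CoM displacement and velocity range on 3 axes
(30 variables) — every value a max − min over the half-open phase window.
All features are therefore non-negative, invariant to additive channel
offsets, and exactly |c|-homogeneous under channel scaling. Multiple trials
per subject are averaged feature-wise (the aggregation used by the original
protocol, which recorded three valid trials, is not documented; averaging
is the neutral choice). Laterality is not modelled: one angle series per
joint is consumed.

The extreme-outlier screen flags values beyond `Q3 + 3·IQR` (and below
`Q1 − 3·IQR`), quartiles by linear interpolation (type 7); an IQR of zero
flags nothing. The screen reports per-subject, per-phase counts for manual
review — exclusion is a decision, not an automatism.

## Principal-component models

PCA is run on the correlation matrix so each variable contributes equally.
Suitability is screened by the Kaiser–Meyer–Olkin statistic
(`KMO = Σr² / (Σr² + Σq²)` over off-diagonal elements, with q the
anti-image partial correlations from the inverse correlation matrix;
required > 0.5) and Bartlett's sphericity test
(`χ² = −(n−1−(2p+5)/6)·ln det R`, df = p(p−1)/2; required p < 0.05).
Components with eigenvalue strictly greater than 1 are retained (a tie at
exactly 1.0 is excluded) and rotated by Varimax with Kaiser row
normalization; the rotation is computed by the SVD fixed-point iteration
followed by planar (pairwise) sweeps, which guards against the SVD
iteration stalling short of a local optimum. Rotated components are ordered
by explained variance (sum of squared loadings) and sign-fixed so each
component's largest-magnitude loading is positive.

Variable selection mirrors the published procedure: variables with a
rotated loading above 0.8 on some component are "retained"; while any
retained variable has a communality (row sum of squared loadings) below
0.800, the lowest-communality variable *among the offending retained set*
is removed and the model refitted. Restricting the removal pool to the
high-loading set follows the procedure's own arithmetic (the variables
excluded for low communality were drawn from those with loadings > 0.8);
a global lowest-communality cascade was tried and found to dismantle the
very structure the selection is meant to distil. The adequacy screen gates
the initial fit only; refits inside the loop are not re-gated, though the
final model reports its own KMO/Bartlett values.

The task-level PCM pools the variables retained across the five phase
models and refits (eigenvalue > 1, Varimax) without further pruning.
Whether adequacy should be re-screened after pooling is not specified by
the source procedure; the pooled model computes and reports the statistics
but does not gate on them (with more variables than subjects they are
reported as NaN).

Component scores use the regression (Thompson) method on the rotated
solution — `W = R⁻¹Λ`, scores = standardized data × W — the common default
of mainstream statistical software; fitted-sample score means are zero by
construction. A pseudo-inverse substitutes when the pooled correlation
matrix is numerically singular.

## Group statistics

Functional disability is ≥2 of: poor self-reported health; handgrip below
27 kg (men) / 16 kg (women); one-leg stance < 10 s; Barthel < 20;
Lawton < 23. The rule is monotone in every indicator.

Normality is screened with Shapiro–Wilk for the smaller group and the
Lilliefors-corrected Kolmogorov–Smirnov test for the larger (Shapiro for
both when the larger group is under the Lilliefors minimum of four);
parametric comparisons use the pooled-variance t, non-parametric ones the
Mann–Whitney U (reported as min(U₁,U₂); exact enumeration when the pooled
sample is ≤ 12 without ties, tie-corrected normal approximation otherwise).
2×2 tables use the Pearson chi-square, with Yates continuity correction
behind a flag that defaults to off — the published statistics are
internally mixed on this point (three match the uncorrected form, the
fall-history value matches the corrected form), so both are available and
the packaged count fixtures record which form each printed value matches.
Cohen's d uses the pooled SD, with the normal-approximation interval
`d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)))`. Component-score comparisons
are Mann–Whitney throughout and, matching the source analysis, unadjusted
for multiplicity (a Holm column is available behind a flag).

## Synthetic cohorts

The generator exists because cohort data of this kind are private: it
emulates the *statistical conditions* of the study, not biomechanical
waveform realism, and every downstream claim the test suite makes about
real data is conditional on that.

What it emulates:

* **Phase durations** per group — truncated normal draws (±2.5 SD) using
  the published per-phase group means and SDs; the disability group is
  slower in every phase, most detectably in sit-to-walk, walk-forward and
  walk-back.
* **Event signatures** — a 1 s quiet-sitting baseline then exact, known
  event times: fast seat-GRF drop at T0, heel-velocity global maximum at
  T1, one-signed CoM ML drift lobes guaranteeing exactly one zero crossing
  at T2 and at T3 (with the AP position inside the 0.7 m gate), a steep
  shoulder-difference crossing at T4, chair-plate loading at T5. Lobe
  onsets fade in smoothly: step onsets would make the zero-phase detector
  filter ring and forge crossings.
* **A known 11-factor structure** over the features. Per subject, eleven
  standard-normal latents drive clusters of amplitude knobs (loading 0.94
  at knob level; the clusters follow the published component descriptions —
  proximal sagittal drive across walking/turning, per-phase
  tri-dimensional trunk velocity, turn-phase knee frontal/transverse
  motion, mediolateral CoM excursion, and so on — each padded to at least
  four indicators). Non-indicator features share one broad per-phase
  background factor (loading 0.55), which keeps the phase KMO statistics
  in a realistic range without the background variables crossing the 0.8
  loading gate. Between-subject amplitude variation has CV 0.25.
* **Group effects** — the sagittal-drive cluster scales with the profile's
  mean hip sagittal ROM (defaults differ by 0.6 within-group SD per
  variable) and trunk velocity amplitudes scale with a group factor
  (0.90 for the disability group).
* **Disability indicators** constructed to satisfy the ≥2-of-5 rule
  exactly, so the classifier must reproduce the generated labels.

Mechanics worth knowing because they were *forced* by the downstream
procedure, not free choices:

* ROM and velocity-range of a channel/phase have separate knobs: a wide
  raised-cosine excursion carries the ROM, with width proportional to
  amplitude over the *nominal* phase duration (so its peak velocity is
  independent of both amplitude and the subject's realized duration), and
  a narrow fixed-width wiggle at the excursion peak carries the velocity
  range. Coupled knobs would flood the phase models with near-duplicate
  pairs; realized-duration widths would stamp a common 1/duration
  component onto all velocity features of a phase.
* Indicator loadings must exceed √0.8 ≈ 0.894 at the feature level: the
  selection pipeline removes high-loading variables whose communality
  (≈ squared loading) falls below 0.800, so weaker planted structure is
  destroyed by the very procedure under test. The defaults land realized
  phase-model loadings in the 0.85–0.95 band of the published solution.
* Factors need ≥4 indicators: one- or two-indicator factors are routinely
  lost to eigenvalue > 1 retention or a single communality exclusion at
  the study's sample size.

What it does not emulate: marker-level anthropometrics, gait-cycle
waveform detail, EMG, within-subject learning across trials (multiple
trials are independent redraws), missing data, or falls. Passing tests
demonstrate that the pipeline recovers *known* structure under the study's
sample sizes and noise levels — not that real TUG kinematics contain that
structure.

## Numerical choices

* Angle noise is band-limited (2nd-order Butterworth, 2.5 Hz) white noise,
  SD 0.5° by default; CoM position noise 2 mm, ML velocity noise 1 mm/s.
  Range features read noise extremes, so noise bandwidth matters more than
  amplitude.
* Varimax converges when the criterion gain falls below 1e-6 or after 100
  iterations, then polishes with ≤50 pairwise sweeps.
* Eigenvalues are clipped at zero before the √λ scaling of loadings.
* Correlation matrices with a condition number above 1e12 are treated as
  singular for KMO.
* Tucker's congruence (used in tests) is |Σxy|/√(Σx²Σy²) per matched
  component. At n = 60 a sample Varimax solution carries irreducible
  cross-loading noise (~0.3–0.5 summed squared loadings per component
  spread over non-member variables), which caps per-factor congruence
  against an idealized pattern near 0.95; whole-solution recovery is
  therefore summarized by the *mean* matched-factor congruence.

## Limitations

* The segmentation rules assume the generator's (and the original
  protocol's) signal conventions; instrumented trials with different plate
  placement or axis conventions need remapping at the TSV layer.
* The published solution reports 59 high-loading variables, 21 exclusions
  and a 38-variable task model, while its printed loading table has 30
  rows; the packaged fixture carries the 30 printed rows and the count
  mismatch is left as-is.
* C3D input is not supported; angle/CoM channels must be exported to the
  documented TSV schema upstream.
* With one CPU-scale cohorts (n = 60) the pooled model's minor components
  beyond the planted structure are sampling-dependent; only the exact
  fixture-based statistics are deterministic reproductions.
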