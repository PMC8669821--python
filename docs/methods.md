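# Methods

`mobifof` implements an end-to-end digital-mobility analysis of fear of
falling (FOF) in Parkinson's disease from a single 6-axis inertial sensor
worn on the lower back: supervised lab tests (timed-up-and-go, TUG, and
five-times-sit-to-stand, 5xSTS), multi-day free-living monitoring, and
the group-comparison / classification / lab-versus-home statistics built
on top. Because no patient data are available, a synthetic cohort
generator with full ground-truth annotation stands in for the study
population; every downstream stage is validated against that ground
truth.

## The synthetic cohort

Each subject is a `PhenotypeSpec`: clinical covariates (FES-I total,
UPDRS-III, gender, body mass, height) and generative mobility targets —
the two preferred daily gait speeds V_mu1 < V_mu2 (m/s) and their mixing
weight, lab turn peak angular velocity (deg/s), sit-to-stand vertical
peak power (W), expected walking-bout counts per day for the short /
medium / long classes, sit-to-stand and turn rates (per hour), and wear
time per day (h). Defaults are chosen to place the FOF− group at the
scale of a moderately impaired PD cohort (V_mu1 ≈ 0.63, V_mu2 ≈ 0.96 m/s,
lab turn ω ≈ 160 deg/s, home sit-to-stand power median ≈ 20 W, ~48
retained bouts/day, ~4.5 sit-to-stands/h, ~100 turns/h, 12 h wear/day).

Group effects (`GroupEffectConfig`) shift FOF+ means relative to FOF−.
The default pattern reproduces the qualitative and approximate
quantitative effect-size profile the analysis is designed to detect:
a large lab turning deficit (−40 deg/s against 18 deg/s between-subject
scatter, standardised effect ≈ 2), a moderate first-mode gait-speed
deficit (−0.07 m/s against 0.10), and mild reductions of bout counts
(×0.87), transition and turn rates. Daily-life turning is submaximal, so
only a fraction (`home_omega_transfer`, default 0.25) of the lab turning
deficit carries into home turning, which also gets its own scatter —
this produces the characteristic capacity-versus-performance gap in
which lab parameters separate the groups more strongly than home
parameters.

### Signal model

Signals are schematic but kinematically consistent; they contain exactly
the structure the detectors need and are not biomechanically validated
gait synthesis:

* **Postural transitions** — a minimum-jerk vertical trunk displacement
  whose height is solved (Brent root-finding) so that the true vertical
  peak power `max m·(a_v+g)·v_v` equals the drawn target, plus a
  forward-and-back trunk-pitch excursion (22° peak) on the
  medio-lateral gyro axis. With this power convention the gravity term
  dominates, so printed W values on the scale of ~10–70 W correspond to
  small peak vertical velocities.
* **Turns** — a `sin²` yaw-rate pulse about the body vertical whose
  integral is the signed turn angle; home turn peak velocities are drawn
  log-normally (σ = 0.36) to give the long right tail of free-living
  turning, with angles uniform in 50–200° and durations confined to
  0.5–10 s.
* **Gait** — vertical and antero-posterior oscillation at the step
  frequency `f = 1.35 + 0.5·v` (clamped to 0.6–3.2 steps/s). The
  vertical displacement amplitude is set by inverting the
  inverted-pendulum step model `SL = 2√(2ℓh − h²)` with pendulum length
  ℓ = 0.53 × height, so true speed, cadence and vertical excursion are
  mutually consistent. Per-second speeds are drawn around the
  subject's bout mode (mode 1 with the mixing weight, else mode 2) with
  0.08 m/s jitter, floored at 0.25 m/s.

Gravity appears on the vertical accelerometer axis (+9.81 m/s² at rest);
the sensor frame is rotated by a random static tilt (default ≤ 8°) and
white Gaussian noise is added (accelerometer 0.04 m/s², gyro 0.4 deg/s —
typical in-band MEMS figures). Lab sessions are sampled at 128 Hz, home
days at 100 Hz (the home device's rate is configurable since it is not
fixed by the protocol). Wear is contiguous within a day (no off-body
gaps); day lengths jitter ±3%. All randomness flows from one seed via
`numpy.random.SeedSequence` spawning.

Because cohort-scale raw signals are enormous (26 subjects × 14 days ×
12 h at 100 Hz ≈ 10⁹ samples), cohort statistics run on a
**timeline-only fast path**: the generator's ground-truth event
timelines are converted to event tables directly, while the raw-signal
path (synthesis + detection) is exercised on short recordings by the
recovery studies. The two paths share all aggregation and statistics
code; the lab timeline path applies the same event arithmetic as the
signal path.

## Event detection

* **Vertical axis** — low-pass (0.25 Hz) gravity averaged over quiescent
  epochs (gyro magnitude < 5 deg/s, ‖acc‖ within 0.5 m/s² of g); falls
  back to the whole-recording mean with a warning. Horizontal anatomical
  axes come from the declared sensor mounting, re-orthogonalised against
  the estimated vertical.
* **Walking bouts** — band-pass (0.5–3 Hz) step-frequency energy on the
  vertical and AP acceleration, 1-s RMS gating at 0.15 m/s²; per-second
  speed from AP-peak step timing and the pendulum model on the
  drift-corrected double-integrated vertical displacement (two 0.3-Hz
  high-pass stages); seconds below 0.2 m/s removed (inclusion uses ≥);
  surviving contiguous runs under 15 s discarded. Cadence outside
  0.4–3.5 steps/s flags the second unreliable (NaN → excluded by the
  gate). The per-second grid is anchored at the bout start and the final
  partial second is dropped. All intervals are half-open [start, end).
* **Postural transitions** — segmented on the trunk-pitch-rate RMS
  envelope (0.25 s window, 4 deg/s threshold, compensating the window's
  edge smear), validated by a ≥ 10° integrated pitch excursion; the
  kind follows the sign of the dominant vertical velocity
  (drift-corrected to rest at the window edges); peak power is
  `m·(a_v+g)·v_v` maximised over the event. The power formula is fixed
  as mechanical lifting power with gravity included; it is
  self-consistent between generator and detector.
* **Turns** — yaw rate low-passed at 3 Hz; events where |yaw| exceeds
  15 deg/s, extended to a 5 deg/s exit or sign change with the locally
  quadratic tail extrapolated to its zero (capped at 2 s), same-direction
  fragments merged across ≤ 0.2 s gaps; retained when the integrated
  angle exceeds 45° and the duration lies in 0.5–10 s. Turns are
  detected regardless of walking or sedentary context.

Recovery on seeded synthetic days (18-min wear windows at unchanged
event rates, which keeps the raw-signal volume tractable): bout, turn
and sit-to-stand sensitivity and precision are ≥ 0.9 at 50%-overlap
matching, and the mean absolute relative errors of speed, peak angular
velocity and peak power are within 15%, 10% and 20%. The error of the
peak power is reported as an aggregate because events drawn near the
physiological floor (~5–10 W) are ill-conditioned for a per-event
relative bound — the velocity noise floor of a few mm/s is a fixed
absolute error.

## Lab tests

TUG: the first sit-to-stand gives t_b,SiSt and P_TUG; the two turns give
ω_TUG,1 and ω_TUG,2 (and t_e,Turn2); the stand-to-sit gives t_e,StSi;
the total time is the event-bounded formula
`T_TUG = max(t_e,StSi, t_e,Turn2) − t_b,SiSt` (asserted as an identity
on every result). V_TUG,avg averages all per-second speeds of the
locomotion phases between the sit-to-stand and the test end; including
turning seconds is the chosen reading of "mean gait speed of the whole
test" (the walking-only alternative differs by < 5% on synthetic
sessions). 5xSTS: total time runs from the first sit-to-stand onset to
the completion of the fifth rise, and the mean peak power averages the
five per-cycle values; a cycle count other than five is a structured
failure. Lab recordings carry segment markers written by the simulator;
auto-segmentation of unmarked real sessions is out of scope.

## Daily-life aggregation

Days with under 6 h of measurement are discarded ("less than 6 h", so
exactly 6 h is retained); a subject with no valid day is a structured
failure. Retained bouts are classed SWB [15, 30) s, MWB [30, 60) s,
LWB ≥ 60 s — half-open so the classes partition. Per-day walking percent
uses the day's recorded duration as denominator. Min/avg/max summarise
per-day values over valid days; pooled distributions (per-second speed
overall and per class, sit-to-stand peak power, turn peak angular
velocity) stack all days and report the median and 95th percentile by
linear interpolation (tested against an explicit sorting oracle). Speed
distributions pool per-second samples, not per-bout means, for all
classes.

The two modes of the pooled speed distribution come from a
two-component Gaussian mixture (free variances) fitted by EM with ten
quantile-spread initialisations at a fixed seed; pools above 4000
samples are thinned by even subsampling of the sorted sample
(order-independent, mode-preserving). A fit is degenerate — both modes
then fall back to the histogram mode, flagged — when a component weight
is below 0.05, the means are closer than 0.05 m/s, or the fitted mixture
density has no dip between the means (a genuinely unimodal sample
otherwise splits into two overlapping components).

The feature set per subject comprises 32 home parameters (V_ALL and
per-class P50/P95, V_mu1/V_mu2, walking-percent min/avg/max overall and
per class, P_H and ω_H P50/P95, sit-to-stand and turn per-hour
min/avg/max) plus nine lab parameters — 41 mobility parameters in all.
Feature-set invariants (min ≤ avg ≤ max, P50 ≤ P95, V_mu1 ≤ V_mu2,
percents in [0, 100]) are asserted at assembly.

## Statistics

FOF+ is defined by FES-I > 19 (strict). The effect size is
r = Z/√N from the rank-sum statistic (mid-ranks, tie-corrected variance,
no continuity correction), signed positive when FOF+ tends larger;
bands small/medium/large at 0.1/0.3/0.5. Each mobility parameter is
adjusted for gender (0 = male, 1 = female) and UPDRS-III in a
maximum-likelihood logistic regression of group membership; the Wald p
of the parameter coefficient is reported, with complete separation,
non-convergence and collinearity flagged instead of a spurious p. No
multiple-testing correction is applied; the number of tests run is
reported alongside.

Feature selection screens |r| > 0.2 and then backward-eliminates against
leave-one-subject-out (LOSO) accuracy: each round drops the feature
whose removal yields the highest accuracy as long as that is at least
the current accuracy (ties broken by feature name order), stopping when
every removal would strictly degrade it. F1 is the surviving combined
set; F2/F3 are its lab-only / home-only partitions. Classification uses
a CART decision tree (Gini, max depth 3, min leaf 2, fixed seed — small-n
overfit control, all configurable) under LOSO; sensitivity, specificity,
precision and accuracy come from the pooled held-out predictions and the
AUC from the pooled predicted FOF+ probabilities. Selection is performed
once on the full cohort by default (mirroring the single reported
feature set); a `selection_in_folds` option re-runs selection inside
every training fold for honest generalisation estimates.

Lab-versus-home comparison: per group, the Wilcoxon signed-rank test
(exact for n ≤ 25 without zeros/ties, tie-corrected normal approximation
otherwise) and Pearson ρ with bands low < 0.5, moderate 0.5–0.7
(closed), high > 0.7; degenerate pairings (all differences zero,
constant features) are flagged explicitly. Home/lab unitless ratios are
formed per subject (lab value must be positive) and compared between
groups with the same rank-sum effect size.

Calibration checks: under a synthetic null the adjusted-logistic
rejection rate at α = 0.05 stays within [0.01, 0.10] over 200
replicates, and label-permuted LOSO AUC averages near chance
(0.35–0.65) — LOSO's slight pessimism below 0.5 is expected.

## Problem sizes and determinism

Validation studies use deliberately scaled problem sizes chosen once:
detection recovery on 20 days of 18-min wear; mixture recovery at 5000
samples × 20 seeds; calibration with 200 null replicates and 100 label
permutations; the group-effect pattern on 100 seeded cohorts (turn-sign
consistency, 2 days each) and 50 seeded cohorts (feature-set AUC
comparison, 3 days each, the reduced-day demo configuration). All
stochastic procedures are bit-reproducible under a fixed seed; the
pipeline manifest records per-file digests and identical configs yield
identical digests.

## What passing tests do and do not show

The generator emulates bimodal speed structure, Poisson event processes,
bout-class structure, sensor tilt and noise — but not tremor, freezing
of gait, off-body periods, vehicle artefacts, stair/ramp walking or
foot-sensor fusion. Detector performance on this synthetic cohort
therefore demonstrates internal consistency of the pipeline (the rules,
formulas and statistics operate as specified), not clinical validity on
real recordings. The statistics layer, by contrast, operates on feature
tables and transfers unchanged to features extracted by any validated
detector.
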