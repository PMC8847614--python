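# Methods

This note documents the models implemented in `gazesurprise`, the
assumptions behind the synthetic-session generator, and the numerical
choices that matter when interpreting its output.

## Task model

Four boxes sit in a horizontal row 15° above fixation, centred at
x ∈ {−8.55, −2.85, +2.85, +8.55}° (eccentricities 15.3–17.3°, i.e. the
boxes lie at roughly 17° from fixation); each box is 5.7° × 4.3°. A cue
marks `n ∈ {1,2,3,4}` contiguous boxes for 2000 ms; contiguity gives 4, 3,
2 and 1 possible placements for n = 1..4. After a 1000-ms empty test array,
a 50-ms warning stimulus (WS) starts a constant 1900-ms foreperiod ended by
the 50-ms imperative stimulus (IS) in one cued box. Expected surprise is
`SUₙ = −log₂(1/n)` bits. The inter-trial interval is uniform on
2000–2500 ms. All positions are in fixation-centred degrees, +x right,
+y up; boxes are indexed 0–3 left to right.

## Synthetic sessions

The generator (`GeneratorConfig`) produces gaze + pupil traces at 500 Hz
from 500 ms before cue onset to 1200 ms after IS onset, with hidden
ground-truth event logs. Defaults are the study conditions: 34 subjects,
40 trials per condition.

**Measurement-space conventions.** Two conventions make the generator's
parameters recoverable by the pipeline rather than merely nominal:

1. *Onsets are threshold crossings.* Saccade latencies reported by
   velocity-threshold detectors are crossing times, not motion starts. The
   generator therefore places each raised-cosine waveform so that its
   analytic 22 °/s crossing occurs at the drawn latency; the sub-threshold
   ramp-up (≈ 3–6 ms depending on peak velocity) precedes it. Ground truth
   logs both times.
2. *Configured means are post-truncation means.* Visually-guided latencies
   are truncated Gaussians (floor 100 ms — the classification boundary;
   the distribution family is a modelling choice). Naive truncation would
   inflate the SU1 mean by ≈ 6.5 ms, so the pre-truncation location is
   solved per condition (Brent root find, Gauss–Hermite integration over
   the subject intercept) such that the marginal post-truncation mean
   equals the configured value.

**Saccade kinematics.** Waveforms have a raised-cosine velocity profile:
`v(t) = Vp/2 · (1 − cos 2πt/D)` with `D = 2A/Vp` (the profile's mean speed
is `Vp/2`, which fixes the duration). Displacement is the exact integral,
so amplitude is met to machine precision. Peak velocity is drawn per trial
(condition mean + subject intercept + residual; variance components from
the velocity model of the study) independently of amplitude — the
amplitude–velocity main sequence is *not* enforced.

**Visually-guided trials** contain one saccade from fixation to the target
box centre at IS + latency, with latency variance components
σ² = 2939.17 ms², τ₀₀ = 1621.30 ms² and condition means
215.8/233.5/244.8/247.8 ms.

**Anticipatory trials** occur with per-condition probability derived from
the pooled 5.50 % incidence and the incidence-rate ratios 1, 1/3.91,
1/5.50, 1/5.82: with balanced conditions the pooled rate is the mean of the
per-condition rates, so `r₁ = 4 · 0.055 / Σ irr ≈ 0.137` and
`r_k = r₁ · irr_k`. Onsets follow a bimodal mixture weighted by the
observed mode counts (32 early : 150 late): the early mode is uniform on
the first 500 ms of the foreperiod (impulsive responses to WS extinction);
the late mode has a linearly increasing density on 1000–1900 ms
(inverse-CDF `1000 + 900·√u`), a concrete rendering of the qualitative
"probability rises as the foreperiod elapses". Amplitudes are Gaussian
around 11.7° (early) and 12.9° (late); the saccade aims at a uniformly
chosen cued box. Anticipatory trials contain no visually-guided saccade.

**Pupil.** Baseline ≈ 4 mm plus a subject baseline intercept (sd 0.5 mm,
removed by baseline correction) and stationary AR(1) noise (sd 0.5 mm,
ρ = 0.995 per sample at 500 Hz, ≈ 0.4 s time constant — hippus-like slow
fluctuation). Luminance transients are raised-cosine bumps with compact
support (cue: −0.30 mm over 800 ms and +0.10 mm over 1500 ms; WS: −0.15 mm
over 550 ms starting at WS offset, mimicking the lagged light reflex), so
they vanish exactly before the 800–1900 ms analysis window and the
pre-epoch baseline. The condition effect ramps linearly from 500 to 800 ms
after WS offset and plateaus at 0.24/0.08/0.09/0.05 mm; a subject dilation
intercept (sd 0.10 mm, matching the reported per-condition dispersion of
window means) is shared across conditions. With noise off, the full
preprocessing chain returns the configured plateau exactly — a designed
identity used by the tests.

**Gaze noise** is slow fixational drift (AR(1), 1-s time constant,
sd 0.1°) plus 0.01° white tracker jitter. White noise of the full 0.1° sd
would produce ~10 °/s velocity noise per axis at 500 Hz and the 22 °/s
criterion would chatter constantly; drift + jitter keeps velocity noise
near 3 °/s, which is what video-oculography traces look like.

**Blinks** are a Poisson process (0.1 events/s) with 100–300 ms gaps;
samples inside a gap are invalid (NaN gaze and pupil).

**What the generator does not emulate**: main-sequence
amplitude–velocity–duration coupling beyond the raised cosine,
microsaccades, smooth drift correction, corrective saccades, pupil
foreshortening, gaze-dependent pupil artifacts, and the heavy right skew
of empirical latency distributions. Passing recovery tests therefore shows
the pipeline is unbiased for well-formed events of known shape — not that
it is robust to every artifact of real recordings.

## Detection and classification

Position is smoothed with a 5-sample moving average (edge-replicated);
speed is the central-difference velocity magnitude; acceleration the
central difference of speed. Candidate samples exceed 22 °/s OR
|3800| °/s²; candidate runs are extended to the surrounding 22 °/s
crossings, merged when gaps are under 20 ms, and dropped when shorter than
6 ms (anti-chatter values; the combination rule and smoothing are stated
choices, as threshold pairs alone do not define a detector). Amplitude is
the start-to-end Euclidean distance, peak velocity the in-event maximum of
the smoothed speed — which under-reads a raised-cosine peak by ≈ 1.3–1.9 %
for typical 17°-saccades (the kernel averages velocity over ≈ 10 ms);
recovery tolerances carry a 2 % attenuation bound for this known bias.

Classification: onset in (WS offset, IS + 100 ms) → anticipatory (mode:
early < 500 ms into the foreperiod, late > 1000 ms, else intermediate —
the intermediate label is ours; the modes are described only
qualitatively); latency in [100, 1000] ms → visually guided; later →
excluded. Saccades during the cue/test epoch are detected but flagged out
of analysis. Trial exclusions for the visually-guided analyses: artifact
(automated proxy: > 20 % invalid samples; the original study used manual
screening), any anticipatory saccade in the trial, latency > 1000 ms,
or landing outside the scheduled target box (landing = mean gaze over
50 ms post-offset). Anticipatory saccades are retained for the count
analyses regardless.

## Pupil preprocessing

Order-fixed chain per foreperiod epoch (onset = WS offset, 38 × 50-ms
bins): linear blink interpolation bridging from 70 ms before to 70 ms
after each gap (edge gaps filled with the nearest valid value) → per-bin
means → 3-bin running median (truncated at edges) → subtraction of the
mean of the 100 ms before epoch onset. "Normalisation to baseline" is
implemented subtractively: results are reported in mm, which a divisive
normalisation would not preserve. The analysis window averages bins whose
centres lie in [800, 1900) ms — bins 16–37.

## Cluster-based permutation test

Per-bin Welch t across trials pooled over subjects; two-sided p < .05
cluster-forming threshold (per-bin Welch df); clusters are maximal
contiguous sign-homogeneous suprathreshold runs, scored by summed t. The
null is the distribution of the largest absolute cluster mass over label
permutations — by default 10,000 shuffles *within subject*, which respects
subject exchangeability (an across-subject option exists). Cluster
p-values use the +1-smoothed estimator
`p = (1 + #{null ≥ |mass|}) / (1 + n_perm)`, so p ∈ (0, 1]. Family-wise
calibration is verified by simulation (200 null datasets, 1,000
permutations each: empirical false-positive rate within the 95 % binomial
CI of 0.05).

## Hick's law

OLS of latency on log₂(number of cued boxes) over subject-by-condition
means (34 × 4 = 136 observations — consistent with the reported F[1,134]);
slope in ms/bit with R² and F-test. A trial-level fit is available via the
same class.

## Accumulator model

First-passage times are gamma(`T`, 1/`R`) (sum of `T` exponential
inter-arrival times at rate `R`); simulation uses a single gamma draw per
trial. Grid fits simulate 10,000 latencies per grid point from a fixed
per-point seed stream (re-used across conditions, so condition RSS curves
differ only through the observed means and re-fits are deterministic;
the simulated-mean SE per point is ≈ 0.6 ms). RSS is defined on condition
means, matching a comparison of simulated to average latency. Non-decision
time defaults to 0 ms (no such stage is specified). Known discrepancy: the
originally reported best rates (51/48/45/45 units/s) are not consistent
with `T/R` applied to the printed condition means, which yields ≈
46/43/41/40; an unstated offset or different RSS definition is likely.
This package reports its own fits and makes no attempt to match those
values.

## Mixed models

Gaussian LMMs (pupil window means: A0/A1; latency: C0/C1; velocity: D0/D1)
use statsmodels `MixedLM` with maximum likelihood (not REML), subject
random intercepts, surprise as a 4-level factor with SU1 reference
(the categorical coding reproduces the reported pairwise contrasts;
a continuous-bits coding would not), and contrasts reported as SU1 − SUk
(latency additionally SU2−SU3 and SU3−SU4). The zero-inflated Poisson GLMM
(anticipatory counts per subject × condition: B0/B1; intercept-only
zero-inflation, subject random intercept in the count part) and the
binomial GLMM (memory accuracy on memory load: E0/E1) are fitted by
direct Gauss–Hermite marginal likelihood (31 nodes, L-BFGS-B, numerical
Hessian for Wald SEs) — no maximum-likelihood mixed-model machinery for
these families exists in the scientific Python stack. Incidence-rate
ratios are `exp` of the SU1-referenced contrasts. Complete separation in
the binomial model (e.g. all-correct data) is flagged and handled with a
small ridge penalty. Likelihood-ratio tests use `2·ΔLL` against χ² with
the parameter-count difference as df; negative statistics from optimizer
noise are clipped at zero with a warning. Stage decisions in the pipeline
use α = 0.01; CBPT cluster p-values keep their conventional .05 threshold.

## Statistical tolerances in the test suite

Recovery checks on condition means use **subject-clustered** standard
errors (SEM of per-subject means across the 34 subjects): trials within a
subject share random intercepts, so the naive trial-level SEM understates
the sampling error of a cohort mean several-fold. The subject-level SEMs
(≈ 7.1 ms latency, ≈ 11.2 °/s velocity at the default design) are also the
dispersions the study reports alongside its condition means. Monte-Carlo
checks use 3-SD binomial/normal bands; calibration checks use 95 % binomial
CIs.

Problem sizes were chosen so the default suite completes in a few minutes:
the full 34 × 160 cohort for the end-to-end recovery checks, 20 cohorts ×
1,000 permutations for CBPT power, 200 datasets × 1,000 permutations
(reduced from 10,000, which only affects p-value resolution, not
calibration) for family-wise error, n = 10⁵ for accumulator closed forms,
and reduced cohorts for null-calibration loops.

## Known limitations

* The ZIP/binomial GLMM standard errors are Wald from a numerical Hessian;
  profile-likelihood intervals are not implemented.
* Wald coverage for the ZIP contrasts is nominal only for data generated
  under the model; permutation nulls of strong-effect count data are
  overdispersed relative to ZIP and show undercoverage (~70 %) even though
  the point estimates correctly collapse to zero.
* The artifact proxy (> 20 % invalid samples) is not claimed equivalent to
  the manual screening it replaces.
* Binocular recordings are processed monocularly (the generator emits one
  eye).
* `MixedLM` occasionally converges poorly on very small null datasets
  (LL(full) marginally below LL(null)); the LR statistic is clipped at 0,
  which is conservative.
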