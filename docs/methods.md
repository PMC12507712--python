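# Methods

This note documents the models, conventions and numerical choices behind
`mi-erd`, and what the synthetic-data tests do and do not establish.

## Signal model of the synthetic generator

Each synthetic recording emulates one MI-training session: alternating rest
(5 s) and cued motor-imagery (5 s) periods, 15 trials per class at 250 Hz on a
32-channel 10-20 montage (the pilot timing — 10 s / 10 s, 20 trials per class
at 500 Hz — is a configuration away). The signal is a sum of

* **Two alpha sources** (sinusoids at `alpha_freq_hz`, default 10 Hz, with
  independent random phases) centred on C3 and C4, projected to the scalp
  with a Gaussian spatial kernel (σ = 0.35 on the unit sphere). The peak
  channel amplitude is `alpha_amplitude_uv` (default 8 µV).
* **Event-locked suppression.** During each MI period, starting
  `reaction_time_s` (0.5 s) after the cue, the contralateral source amplitude
  is scaled by `sqrt(1 + erd_contra_pct/100)` and the ipsilateral source by
  `sqrt(1 + erd_ipsi_pct/100)` (power goes as amplitude squared). Gating uses
  a 100 ms raised-cosine ramp to avoid spectral splatter into the baseline.
  Defaults −40 % / −20 % imply a lateralization index of exactly 20 %.
* **1/f background noise** (`noise_exponent` = 1, broadband RMS
  `noise_amplitude_uv` = 4 µV per channel) spatially blurred by a Gaussian
  channel-distance kernel (σ = 0.55). The blur plays the role of volume
  conduction: neighbouring clean channels correlate well above 0.5 — and,
  importantly, still do so after common-average referencing, which a single
  global noise component would not survive.
* **Optional artifacts**: frontal-dominant Gaussian blink transients
  (~1 per 20 s) and a 50 Hz line sinusoid.

Defaults were fixed once to make the alpha signal clearly super-threshold
(in-band alpha-to-noise power ratio ≈ 20 at the source channels, i.e. an
ERD dilution well under the 5-percentage-point recovery tolerance) while
keeping single-trial estimates visibly noisy, as in real MI data.

What the generator does **not** model: biophysical head geometry and realistic
volume conduction, EMG, non-stationary alpha (the oscillator amplitude is
deterministic between events), eye movements other than blinks, and
electrode drift. Passing parameter-recovery tests therefore demonstrates the
*correctness of the analysis arithmetic and plumbing* under controlled
conditions, not robustness to every failure mode of real recordings.

Between-subject variability in cohort simulations enters through a
per-subject ERD gain multiplier (`subject_gain_sd`, default 0.25, shared by
both conditions of a subject as in a within-subject design) and through the
questionnaire model: items are i.i.d. discretized truncated normals around
per-condition means (defaults 3.3 control / 5.1 embodied, SD 1.3, chosen to
match the reported scale of the embodiment contrast).

## Preprocessing chain

Order: zero-phase FIR band-pass 1–40 Hz → resample to 125 Hz (cue indices
re-mapped) → bad-channel detection → burst cleaning → spherical-spline
interpolation of flagged channels → common-average reference (CAR) → seeded
ICA with heuristic component rejection → epoching −5 to +5 s (half-open) →
peak-to-peak epoch rejection. Narrow filter transition bands (0.5 Hz low,
2 Hz high) keep the chain near-idempotent: re-running it on cleaned data
changes signal RMS by well under 1 %.

Bad-channel rules (all deterministic): a ≥ 5 s near-constant run ("flat");
more than 15 % of 1 s windows beyond the channel's own robust (median + 5
MAD) RMS bound — per-channel, so a consistently strong alpha channel is not
penalized; maximum absolute correlation with every other channel below 0.5;
and a 50 Hz power fraction that is both a > 4 z-score outlier across channels
and at least 1 % of total power (the absolute floor stops the z-score firing
on the negligible residue left above the low-pass edge). More than 50 %
flagged channels aborts the run as a quality failure.

Burst cleaning is a simplified, deterministic artifact-subspace method: the
cleanest 60 s (lowest total RMS) calibrate principal axes and per-component
RMS; in 0.5 s half-overlapping Hann windows, components whose RMS exceeds
10× their calibration value are zeroed and the window rebuilt from the
remaining subspace. Component amplitude is measured as RMS (not SD) so
baseline shifts inside a window register. Sample count is never changed, and
burst-free input passes through bit-near-identically. The published
Riemannian ASR variant is out of scope; the burst-criterion contract (10 SD,
no segment removal) is preserved.

Artifact ICs are identified by rule, not by a trained classifier: a blink
score (frontal-dominance of the topography × sub-4 Hz power fraction), a
muscle score (20–40 Hz power fraction) and a line score (50 Hz fraction),
each normalized to [0, 1]. Components scoring ≥ 0.9 — the analogue of a
≥ 90 % classifier probability — are flagged and at most six (highest first)
are removed; the cap mirrors the original manual-selection limit. ICA runs
on a 20-component PCA subspace with 4× decimation purely for speed; artifact
components are high-variance and unaffected by the reduction. Epoch
rejection replaces visual inspection with a 100 µV peak-to-peak threshold.

## Time-frequency analysis and ERD

ERSP uses Morlet wavelets at 1 Hz spacing over 8–12 Hz, cycles = f/2 clipped
to [3, 6]. Epochs are reflection-padded by 1 s before the transform so
neither the baseline nor the late task window carries convolution edge bias.
The baseline is *per-trial* and divisive: mean power over the symmetric
pre-cue interval, then dB. Per-trial baselining makes the trial-level
Wilcoxon inputs self-normalized; a condition-average baseline is the main
alternative and would shrink trial-to-trial ERD variance at the cost of
coupling trials.

ERD(%) = (10^(ERSP/10) − 1)·100 maps dB monotonically onto (−100 %, ∞). The
analysis window is [1, 5) s post-cue for both protocols; requests starting
earlier are clamped to 1 s (reaction-time exclusion) with a warning. The
lateralization index is computed from the four class-mean window ERDs at
C3/C4; its sign convention (positive = contralateral dominance) follows from
subtracting ipsilateral-minus-contralateral per class. Reported table values
round half-up at two decimals (the helper first snaps to 10 decimals so
binary float error cannot flip a decimal halfway case).

## Statistics

All tests are two-sided at α = 0.05 with no multiplicity correction (a
deliberate, documented limitation — the analysis reports a small fixed family
of comparisons). Mann–Whitney U uses midranks; p is exact by enumeration for
tie-free samples with n₁·n₂ ≤ 400, otherwise normal approximation with tie
and continuity corrections. The reported statistic is U of the first sample
(`convention="first"`); published tables differ in which U they print, so
`max`/`min` conventions are selectable. The one-sample Wilcoxon signed-rank
test drops zero differences, is exact for n ≤ 20 tie-free samples, and
approximates otherwise. Normality screening uses a one-sample KS test against
a normal with the group's fitted mean/SD — anti-conservative (Lilliefors
effect), accepted because it only routes toward the nonparametric tests that
are used anyway — and homoscedasticity uses the median-centred Levene
(Brown–Forsythe) test.

## Embodiment models

LR is OLS of the outcome (per-hand window ERD at the contralateral
electrode, or LI, one observation per subject × condition) on the embodiment
composite. LME adds a random intercept per subject and is fitted by maximum
likelihood — not REML — so AIC/BIC are comparable across LR and LME; the
criteria use k = 4 (two fixed effects, random-intercept variance, residual
variance). The headline R² for the LME is the conditional (Nakagawa-style)
R², (var_fixed + var_between)/(var_fixed + var_between + var_resid), because
with near-zero slopes only the variance decomposition can produce the
moderate-to-large R² values such models report; the marginal R² is emitted
alongside. When every subject has a single observation the between/within
split is unidentified, so the fit falls back to the OLS solution with zero
random variance (with a warning). The SE of the random-intercept SD comes
from the delta method with the residual scale held fixed — adequate for
coverage checks, slightly conservative.

## Classification

Epochs are band-passed 8–28 Hz and restricted to the 1–5 s MI window (the
same window as the ERD analysis; the covariance window is configurable).
Per-trial covariances are uncentered (so filtered-signal variance is exactly
wᵀCw), trace-normalized before per-class averaging. The composite covariance
is whitened with a rank tolerance of 1e-6 — deliberately coarse enough to
reject the CAR null direction, whose whitened eigenvalue is pure noise — and
the whitened class covariance eigendecomposed; three eigenvectors from each
spectral extreme give six filters (ridge 1e-6·trace on rank deficiency).
Features are log variance fractions; the classifier is LDA with Ledoit–Wolf
shrinkage of the pooled covariance. Monte Carlo cross-validation draws ten
seeded stratified 80/20 splits; CSP and LDA see the training split only.
Stratification (the split rule itself fixes only the 20 % test share)
avoids empty-class folds at 30 trials.

## Cohort analysis

The unit of statistical observation for condition comparisons is the
subject: per-subject class-mean window ERDs and LI feed subject-level
Mann–Whitney tests, matching group tables built from per-subject means.
Failed subject × condition stages are recorded and the cohort statistics run
over completers (two-condition subjects), aborting below three. Reports
carry the seed, package version and a config hash; identical configuration
reproduces identical tables.

## Problem sizes in the test suite

Simulation-backed checks are seeded and sized to balance statistical
resolution against wall-clock cost: classifier chance calibration uses 500
permutation replicates on one subject's epochs (log-variance features are an
exact function of per-trial covariances, so cross-validation reuses cached
covariances); mixed-model recovery uses 500 cohorts at 39 × 2; test
calibration uses 2000 null replicates; and the end-to-end null-cohort check
runs 10 full 13 × 2-condition pipeline replicates with the time-frequency
stage restricted to the channels of record (C3/C4). The null-cohort check
asserts the headline pattern per comparison: each ERD/LI condition test
non-significant in ≥ 90 % of replicates and the embodiment comparison
significant in ≥ 90 %.

## Known limitations

* The component heuristics are tuned to the generator's artifact morphology;
  real muscle/ocular activity is more varied than the rules assume.
* The simplified burst cleaner attenuates to the calibration threshold
  rather than reconstructing from a learned clean manifold.
* Item-level questionnaire structure (inter-item correlation, reverse-coded
  items) is not modelled; only composite-level behaviour is calibrated.
* The KS normality screen is anti-conservative by construction (see above).
* Between-subject ERD heterogeneity is a single multiplicative gain; real
  subjects also differ in alpha frequency, topography and reaction time.
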