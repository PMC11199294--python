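# Methods

This note records the models, conventions, parameter choices and known
limitations of `midstates`, in the order the pipeline runs them.

## Data model and preprocessing

ERPs are stored as average-referenced channels × time matrices in
microvolts, one per (subject, merged condition). All latencies at API
boundaries are in milliseconds; sample indices are internal. Epoch
windows are half-open `[start, end)` in samples, so an epoch spans
exactly `round(fs · span / 1000)` samples (−500…+1000 ms at 256 Hz is
384 samples).

Merging pools raw small/large reward cue epochs into `reward` (likewise
`loss`); trial counts add. Subjects with fewer than 9 reward or loss
trials, or fewer than 12 neutral trials, after artifact rejection are
excluded with an explicit report rather than silently dropped.

The EDF adapter reads continuous EDF+ recordings through MNE and epochs
around annotated cue markers. Manual, ICA-based ocular correction of a
typical lab workflow cannot be automated faithfully; the adapter instead
applies a documented amplitude-threshold rejection (any sample beyond
±100 µV discards the epoch; configurable). The band-pass (default
1–15 Hz) is a zero-phase forward-backward Butterworth filter
(`sosfiltfilt`, order 4 per direction); only the band is part of the
emulated design, the realization is ours. A minimal EDF+C writer
(16-bit, annotations channel) exists solely to produce synthetic test
recordings.

## Topographic consistency test

At each time point the subject maps are average-referenced and
L2-normalized, and the statistic is the GFP of their mean. Normalizing
first means between-subject amplitude differences cannot masquerade as
topographic consistency; whether the original formulation normalizes is
not restated in the emulated design, so this choice is isolated in
`_normalize_maps` for sensitivity analysis. The null permutes channel
values independently within each subject's map (full permutation, not
sign flipping). Dataset-level trimming runs the test per group ×
condition cell and takes the per-time-point maximum p over cells, so the
retained window is where *every* cell is consistent; only leading and
trailing non-significant runs are trimmed — interior gaps are retained.

Monte-Carlo p-values throughout the package use the add-one rule
`(1 + #{null ≥ observed}) / (1 + N)` with ties counting toward the null:
p is never zero and the test is exact under exchangeability.

## Microstate clustering

Modified k-means on instantaneous topographies: assignment by largest
signed projection onto unit templates (polarity-sensitive default —
ERPs are phase-locked averages, so a polarity reversal is a different
brain state; a polarity-invariant mode squares the projection and
updates templates by the first principal direction instead of the
normalized mean). Restarts (default 20) are seeded; the restart with the
highest explained variance wins. Empty clusters are re-seeded from a
random map. Ties in the assignment argmax go to the lowest class index.
No minimum-duration smoothing is applied to backfitted labels: brief
states are reported, not suppressed.

Explained variance is `Σ_t (u_{a(t)}·v_t)² / Σ_t ‖v_t‖²` over the maps
considered; the per-time-point curve is reported as `(u_{a(t)}·v_t)²/C`
(C = channel count), which bounds it by GFP² and gives the
area-under-the-curve parameter µV²·ms units. The exact normalization
used by legacy microstate software is not public; this definition is one
consistent choice and is isolated in two functions.

The class count is chosen by subject-wise cross-validation: subjects are
split into folds stratified by group, templates are fit on the training
subjects' concatenated cell grand means and scored on held-out grand
means; the selected k is the smallest whose mean held-out gain over k−1
falls below ε (default 0.01), else the largest candidate. A pipeline
override (`k_override`) mirrors the common practice of trading a few
held-out percent for a more interpretable smaller model.

## Microstate parameters and analysis windows

Per class appearance: onset and offset are the first and last labeled
sample latencies; duration is `offset − onset` (exclusive endpoint
convention — the inclusive alternative differs by one sample step);
AUC integrates the explained-variance curve over labeled samples; the
center of gravity is the EV-weighted mean latency; mean GFP averages the
GFP curve over labeled samples.

Parameters are extracted within a per-class analysis window that
isolates a single appearance, following the rule of restricting analysis
to periods where a class appears once. The window is computed as the
union over the six cells of the class's longest contiguous appearance in
the backfitted grand mean. The union (rather than any single cell's
appearance) covers between-cell timing differences — truncating at one
cell's offset would clip exactly the effects under test — while
excluding stray isolated labels elsewhere in the epoch, which otherwise
inflate the duration and offset parameters catastrophically (a single
mislabeled sample 100 ms after the appearance would extend the measured
offset by 100 ms). Explicit per-class windows can override this rule.

## Randomization inference

Effects are tested on the 2 × 3 table of cell parameters. Statistics:
double-centered sum of squares for the interaction, sum of squared
level-mean deviations for main effects, absolute difference for
post-hoc contrasts. The factorial decomposition on cell means is the
standard choice; the legacy software's exact statistic is not published.

The null permutes group labels across subjects and condition labels
within subjects (each subject keeps their three ERPs — the
repeated-measures structure is preserved); the interaction permutes both
jointly and independently, main effects permute only their own factor,
and contrasts permute only the labels distinguishing the two cells.
Templates are **not** refit per randomization: only backfitting, window
masking and feature extraction are recomputed. Refitting k-means inside
5000 randomizations is computationally prohibitive and fixed maps are
the convention of topographic randomization software; the templates are
an input to the test, so held fixed they leave the permutation test
valid for the parameters given those maps.

A randomization in which the class vanishes from some cell has no
defined parameter table; such draws are redrawn (logged, capped at 20·N
total draws) rather than imputed, which would distort the null. No
multiple-testing adjustment is applied; the results table records how
many tests were run.

Because projection is linear, the engine precomputes per-subject
template projections once; a permuted cell's backfit then costs a small
mean plus an argmax, making 5000 randomizations on a 53-subject dataset
a matter of seconds.

## ERP scores and partial correlation

The template map is the group-difference of window-averaged maps for a
chosen condition; the sign convention (which group is subtracted) is
recorded in the output because every downstream correlation sign depends
on it. Scores are plain dot products (µV² scale). Partial correlation
uses the closed form on pairwise Pearson correlations, a two-tailed t
test on n−3 degrees of freedom, and a Fisher-z 95% CI with
SE = 1/√(n−4); it is computed on the pooled sample with the covariate
adjustment, with a per-group option.

## Synthetic data

Each subject–condition ERP is a sum of non-overlapping microstate
segments (amplitude × planted template, hard switches; an optional
cross-fade is deliberately absent — hard switches make ground-truth
onsets/offsets unambiguous for recovery tests) plus spatially smoothed
Gaussian noise, then average-referenced. Defaults, chosen once as
typical of cue-locked ERP averages and fixed thereafter:

| parameter | default | meaning |
|---|---|---|
| amplitudes | 2.5–4 µV | segment strength along a unit-norm map |
| `noise_sd` | 1 µV | residual noise SD of a subject's average ERP |
| `subject_onset_jitter_ms` | 10 ms | per-subject common shift of all boundaries |
| `subject_log_amp_sd` | 0.1 | per-subject log-normal amplitude factor |
| layout | 30 channels | Fibonacci spiral on the upper unit hemisphere |
| templates | quadratic spherical polynomials | smooth maps, pairwise cosine ≤ 0.6 |

Noise is white Gaussian smoothed across channels with a Gaussian kernel
over inter-electrode distance (volume-conduction-like spatial
correlation); it is white in time. Clinical scores are a planted linear
function of a subject's realized segment amplitude plus Gaussian noise;
`clinical_noise_for_rho` converts a target correlation into the
required noise SD.

What the generator does *not* emulate: single-trial variability and
trial-varying latency jitter (ERPs are generated directly at the
average level), temporally correlated or 1/f noise, transition
cross-fades, volume-conducted artifact topographies (EOG), or
behavioral/staircase dynamics. Passing recovery tests therefore shows
the analysis machinery is correct and calibrated under a faithful but
idealized ERP model — not that real recordings of any particular study
would yield any particular effect.

## Calibration studies and problem sizes

The simulation studies in `midstates.calibration` run at sizes chosen to
answer each question in minutes on a single core:

- **Null calibration**: 200 datasets, 2 × 12 subjects, 20 channels, 100
  frames over a 0–500 ms three-class timeline (fs 200 Hz), 500
  randomizations each; rejection rate at 0.05 is reported with a Wilson
  95% CI. Templates are fit per dataset from the observed concatenated
  grand means, exactly as the pipeline does.
- **Crossover power**: ±40 ms duration crossover in the middle class,
  at the emulated design's group sizes (30 + 23), 100 replicates.
- **CV plateau**: 3 planted classes at high SNR (noise 0.3 µV), 50
  replicates, candidate k ∈ 1…5.
- **Score chain**: planted r = −0.4 at n = 53, 200 replicates; the full
  template-projection and partial-correlation chain recovers a negative
  r in essentially all replicates with mean near the planted value.

## Numerical and degenerate-input conventions

All-zero data cannot be clustered or scored (explicit errors). Tie
breaks: lowest class index in backfitting; ties count toward the null in
every Monte-Carlo p. Average reference requires ≥ 2 channels; partial
correlation requires n ≥ 4 and non-degenerate variances; a zero
group-difference template cannot be projected onto. Windows are closed
`[start, end]` at feature level (clamped to sample latencies), and the
absent-feature signal is `None`, propagated rather than raised wherever
a class may legitimately vanish.

## Known limitations

- Features are computed on cell grand means, so inference is about the
  group-level microstate sequence; no subject-level random-effects model
  is provided.
- The permutation scheme for the interaction (joint independent
  permutation of both factors) is one of several defensible choices and
  is isolated in one function.
- The EDF reader trusts MNE's annotation parsing; only EDF+C with
  standard annotations is exercised.
- Source localization of group differences is out of scope.
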