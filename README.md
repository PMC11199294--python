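# midstates

Microstate analysis of cue-locked event-related potentials (ERPs) from
incentive paradigms such as the monetary incentive delay (MID) task, for
researchers comparing reward/loss/neutral cue processing between two
subject groups (e.g. a patient group and matched controls).

An ERP microstate is a brief period during which the scalp topography
stays quasi-stable. The package segments group × condition grand-mean
ERPs into microstates and asks where, when and how strongly the groups
differ:

1. **Topographic consistency test (TCT).** At each time point *t*, the
   statistic is the global field power of the mean of the individually
   L2-normalized subject maps, GFP(mean_i v̂_i(t)), with a null built by
   permuting channel values within each subject's map. Leading and
   trailing non-significant runs are trimmed from the analysis window.
2. **Modified k-means clustering.** Instantaneous maps v_t of the
   concatenated grand means are clustered into k unit-norm template
   topographies u_1..u_k, assigning each map to the template with the
   largest (signed, since ERPs are polarity-locked) projection u_j·v_t
   and updating templates as normalized cluster means; k is chosen by
   subject-wise cross-validated explained variance
   Σ_t (u_{a(t)}·v_t)² / Σ_t ‖v_t‖².
3. **Backfitting and parameters.** Templates are assigned back to each
   cell's grand mean; per appearance of a class the six parameters are
   onset, offset, duration, explained-variance area under the curve,
   center of gravity of that curve, and mean GFP.
4. **Randomization statistics.** Group, condition and group × condition
   effects on the 2 × 3 cell-parameter table are tested by permuting
   group labels across subjects and condition labels within subjects
   (5000 randomizations by default, fixed templates), with Monte-Carlo
   p = (1 + #{null ≥ observed}) / (1 + N).
5. **ERP scores and clinical correlation.** For a window with a group ×
   condition interaction, the group-difference topography is a template
   map; the dot product of each subject's window-averaged map with it
   yields one ERP score per subject, related to clinical scores by
   Pearson partial correlation (Fisher-z 95% CI).

Because no raw EEG from the emulated study design is publicly available,
the package ships a first-class synthetic-data module that generates
MID-style task schedules, multi-subject ERP datasets with planted
microstate timelines and group × condition effects, and clinical score
tables with planted correlations — the test bed for all calibration and
recovery studies.

## Worked example

Simulate a 30 + 23 subject dataset in which the second microstate lasts
40 ms longer under reward cues in patients and 40 ms shorter in
controls, then recover that interaction:

```python
import numpy as np
from midstates import (GroundTruth, default_timeline, make_layout, make_templates,
                       simulate_erp_dataset, fit_microstates, backfit,
                       extract_features, interaction_test, grand_mean)
from midstates.microstates import match_templates
from midstates.randstats import class_analysis_window

layout = make_layout(30, seed=0)
templates = make_templates(4, layout, seed=1)
timeline = default_timeline()
for g, d in (("patient", +40.0), ("control", -40.0)):
    t = [list(s) for s in timeline[(g, "reward")]]
    t[1][2] += d; t[2][1] += d
    timeline[(g, "reward")] = [tuple(s) for s in t]
truth = GroundTruth(templates, timeline, noise_sd=1.0,
                    subject_onset_jitter_ms=10.0, subject_log_amp_sd=0.1)
ds = simulate_erp_dataset(truth, (30, 23), layout, seed=2)

maps = np.concatenate([grand_mean(ds, g, c)[:, ds.time_mask(0, 700)].T
                       for g in ds.groups for c in ds.conditions])
model = match_templates(fit_microstates(maps, 4, n_restarts=20, seed=3), templates)
print(model.summary())
window = class_analysis_window(ds, model, 2)
seg = backfit(model, grand_mean(ds, "patient", "reward"), ds.times, window=window)
f = extract_features(seg, 2, check_contiguous=False)
print(f"patient/reward class 2: duration {f.duration:.1f} ms")
print(interaction_test(ds, model, 2, window, "duration", n_rand=1000, seed=4).summary())
```

prints

```
Microstate model
  classes:            4
  channels:           30
  polarity sensitive: True
  train expl. var.:   96.5%
patient/reward class 2: duration 273.4 ms
Randomization test: interaction
  feature:   duration (class 2, window 179.688-457.031 ms)
  observed:  2049.76
  p-value:   0.000999  (1000 randomizations)
```

The four fitted templates explain 96.5% of the grand-mean topographic
variance; the patient/reward duration (273 ms) reflects the planted
40 ms lengthening over the 240 ms baseline plus one-sample
discretization, and the group × condition randomization test rejects
decisively (the smallest attainable p at 1000 randomizations is 1/1001).

The same analysis runs end to end from a YAML configuration via the CLI:

```sh
midstates simulate --out dataset/ --seed 1
midstates run --config config.yaml
midstates report --outdir run/
midstates test-null --n-datasets 200 --n-rand 500
```

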