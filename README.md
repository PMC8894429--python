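# wmprecision

Analysis pipeline for **precision of perception and working memory** in
delayed matching tasks, and for its association with **musical
sophistication**.

In the underlying paradigm a participant hears (or sees) a stimulus — a pure
tone between 440 and 880 Hz, white noise amplitude-modulated at 5–20 Hz, a
colour hue in 0–300, or a box flashing at 5–20 Hz — and later reproduces it
by clicking on an 800 px horizontal scale whose central 80% maps linearly
onto the stimulus parameter range. In the *working-memory* condition the
match follows a masker and a 2–4 s delay; in the *perception* condition the
target is replayed 100 ms after each match attempt. Each trial yields an
error: for frequency-like features the raw error is divided by the target
(equal parameter steps sound smaller at higher values), for colour hue it is
kept in raw units. A participant's **precision** for one feature and
condition is

```
precision = 1 / SD(normalised matching errors)
```

and precisions are z-scored across participants within each feature ×
condition cell. The inferential stage residualizes the 18-item Goldsmiths
Musical Sophistication Index total (range 18–126) on age and a 12-item
matrix-reasoning score, correlates the residuals with each precision
measure, controls the family with Holm–Bonferroni, and compares dependent
correlations (e.g. frequency-WM vs frequency-perception, both sharing the
adjusted Gold-MSI score) by resampling participants with replacement (5000
samples), reporting both a t test of the resampled differences and a
percentile p-value.

Because the real participant tables are an optional external download, the
package ships a **synthetic cohort generator** with the same statistical
structure (latent sophistication trait, per-condition error scales whose
logs correlate with the trait, questionnaire items from a graded threshold
model, age/reasoning covariates), so every stage is testable end to end.

## Worked example

```python
from wmprecision import (GenerativeConfig, simulate_experiment,
                         compute_errors, estimate_precision, zscore_precisions,
                         PrecisionAssociationModel)

cfg = GenerativeConfig(n_participants=48, seed=12)
participants, responses, pframe = simulate_experiment(cfg, experiment="exp2",
                                                      trials_per_condition=14)
precision = zscore_precisions(estimate_precision(compute_errors(responses)))
res = PrecisionAssociationModel(precision, pframe, n_resamples=5000).fit(seed=12)
print(res.summary())
```

prints

```
Precision-association analysis
==============================================================================
outcome: msi_total   covariates: age, matrix_score   adjustment: residualize_x_only
n = 48 complete cases (0 dropped)   alpha = 0.05
------------------------------------------------------------------------------
measure                                      r    df         p    p_holm  sig
am_rate:perception                       0.162    46    0.2727    0.5454
am_rate:working_memory                   0.049    46    0.7429    0.7429
tone_frequency:perception               -0.219    46    0.1343    0.4028
tone_frequency:working_memory            0.312    46    0.0306    0.1224
tone_frequency:working_memory | tone_frequency:perception   0.316    43    0.0344
------------------------------------------------------------------------------
dependent-correlation comparisons (bootstrap, resampled with replacement)
  freq_wm_vs_am_wm: r1=0.312 r2=0.049 t=100.23 p_t=0 p_percentile=0.172
  freq_wm_vs_freq_perception: r1=0.312 r2=-0.219 t=216.85 p_t=0 p_percentile=0.0052
==============================================================================
```

Reading this: the synthetic cohort was generated with a strong latent link
(rho = 0.5) between sophistication and frequency-WM precision and weak links
elsewhere. At n = 48 with 14 trials per condition the estimated
frequency-WM association (r = 0.31) is attenuated by trial noise, the other
associations hover near zero, and the frequency-WM vs frequency-perception
comparison is clearly asymmetric (percentile p = 0.005). `res.to_report()`
returns the same content as a JSON-able dict; `res.associations_frame` as a
DataFrame.

The same chain is available from a shell:

```
wmprecision simulate --experiment exp2 --n-participants 48 --seed 12 --out-dir run/
wmprecision score --responses run/responses.csv --out run/precision.csv
wmprecision analyze --precision run/precision.csv --participants run/participants.csv --out-dir run/
wmprecision power --r 0.40 --alpha 0.05 --power 0.80   # -> 47
```

`wmprecision all --config cfg.yaml` runs the full chain reproducibly; the
written `report.json` is byte-identical across runs with the same seed and
config. Real tabular exports can be adapted onto the internal CSV schemas
with `wmprecision.io.read_table_with_mapping`.

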