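# Methods

## Measurement model

Each matching trial yields an error `matched − target`. Features for which
perceptual distance shrinks with parameter magnitude (tone frequency, AM
rate, flash rate) use the **relative** error `(matched − target) / target`;
colour hue uses the **absolute** error. Precision for one participant,
feature and condition is the inverse of the sample standard deviation
(n − 1 denominator) of these normalised errors. Errors are not mean-centred
before the SD beyond what the SD itself removes: a constant matching bias
does not change the SD and therefore does not inflate precision. No
outlier-trial rejection is applied by default (a clamp/trim hook exists for
sensitivity analyses). Precisions are z-scored across participants within
each feature × condition cell using the cross-participant mean and sample
SD; when several experiments are analysed, pooling is per experiment so
that cohorts are not mixed.

Degenerate inputs fail loudly: a zero within-participant error SD names the
participant; fewer than `min_trials` (default 2) trials in a cell flags the
estimate missing (NaN) rather than fabricating a value; a zero
cross-participant spread aborts the z-scoring.

## Scale mapping

The full parameter range maps affinely onto the central `usable_fraction`
(default 0.8) of the `pixel_width` (default 800) scale; the excluded 10%
margins at each end correspond to no parameter at all, which is why
scheduled targets drawn uniformly from the parameter range never fall in a
margin. `param_to_scale` / `scale_to_param` are exact inverses on their
bands; pixels inside a margin are rejected.

## Synthetic cohort

The generator emulates the joint structure the analysis assumes, not any
individual dataset:

- A latent sophistication trait `T ~ N(0, 1)` receives small standardised
  contributions (default 0.1 each) from age (uniform on 18–80) and a
  matrix-reasoning ability that also produces the 0–12 matrix score.
- For each feature × condition cell with target correlation ρ,
  `log σ = log σ̄ + s·(−ρ·T + √(1−ρ²)·ξ)`, so that corr(T, −log σ) = ρ
  exactly in population. Defaults: ρ = 0.5 for frequency working memory,
  0.1 for AM-rate WM and the perception cells, 0 for the visual cells;
  spread `s = 0.4`.
- Typical error scales: σ̄ = 0.15 (relative) for working memory, 0.05 for
  perception — perception distributions are narrower by construction — and
  30 hue units for colour-hue WM (the absolute-mode analogue; per-feature
  SD magnitudes are not published, so these are plausibility defaults,
  config-exposed).
- Questionnaire items follow a graded threshold model: item latent
  `T + 0.4·ε` is cut at six equally spaced thresholds (±1.25) into the 1–7
  response range. Totals of the 18 items therefore lie in 18–126 and
  correlate ≈ 0.97 with the trait; items 1–7 form the musical-training
  subset (subtotal 7–49). Only the total's range and correlation structure
  matter downstream.
- Per-trial errors are Gaussian on the normalised scale:
  `matched = target·(1 + e)` (relative) or `target + e` (absolute) with
  `e ~ N(0, σ²)`. Matches are not clamped to the parameter range by
  default, because clamping induces exactly the boundary skew the excluded
  scale margins avoid.

What passing tests on this cohort do **not** show about real data: the
generator has no response times, no practice or fatigue effects, no
heavy-tailed guessing contamination, no equipment variance, and the masker
interference is absorbed into the WM σ rather than modelled. Parameter
recovery here demonstrates that the pipeline is a consistent estimator of
the structure it assumes, not that real errors are Gaussian (that is what
the per-participant Shapiro–Wilk report is for).

## Attenuation

The pipeline correlates a noisy questionnaire total with a noisy precision
estimate, so recovered correlations are attenuated relative to the
generative ρ by three multiplicative factors: questionnaire discretisation
(≈ 0.97), the curvature of `precision = exp(−log σ)` against the latent
log scale (≈ 0.96 at spread 0.4), and trial noise in the SD estimate
(≈ 0.90 at 14 trials, ≈ 0.99 at 100). At the published 14-trials-per-cell
design a generative ρ = 0.5 is recovered as r ≈ 0.42 on average; recovery
analyses in the tests and acceptance script use 100 trials per cell so that
the estimator, not trial noise, is what is being checked, and the 14-trial
attenuation is quantified in its own test rather than hidden.

## Association pipeline

The sophistication total is residualized on age and matrix score by least
squares with an intercept (`residualize_x_only`, the default) and the
residuals are correlated with each z-scored precision measure; p-values
come from the t transform of r with df = n − 2. `residualize_both`
residualizes both sides and equals the closed-form higher-order partial
correlation (df = n − 2 − k); it is used for the additional
frequency-perception partial when a perception condition is present.
Missing rows are removed listwise with a logged count. The Holm family
defaults to the sophistication × precision associations within one
experiment; the adjusted p-value is the step-down cumulative maximum
`max_j≤i (m − j + 1)·p(j)` capped at 1.

**Dependent-correlation comparison.** Two correlations sharing the adjusted
sophistication score are compared by resampling participants with
replacement (default 5000 resamples) and computing `r(x,y1) − r(x,y2)` per
resample. Two p-values are reported: a one-sample t test of the resampled
differences against zero, and the percentile p
`2·min(frac ≤ 0, frac ≥ 0)`. The t test treats the B resampled differences
as independent observations, so its standard error shrinks with √B and it
rejects far too often under an equal-correlation null; the percentile p is
the calibrated quantity (≈ 5% null rejection at n = 50 in the acceptance
check) and should be the one interpreted. Both are emitted because both
conventions exist in the literature for this resampling scheme. Degenerate
resamples (zero variance) are redrawn with a logged count; more than 10%
redraws aborts. With a fixed seed the resampling indices depend only on the
seed and n, which makes the comparison exchangeable: swapping y1 and y2
negates the t statistic and preserves both p-values exactly.

**Power.** The required sample size for detecting a correlation r uses the
Fisher-z approximation `n = ⌈((z_{1−α/2} + z_power)/atanh r)² + 3⌉`, floored
at 4; r = 0.40 at α = 0.05 (two-tailed) and power 0.80 gives 47.

## Numerical and design choices

- Sample SDs use the n − 1 denominator throughout.
- Pearson r is computed from centred inner products and clipped to [−1, 1]
  against rounding; p-values are two-sided everywhere.
- Reported degrees of freedom follow a single convention (n − 2, minus k
  for full partials); published df conventions vary and are not
  reverse-engineered.
- "Resampling with replacement" is a participant-level bootstrap; a
  permutation proper would sample without replacement and would test a
  different (exchangeability) null.
- The AM-noise envelope is `1 − d/2 + (d/2)·sin(2πft)` (phase 0), spanning
  [0, 1] at full depth; any fixed phase/DC convention yields the same
  modulation percept. Masker pips are contiguous and unramped; WAV export
  is mono 16-bit PCM peak-normalised to −1 dBFS.
- Reports serialise with sorted keys and fixed indentation, so identical
  seed + config gives byte-identical files.
- Problem sizes in the recovery and calibration analyses (100 end-to-end
  runs at n = 500 with 100 trials per cell; 500 calibration simulations of
  500 resamples at n = 50) were chosen so each Monte-Carlo rate has a
  binomial standard error well inside the band being checked.

## Known limitations

- The inverse-SD statistic is a pure spread measure; it does not separate
  memory precision from guessing (no mixture modelling), by design.
- The generator's covariate links are linear and weak; it cannot probe
  nonlinear confounding.
- The bootstrap comparison assumes the two correlations share rows
  one-to-one; unbalanced missingness across measures is handled by listwise
  deletion before resampling, which can discard information.
- Visual stimuli are parameterised only; no visual rendering or masker
  synthesis is attempted.
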