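# hrrhythm

Analysis of stress-related heart-rate *rhythm* in wearable data. Consumer
smartwatches record a smoothed 1 Hz heart-rate stream (each sample is the
average over the preceding 60 s) alongside self-reported stress timestamps.
Average heart rate alone is a weak stress marker — it is confounded by
activity, posture, and circadian phase — so this package characterises the
*temporal structure* of the signal around stress events instead: how
persistent, how predictable, how long-range-correlated the rhythm is.

It is aimed at researchers working with naturalistic wearable cohorts
(e.g. students self-reporting stress over a semester) who want the full
chain from raw CSVs to a paired stress-vs-normal comparison table, plus a
synthetic-cohort generator to validate every stage without access to raw
participant data.

## Method

For each participant the pipeline:

1. **Filters artifacts** — samples below 60 bpm or above the age-predicted
   maximum (220 − age) are removed as sensor errors.
2. **Windows the signal** — a 20-minute window (±10 min) around each stress
   report, and an equal number of randomly placed, disjoint *normal*
   windows per participant for balance.
3. **Tests stationarity** — Augmented Dickey–Fuller test per window
   (constant term, AIC lag selection under the Schwert bound); first-order
   differencing `x'ₜ = xₜ₊₁ − xₜ` is then applied to all windows uniformly.
4. **Extracts ACF features** — from the correlogram with a 95% band
   (±1.96/√n): the number of *significant lags* (|r_k| above the band, a
   persistence measure) and the number of *peaks* (strict local maxima, a
   roughness measure).
5. **Runs DFA** — detrended fluctuation analysis on the 300 samples after
   the event: integrate the profile `y_k = Σᵢ≤k (xᵢ − x̄)`, detrend in
   equal segments of size s (order-1 polynomial, segments taken from both
   ends so the remainder is covered), pool RMS residuals into F(s), and
   fit the scaling exponent α as the slope of log F(s) vs log s.
   α ≈ 0.5 is white noise, α ≈ 1.0 pink (1/f) noise, α ≈ 1.5 Brownian
   motion.
6. **Compares groups** — features averaged per participant within each
   label, then a paired t-test across participants (ACF features on the
   differenced transform, α on the actual signal). Monotonic trends in
   event frequency (e.g. over hours of the day) use the Mann–Kendall test
   with tie-corrected variance and continuity correction.

The synthetic generator produces 1 Hz cohorts with a circadian sinusoid,
long-range-correlated noise built by spectral synthesis (power spectrum
f^(−β) with β = 2α − 1, so the DFA exponent of the output converges to the
configured α), stress episodes with an elevated mean and a separately
targeted α spliced in with a short cross-fade, and a configurable fraction
of out-of-range artifacts.

## Worked example

```bash
python analysis/01_simulate_cohort.py      # 10 participants, 1 day each
python analysis/02_preprocess_windows.py
python analysis/03_extract_features.py
python analysis/04_compare_stress_normal.py
python analysis/05_descriptive_summary.py
python analysis/06_parameter_recovery.py
```

Step 04 prints the comparison table for the default cohort (stress α
target 0.63 vs normal 0.61, 13 events per participant):

```
                 parameter test_transform  t_statistic  p_value  n_pairs  mean_normal_actual  mean_stress_actual
Number of significant lags    differenced    -0.051589 0.959983       10           19.869231           28.215385
           Number of peaks    differenced    -1.160871 0.275558       10          189.884615          187.584615
  Scaling Exponent (Alpha)         actual     0.935407 0.373996       10            0.630593            0.637041
```

The α row recovers the injected direction (stress 0.637 > normal 0.631);
with only 10 participants and a 0.02 exponent gap the paired test is, as
expected, not significant — step 06 shows that a clearly separated
contrast (α 1.0 vs 0.7, +8 bpm) is recovered with a significant paired t
in every cohort, while matched null cohorts show no systematic direction:

```
effect cohorts (5): stress>normal alpha in 5, significant lags in 5, alpha paired-t significant in 5
null cohorts (5): stress>normal alpha in 2 (no systematic direction expected)
```

The same pipeline is scriptable via the `hrrhythm` CLI
(`simulate`, `preprocess`, `features`, `compare`, `run-all`), e.g.

```bash
hrrhythm simulate --outdir cohort/ --n-participants 10 --seed 0
hrrhythm run-all --samples cohort/samples.csv --events cohort/events.csv --outdir out/ --seed 0
```

## Layout

- `src/hrrhythm/` — the library: `synthetic_data`, `preprocessing`,
  `stationarity`, `acf_features`, `dfa`, `trend_tests`, `descriptive`,
  `pipeline`, `cli`.
- `analysis/` — numbered drivers reproducing the full analysis sequence,
  writing tables under `results/`.
- `tests/` — unit, property and end-to-end suites, including naive
  reference implementations used as oracles.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  details and limitations.
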