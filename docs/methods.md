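# Methods

## Signal model

The pipeline treats each participant's recording as a 1 Hz bpm series in
which every sample is a 60 s trailing average. Consequences of that
smoothing: values are fractional, beat-to-beat (RR-interval) variability
is unobservable, and all rhythm statements concern the *smoothed* rate.
Nothing in this package estimates heart-rate variability.

The synthetic generator emulates the features the analysis is sensitive
to:

- **Circadian baseline.** A single 24-h sinusoid, acrophase 15:00,
  default amplitude 7 bpm on an 80 bpm baseline. Real daytime heart rate
  has meals, activity bouts and posture changes on top of this; the
  generator deliberately omits them, so passing tests demonstrate
  correctness of the machinery, not robustness to activity confounds.
- **Long-range-correlated noise.** Spectral synthesis: complex Gaussian
  Fourier coefficients scaled by f^(−β/2), β = 2α − 1, inverse-FFT,
  standardised to zero mean and unit variance. This maps the target DFA
  exponent α onto the spectral exponent exactly in theory (white α = 0.5
  ↔ β = 0; pink α = 1.0 ↔ β = 1; Brownian-spectrum α = 1.5 ↔ β = 2), and
  the generator's output recovers α to within ~0.01 at n = 2¹⁴ (checked
  over seeds in the test suite). A Davies–Harte fGn construction would
  give exact finite-sample covariances but is unnecessary at this
  accuracy.
- **Stress episodes.** Within ±600 s of each event the noise is replaced
  by a segment generated at `stress_alpha` and the mean is raised by
  `stress_mean_shift`; both are applied through a short (≤30-sample)
  linear cross-fade so the two regimes' exponents remain independently
  verifiable and no artificial step edge is introduced. Event times are
  drawn uniformly with rejection so stress windows never overlap; the
  generator refuses configurations that cannot fit.
- **Artifacts.** A fraction `artifact_rate` of samples is replaced by
  values drawn uniformly from [30, 59] or [221 − age, 250] (coin flip
  between low and high). Only the filter bounds are principled; the
  artifact *distribution* is a modelling choice, and uniform keeps every
  artifact unambiguously outside the valid band.

Default conditions: 10 participants, 1 day at 1 Hz, 13 events each,
artifact rate 6.2%, age 22, normal/stress α = 0.61/0.63, shift 10 bpm
(putting stress-window means near 93 bpm). These mirror the cohort-level
statistics of the naturalistic student study this analysis targets, at
desk scale: the real cohort wore watches for ~90 days and numbered 117,
which only affects statistical power, not any estimator.

A deliberate mismatch with real data: the generator's normal-regime
noise (α < 1) is stationary, so nearly all raw synthetic windows pass
the ADF test, whereas real heart-rate windows are mostly non-stationary.
The protocol differences *all* windows uniformly regardless of the
per-window ADF outcome, so this mismatch does not alter the analysis
path; the ADF results are recorded for reporting only.

## Preprocessing

Filter: keep 60 ≤ x ≤ 220 − age; both bounds inclusive ("below"/"above"
read strictly). The filter is idempotent and reports the removed
fraction. Windows keep whatever filtered samples fall in their span; a
window is retained when it holds ≥ 80% (configurable) of the expected
2·half_width/Δt + 1 samples. Events too close to a recording boundary
are dropped with a warning. Stress windows from events closer than
20 min overlap and both are kept — self-reports are not deduplicated.
Normal windows are placed by seeded rejection sampling, uniform over
centers whose spans avoid every stress span and every previously placed
normal span; when eligible time runs out the shortfall is warned about
and the participant contributes fewer pairs.

## Stationarity

ADF regression with a constant and no trend term (windows have a
nonzero mean; no deterministic trend is posited). Lag order: AIC
selection below the Schwert bound ⌊12(n/100)^¼⌋, capped to keep the
regression overdetermined. Decision level 0.05. Constant windows are
degenerate (NaN statistic, flagged), not errors.

## ACF features

Biased estimator (lagged covariance over n and total variance), FFT
path, checked against an explicit double loop to 1e-10. Default band is
the constant white-noise band 1.96/√n; Bartlett's cumulative band is
available by flag but changes the *significant lags* feature's meaning
(it tests each lag against the null that all lower lags are real, not
white). Default `max_lag` is 600 — half the nominal 1201-sample window.
The band is calibrated for lags ≪ n; at lags comparable to n the biased
estimator's variance (n−k)/n² pushes the false-positive rate below
nominal, which is acceptable for a feature used comparatively between
matched groups. Peaks are strict interior local maxima; ties break
toward non-peak so the count is conservative and deterministic. Whether
"peaks within the 95% confidence interval" should count only significant
peaks is genuinely ambiguous; both readings are implemented
(`peaks_significant_only`), default = all strict local maxima.

## DFA

Profile = cumulative sum of deviations from the window mean. Both-ends
segmentation: ⌊n/s⌋ segments from the start and the same number from
the end, so a non-multiple remainder is covered by the backward pass
(at the cost of double-counting the interior overlap) instead of being
discarded. Per-segment detrending by least squares on a centred/scaled
abscissa (order 1 by default); residuals pooled into one RMS per scale.
Scales: ~15 log-spaced integers in [4, n/4], deduplicated after
rounding; α is the OLS slope of log₁₀F on log₁₀s with R² reported.
Scales with zero or non-finite fluctuation are dropped with a warning;
fewer than 4 survivors or a scale span under 4× is an error. DFA runs
on the *actual* (undifferenced) window — it tolerates non-stationarity
by construction, and differencing would shift α by one. The default
span is the 300 samples after the window center (the five minutes
following the stress report), with `dfa_span="full"` available; the
post-event span is the one the comparison is designed around, since the
autonomic stress response unfolds after the report.

## Tests and comparison

Mann–Kendall: S over all ordered pairs, tie-corrected variance
(n(n−1)(2n+5) − Σt(t−1)(2t+5))/18, ±1 continuity correction, two-sided
normal p by default (one-sided by flag). All-tied input is degenerate
(S = 0, p = 1). Paired t: per-participant averages first, then one
stress−normal difference per participant; participants lacking either
label drop out of the pairing and are listed in the manifest.
Zero-variance differences are degenerate. Three uncorrected p-values
are reported, matching the protocol's reporting style; no
multiple-testing correction is applied by default. The report tests the
ACF features on the differenced transform and α on the actual signal,
and carries group averages for both transforms (α has no differenced
column by construction).

## Descriptive summaries

Weekday/hour binning uses local naive timestamps by truncation; week
starts Monday, weekend = Sat+Sun, per-day rates = weekday total/5 and
weekend total/2. Event-count sd is the sample sd, defined as 0 for a
single participant. The hourly trend test applies Mann–Kendall to the
24-bin counts restricted to a possibly midnight-wrapping span.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; each participant's stream is keyed on
(seed, CRC-32 of the participant id) so participants are reproducible
in isolation. Reruns with the same config and seed produce
byte-identical CSV/JSON outputs; the manifest records config, seed,
library versions and per-stage row counts (not wall-clock time, which
would break bit-reproducibility). Problem sizes in the analysis drivers
and test suites — 1-day recordings, 10-participant cohorts, 2¹⁴-sample
calibration series, 20-cohort recovery runs — were chosen as the
smallest sizes at which the estimators' sampling noise is clearly below
the effects being checked.

The parameter-recovery experiment uses a deliberately detectable
contrast (α 1.0 vs 0.7, +8 bpm) rather than the default 0.63/0.61:
recovery experiments ask whether the pipeline sees an injected effect
at all, and the small empirical gap between the defaults is an estimate
from a 117-participant cohort, not a generator target a 10-participant
synthetic cohort could be expected to resolve (the worked example in
the README shows exactly that: right direction, not significant).

## Limitations

- No activity, posture, respiration or motion-artifact model beyond the
  uniform out-of-range artifact rate; real wearable confounds are out of
  scope.
- Self-report timing error is not modelled; episodes are centred exactly
  on their timestamps.
- Single-slope DFA only: no crossover detection or multifractal
  extension.
- The ACF/DFA features are computed per window and compared between
  groups; no within-participant longitudinal (e.g. semester-phase)
  modelling is included.
- Event times are uniform in time by default, so diurnal/weekday event
  structure present in real cohorts is absent unless injected by the
  caller.
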