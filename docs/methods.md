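# Methods

## Synthetic chronic iEEG (`synth`)

Each record simulates a chronic 16-channel implant (desk scale: 4 channels)
as a sum of independent band-limited Gaussian processes per clinical band,
plus white noise. Three independent random streams (signals, event process,
diary) are derived from one seed via `SeedSequence([seed, stream])`, so the
event schedule is invariant to how the signal stream is consumed.

- **Seizures** follow a Poisson process with a refractory dead time; the
  requested monthly rate r is dead-time corrected (λ = r / (1 − rτ)) so the
  realized rate matches the configured one. Ictal discharges are
  large-amplitude sinusoids on all channels for the ictal duration.
- **Pre-ictal signature**: over the horizon before each onset, the power of
  one configured band on a subset of channels is ramped multiplicatively up
  to a peak gain of `1 + effect_size · σ₀/μ₀`, i.e. `effect_size` is in
  units of the band feature's baseline z-score. `effect_size = 0` yields an
  exact null record.
- **AED confound**: a slow multi-day concentration cycle (geometric
  pharmacokinetic closed form) modulates baseline band power on all
  channels, mimicking drug-level drift.
- **Diary**: each true event is reported with a miss probability, and
  spurious events are added by an independent Poisson process, reproducing
  the diary/iEEG discrepancy documented in the trial table.

## Feature bank (`features`)

Features are enumerated channel-major over (channel, filter, analyzer):
16 × 6 × 3 = 288 at clinical scale. Filters are the six clinical bands
scaled by the ratio of the actual Nyquist to a 200-Hz reference Nyquist,
so the bank is well defined at reduced sampling rates. Analyzers are three
energy statistics of the band-filtered epoch signal. Epochs are 13.8 s
(desk scale 240 s), non-overlapping, floor-truncated to the record. The
AED-stability screen computes the Spearman correlation of each feature
series with the simulated AED level and excludes features whose correlation
exceeds a permutation-calibrated threshold; it disables itself (with a
warning) when the AED level is constant.

## Labeling and training (`train`)

Epochs fully contained in `[onset − horizon, onset)` are pre-ictal
(a 30-min horizon over 13.8-s epochs gives ⌊1800/13.8⌋ = 130 positive
epochs per isolated onset); epochs intersecting the ictal interval or the
1-h post-ictal window are excluded, and exclusion takes precedence.

Selection uses 10-fold **block-wise** cross-validation (contiguous,
time-ordered blocks; earliest blocks absorb the remainder). Forward
selection adds the feature that maximizes mean out-of-fold balanced
accuracy until the improvement falls below a tolerance or 16 features are
reached; backward elimination then removes features whose removal does not
cost more than the tolerance. The classifier is linear discriminant
analysis with convex shrinkage toward a scaled identity,
`(1 − s)Σ + s·(trΣ/p)I`, computed in closed form (verified against
scikit-learn's `lsqr + shrinkage` solver); fold statistics are obtained by
subtracting held-out blocks from totals, so CV cost is independent of the
number of folds.

The likelihood series used for evaluation is the pooled out-of-fold
likelihood, and the advisory state over epoch *i* is computed from the
likelihood of epoch *i − 1* (one-epoch causal latency), so an onset can
only be credited to a warning raised before the data containing it existed.

## Advisory state machine (`advisory`)

Likelihood above θ_high maps to red, below θ_low to blue, otherwise white,
with an optional minimum dwell that absorbs single-epoch flickers. A raised
red warning additionally **persists for one pre-ictal horizon of epochs**
after the last supra-threshold epoch (`red_hold`): the warning is a claim
that a seizure is likely within the horizon, so it remains active for that
long. The published description leaves the minimum red duration
unspecified; this persistence rule is the implemented stand-in. θ_high is
calibrated by bisection so that the *delivered* (post-hold) red time
fraction matches the red target (default 0.25, cf. the trial's mean 23%
time in red); θ_low is the blue-target quantile.

Auxiliary clinical logic: seizure clustering (events within 8 h of the
previous cluster member collapse into one lead event), eligibility
screening (2–12 collapsed events/month, no 30-day seizure-free internal
gap), leading seizures (sufficient recorded history before onset), and the
data-collection completion rule (≥ min leading seizures within a sliding
window).

## Chance-corrected metrics (`metrics`)

State time fractions are accumulated as exact rationals, so they sum to 1
identically. With n onsets and red time fraction ρ, the red gate tests
K ≥ k against Binomial(n, ρ) (upper tail) and requires sensitivity > 0.65;
the blue gate tests K ≤ k (lower tail). Either gate passing at α = 0.05
advances the patient. The likelihood ratio compares seizure rates in high
vs moderate advisory time and renders as the `ALL` sentinel when no
seizure fell in the moderate state. Degenerate timelines (ρ = 0 or 1) are
reported as "not evaluable" rather than tested.

## Desk scale and recovery experiment

The desk-scale preset (4 channels at 0.2 Hz, 240-s epochs, 30-day records,
~8 seizures/month, 8 selected features max) makes a full pipeline run cost
about one second, enabling seed sweeps. With effect size 2, the red chance
test rejects at α = 0.05 in 47/50 seeds (0.94 > 0.90); the three failures
are one record with a single seizure (untrainable, counted as a failure)
and two records whose signature band was not selected. With effect size 0,
the rejection rate is 4/200 = 0.02 ≤ 0.05 + 3·SE(200) ≈ 0.096, and the
overall advancement rate (either gate) is 14/200 = 0.07, also within
tolerance.

## Trial table (`trial`)

`data/first_in_man_trial.csv` transcribes the published per-patient
results; `summarize_table` recomputes every printed average with the
table's half-up rounding convention, including per-column sample sizes
(frequencies over 14 patients, sensitivities over the 10 advisory-phase
patients, NPV over the 5 blue-enabled patients, likelihood ratios over the
8 finite values), the discrepancy-ratio extremes 0.06–13.51, and the
undefined ratio for the patient with no iEEG-confirmed seizures.
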