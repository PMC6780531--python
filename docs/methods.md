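# Methods

## Study design being emulated

The package models a paired pacing experiment: patients undergoing
percutaneous implantation of a self-expanding aortic valve are atrially
paced (AAI mode, ventricles activated through native conduction) in
bursts of ≥30 s at 50, 60, …, 120 bpm, once before any intervention
(baseline phase) and once immediately after prosthesis release
(released phase). Valve release commonly produces an intrahisian
conduction delay resembling left bundle branch block, so the released
phase has a widened QRS at otherwise controlled heart rates. Burst-level
interval values are means of three consecutive beats after discarding
the first ten (`average_burst`), which is when ECG intervals have
stabilized at the new rate.

Within each burst the QRS-T complex is decomposed as

```
QT = QRS + QRSend-Tpeak + Tpeak-Tend
```

(depolarization, plateau/early repolarization, late repolarization /
transmural dispersion). All durations are stored in milliseconds; the
cycle length RR is carried in seconds alongside the pacing rate.

## Synthetic cohort generator

### Structure

For patient *i* at rate *r* (defaults in parentheses):

* Baseline QRS: `QRS_i ~ N(98.50, 21.78²)` ms, constant across rates and
  bursts — depolarization time is rate-invariant over 50–120 bpm in this
  design.
* Widening: `dQRS_i ~ N(32.5, 13.77²)` ms; released QRS is
  `QRS_i + dQRS_i` everywhere. The SD is taken as
  `sqrt(25.77² − 21.78²)`: the released-phase QRS spread treated as
  baseline spread plus independent patient-level widening variance.
* Baseline QT: `mu[r] + sqrt(f)·s[r]·z_i + sqrt(1−f)·s[r]·e_{ir}` with a
  shared standard-normal patient score `z_i`, per-rate total SDs `s[r]`
  and between-patient fraction `f = 0.7`. Per-rate totals match the
  configured SDs exactly while patients keep their rank across rates.
  The per-rate means and SDs default to the printed per-frequency values
  of the reference cohort (`DEFAULT_QT_*` in `synthetic_cohort`).
* Released QT: the *realized* baseline QT plus `dQRS_i`, plus an
  independent patient-level `extra_i ~ N(0, s_extra²)` (repolarization
  prolongation beyond the widening itself), plus a deterministic
  per-rate calibration offset that pins the released per-rate
  expectation to the configured released means. Because the released
  value inherits the baseline burst noise, δ quantities carry only
  patient-level variance; this idealization is what makes the configured
  δ-QT/δ-QRS coupling exactly recoverable.
* Sub-intervals: Tpeak-Tend is drawn around its phase/rate mean
  (baseline 87.0 ms; released adds a base shift plus a high-rate rise,
  defaults 0 below 100 bpm and +6/+10/+14 ms at 100/110/120 bpm, with
  the base shift chosen so the phase-mean δ-Tpeak-Tend is +4.07 ms);
  QRSend-Tpeak is the remainder `QT − QRS − Tpe`, so the sum
  decomposition holds to machine precision. Infeasible configurations
  (a non-positive expected sub-interval at any rate/phase) are rejected
  at validation time with the offending rate and phase named.

### Correlation targeting

The headline coupling is the pooled per-burst Pearson correlation
between δ-QT and δ-QRS (default target ρ = 0.79). Under the model,

```
δ-QRS(i, r) = dQRS_i
δ-QT(i, r)  = dQRS_i + extra_i + d(r)
```

where `d(r)` is the deterministic calibrated per-rate δ-QT expectation.
Pooling over the rate ladder adds the between-rate variance
`Var_r(d)` (≈ 41.7 ms² under the default calibration) to the δ-QT
variance without contributing covariance, so the generator sizes

```
s_extra² = max( sd(dQRS)²·(1/ρ² − 1) − Var_r(d), 0 )
```

which yields a pooled correlation of ρ in expectation and reduces to the
simple `sd·sqrt(1/ρ² − 1)` rule when the calibrated per-rate δ-QT means
are flat. If the between-rate spread alone already exceeds the implied
total (ρ close to 1 with strongly rate-dependent calibration), the
clamp at zero applies and the realized correlation falls below the
target; the default calibration is far from this regime.

### Attrition

Two released-phase loss mechanisms, both off by default: complete loss
of the released phase (third-degree AV block after release, probability
`p_av_block`) and truncation of the released rate ladder at a random
lower Wenckebach point (probability `wenckebach_released_drop`).
Baseline bursts are never altered. Attrition, sex assignment and each
patient's interval draws use separate RNG substreams of the single
config seed, so toggling one knob never perturbs the others.

### What the generator does not emulate

Beat-to-beat QT/RR hysteresis within a burst, QRS-morphology classes,
rate-dependent QRS shortening at high frequencies, biochemical or
hemodynamic confounders, and the exact per-rate availability pattern of
the reference study's tracings (its 96 paired tracings from 23 patients
imply an unreported attrition pattern; the default generator produces
complete ladders, 184 pairs). Passing tests therefore demonstrate
correctness of the pipeline and internal consistency of the calibrated
model — not that real paced cohorts behave this way.

## Derived statistics

* `qt60_reference`: the patient's measured QT at 60 bpm per phase (mean
  if several bursts; optional linear interpolation from the 50- and
  70-bpm rungs, disabled by default).
* `qtc_deviation = QT60 − QTc` per burst; identically zero at 60 bpm for
  the four rate-only formulas.
* `phase_contrast`: released − baseline within patient at the same rate;
  unpaired patient/rates are skip-logged, never silently dropped.
  Cohort summaries average burst-level deltas by default (every paired
  tracing counts once); a `patient_first` flag switches to
  patient-mean-of-means since either convention is defensible.

## Inference

All CIs and tests resample patients with replacement (cluster
bootstrap); within-patient correlation is preserved by construction.

* CI95: percentile interval, default `n_boot = 2000`;
  bias-corrected-accelerated (BCa) available via `ci_method="bca"` with
  a delete-one-patient jackknife for the acceleration term.
* Two-sided p for H0: θ = 0: recentred bootstrap,
  `p = (1 + #{|θ* − θ̂| ≥ |θ̂|}) / (B + 1)`.
* Degenerate replicates (statistic undefined, e.g. a zero-variance
  correlation resample) are redrawn, capped at 10× `n_boot` attempts.
* `rate_trend`: identity-link Gaussian working model (ordinary least
  squares) for the slope on rate in ms/bpm, with cluster-bootstrap
  inference so no parametric error assumption is leaned on; requires
  ≥ 3 distinct rates.
* `bonferroni`: `min(1, p·m)` with `m` at least the number of p-values.

## Numerical and design choices

* Formula units: the linear corrections are implemented as
  `QT[ms] + 154·(1 − RR[s])` (Framingham) and
  `QT[ms] + 1.75·(HR[bpm] − 60)` (Hodges) — the only dimensionally
  coherent reading of the conventional second-based constants 0.154 and
  0.00175, and the one that reproduces the calibration aggregates. The
  Rautaharju heart rate is always `60/rr_s` of the burst, never supplied
  independently.
* Averaged intervals keep full float precision; reports round to 0.1 ms,
  machine-readable CSVs do not round.
* CSV round-tripping uses shortest-repr floats and `round_trip` parsing,
  so write∘read∘write is byte-identical; rows are sorted by
  (patient_id, phase, rate_bpm).
* Sum-decomposition tolerance: 5 ms for measured data (manual caliper
  measurements are not exactly additive), 1e-6 ms for generated truth.
* The Wenckebach point is not serialized; on read it is inferred as the
  highest rate present per phase.
* Rare-tail guards in the generator: QT is truncated 1 ms below the
  cycle length, and Tpeak-Tend is nudged to keep both repolarization
  sub-intervals ≥ 0.5 ms; with default conditions both guards are
  ~5σ events and have no measurable effect on any summary.
* Equal-weight desk oracles (`equal_weight_table2_oracle`,
  `equal_weight_deviation_oracle`) apply the formulas directly to
  per-rate mean QT values with equal rate weights. Since all formulas
  are linear in QT, formula-of-mean equals mean-of-formula, making the
  oracle an exact independent check on the pipeline's expectations; it
  differs from burst-count-weighted study aggregates by ≲ 0.4 ms.

## Problem sizes

The test suite and the acceptance script use replicate means over 40
default 23-patient cohorts for phase contrasts and deviations, one
2000-patient cohort for correlation recovery, 500 simulations (200
patients, 1000 resamples) for CI coverage and 1000 null simulations
(23 patients, 400 resamples) for the type-I error of the paired test —
sizes at which the Monte-Carlo standard errors are several times
smaller than the tolerances being checked, while the whole suite runs
in well under a minute.

## Known limitations

* The δ noise model (released inherits baseline burst noise) makes
  within-pair measurement error vanish; real paired tracings would add
  ~√2·(burst SD) of noise to each δ, attenuating the pooled correlation.
  The calibration absorbs this by construction rather than modeling it.
* Percentile bootstrap CIs undercover mildly at n = 23 (≈93–95 %
  empirical coverage in the suite's simulations); BCa narrows but does
  not eliminate this.
* The printed baseline QT SD at 100 bpm (2.08 ms) is implausibly small
  next to its neighbours (~17–27 ms) and is used as configured; it only
  reduces noise at one rung of the ladder.
* Formula comparisons beyond the implemented five (spline or
  subject-specific QT/RR fits, QT−QRS subtraction) are out of scope.
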