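# circphase

Circadian phase prediction for rotating shift workers from wrist-worn
light and activity recordings.

Knowing the phase of a worker's circadian clock — conventionally indexed by
the core body temperature minimum (CBTmin) or the urinary
6-sulphatoxymelatonin (aMT6s) acrophase — makes it possible to anticipate
windows of impaired alertness on night shifts. Direct melatonin assays are
impractical in the field, so `circphase` estimates phase by simulating a
limit-cycle oscillator model of the human circadian pacemaker driven by
ambulatory actigraphy, and provides the full surrounding analysis: rest
scoring, cosinor reference phase from urine collections, prediction-error
evaluation, and a synthetic shift-worker cohort generator for testing every
stage without access to field data.

## The model

The pacemaker is a forced Van der Pol-type oscillator in the state plane
(x, x_c), where x tracks the daily core body temperature variation:

    dx/dt  = (π/12) [ x_c + μ (x/3 + 4x³/3 − 256x⁷/105) + B(t) + N(t) ]
    dx_c/dt = (π/12) { L_q B(t) x_c − x [ (24/(0.99729 τ_c))² + L_k B(t) ] }

with photic and non-photic drives modulated by the oscillator state:

    B(t) = B̂(t) (1 − l_s x)(1 − l_s x_c)
    N(t) = N̂(t) (1 − tanh(a_s x))

B̂(t) is the output of a dynamic light processor (Process L): a
photoreceptor pool with activated fraction n, activation rate
α(I) = α₀ (I/I₀)^p driven by photopic lux, recovery rate β, and drive
B̂ = G α (1 − n), so bright-light onset produces a strong drive that adapts
as the pool depletes. N̂(t) is a square wave over scored main rest
intervals, ρ(1/3 − σ) with σ = 1 during rest. Defaults: μ = 0.13,
τ_c = 24.2 h, L_q = 1/3, L_k = 0.55, l_s = 0.4, a_s = 10, α₀ = 0.05 min⁻¹,
β = 0.0075 min⁻¹, G = 33.75, p = 0.5, I₀ = 9500 lux, ρ = 0.032.

Running the model in photic-only mode (N ≡ 0) or with both drives (the PNP
model), the CBTmin events — interpolated local minima of x(t) — are read
out as predicted aMT6s acrophases and compared against the cosinor acrophase
of block-collected urinary aMT6s, with prediction error defined as measured
minus predicted, wrapped to (−12, 12] h (negative shift = phase delay).

## Worked example

Generate a small synthetic cohort (7-ish diurnal days at habitual sleep
23:16–07:23, then 3–5 night shifts 20:00–08:30 with daytime sleep
09:20–15:57 and calibrated dim workplace light) and run both model variants:

```sh
circphase simulate --out demo --n-subjects 3 --seed 42
circphase run demo --mode both --out demo_report
```

From `demo_report/cohort_report.json`, subject S00:

```
mid_sleep_h            3.265     # average diurnal mid-sleep (clock h)
measured  diurnal 3.72  night 4.67  shift −0.95   # cosinor aMT6s reference
PNP model diurnal 2.86  night 5.35  shift −2.49   # predicted acrophases
errors    diurnal +0.85  night −0.68               # measured − predicted (h)
```

The subject's clock is measured to delay by 0.95 h across the night block;
the PNP simulation, initialized from mid-sleep and driven only by the
recorded light and rest pattern, predicts a delay as well (−2.49 h), placing
its night-shift acrophase within 0.7 h of the measured one. The cohort
summary (`demo_report/summary.csv`) collects, per schedule and model, the
mean and absolute-mean errors, the fraction of subjects within ±30/60/120
min, correlation and paired-t statistics, and direction-of-shift accuracy
(here 3/3 delays predicted correctly by both models).

The library surface mirrors the pipeline: `circphase.model` (oscillator,
light processor, CBTmin extraction), `circphase.actigraphy` (ingestion,
rest scoring, mid-sleep, non-photic input), `circphase.cosinor` (excretion
rates, cosinor acrophase, phase shift), `circphase.evaluation`
(error summaries, direction accuracy, reaction-time consequence of a phase
error), `circphase.synthetic` (cohort generator), `circphase.pipeline`
(subject/cohort orchestration).

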