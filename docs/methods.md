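# Methods

## Pacemaker model

The core is a forced Van der Pol-type limit-cycle oscillator for the human
circadian pacemaker. The state (x, x_c) follows

    dx/dt  = (π/12) [ x_c + μ (x/3 + 4x³/3 − 256x⁷/105) + B(t) + N(t) ]
    dx_c/dt = (π/12) { L_q B x_c − x [ (24/(0.99729 τ_c))² + L_k B ] }

x is interpreted as the daily variation of core body temperature (its local
minima are the CBTmin phase markers); x_c is the Liénard complementary
variable. The seventh-order restoring term flattens the limit cycle toward
unit amplitude (max |x| ≈ 1.00); the empirical factor 0.99729 in the
stiffness makes the simulated free-running period equal τ_c rather than the
harmonic approximation 24/τ_c·24 — with defaults, 30 unforced days give a
mean CBTmin spacing of 24.200 h.

Model constants and their defaults:

| symbol | meaning | default | units |
|---|---|---|---|
| μ | nonlinearity stiffness | 0.13 | – |
| τ_c | intrinsic period | 24.2 | h |
| L_q, L_k | photic coupling into dx_c/dt | 1/3, 0.55 | – |
| l_s | light sensitivity of the photic modulator | 0.4 | – |
| a_s | activity sensitivity (tanh gain) | 10.0 | – |
| α₀ | photoreceptor activation rate at I₀ | 0.05 | min⁻¹ |
| β | photoreceptor recovery rate | 0.0075 | min⁻¹ |
| G | photic drive gain | 33.75 | – |
| p | lux-compression exponent | 0.5 | – |
| I₀ | reference illuminance | 9500 | lux |
| ρ | non-photic drive magnitude | 0.032 | – |

The oscillator constants are the published values for this model family.
The light-processor constants and ρ are taken from the same model lineage's
standard phototransduction formulation; they are defaults, not fitted
values, and every one is overridable through the YAML config (`tau_c:`,
`ls:`, `rho:`, ...). No per-individual parameter fitting is attempted —
every subject is simulated with the same parameter set, which is a known
source of under-dispersion in predicted phases relative to real cohorts.

### Light processing

Within each one-minute epoch the recorded lux is constant, so the
photoreceptor equation dn/dt = 60[α(I)(1−n) − βn] (time in hours) is linear
with constant coefficients and is advanced by its exact exponential update;
B̂ = G α (1−n) is evaluated at each epoch start. This makes the processor
exactly reproducible and immune to stiffness at bright-light steps. At the
reference illuminance the fixed point is n* = α₀/(α₀+β) ≈ 0.870,
B̂* ≈ 0.220. n(t₀) starts at the fixed point for the first epoch's lux,
removing an arbitrary start-up transient.

### Integration

Fixed-step classical Runge–Kutta on the one-minute epoch grid, drives held
constant within each epoch and the state-dependent modulators re-evaluated
at every substage. Rationale: deterministic output with no adaptive-solver
heuristics, verified three ways — halving the step changes x by < 10⁻⁶
(with the epoch drives held fixed), an adaptive high-order reference
(DOP853 at rtol 10⁻¹¹) agrees to < 10⁻⁴ over 14 days, and the photic-only
mode is bit-identical to the PNP mode with N̂ ≡ 0. Note that *regenerating*
B̂ on a finer grid changes the drive itself (the processor output is
sampled per epoch), which perturbs x by ~10⁻⁴; this is a property of the
epoch representation, not integrator error.

### Phase markers and initialization

CBTmin events are local minima of x refined by a three-point parabolic
interpolation; minima closer than 16 h (sub-cycle wiggles) resolve to the
deeper one, and a non-oscillating trajectory raises an error rather than
returning an empty list. Predicted aMT6s acrophase on a calendar date is
the CBTmin event dated to that day — the two markers are equated, with a
configurable fixed offset defaulting to 0 (whether the original analyses
used a nonzero offset is not documented; 0 is the conservative choice).

Initialization places the state on the unit circle from a CBTmin clock
estimate: θ = 2π(t₀ − t_CBTmin)/24, x = −cos θ, x_c = sin θ, assuming
uniform angular velocity over the 24 h day (an entrained rhythm's angular
velocity, not τ_c's) and unit amplitude. The CBTmin estimate is the average
diurnal mid-sleep time (heuristic mode) or the measured diurnal aMT6s
acrophase ("oracle" mode). Limitation: the true limit cycle's nadir has
x_c ≈ −0.10 rather than 0, so this harmonic placement makes the first
simulated nadir arrive 0.4–0.8 h early depending on phase; the transient
decays over the first days of integration and is dominated by light-driven
entrainment well before the prediction dates. Tests of
initialization-date self-consistency therefore use a 1 h band rather than
exact equality.

## Actigraphy processing

Rest scoring operates on the smoothed activity series (11-minute centred
median): candidate intervals are maximal runs below 40 counts/min whose
mean lux is below 10 lux; runs of ≥ 3 h are main rest, shorter runs are
naps and never enter the non-photic input. Candidates separated by < 60 min
of dim epochs are merged — an automated, reproducible stand-in for the
manual boundary adjustment used with commercial scoring software whose
thresholds are proprietary. These defaults are validated against the
synthetic generator (exact recovery at zero noise, ≤ 10 min at default
noise), not claimed to replicate any vendor algorithm.

Off-wrist gaps overlapping an expected sleep window (derived from the work
diary: daytime window 09:20–15:57 after night shifts, otherwise nocturnal
23:16–07:23) by ≥ 50% of the window duration are imputed as rest with lux
and activity zeroed; other gaps carry lux 0 (a conservative no-drive
assumption) with a logged warning. Mid-sleep is the circular (vector) mean
of main-interval midpoints on the 24 h circle — linear means break for
clusters straddling midnight, and the circular mean provably minimises the
summed squared chord distance, which a grid-search oracle confirms.

## Reference phase (cosinor)

Each urine block contributes an excretion rate, concentration × volume /
duration (ng/h). A fixed-24 h single-component cosinor,
M + A·cos(2π(t−φ)/24), is fitted by ordinary least squares in the linear
(M, a, b) parametrisation; φ = atan2(b, a)·24/2π as a clock time, and the
zero-amplitude significance test is the regression F-test, flagged (not
silently dropped) at α = 0.10. Design choice: when block boundaries are
known, the cosine/sine regressors are their exact block averages rather
than midpoint evaluations. With equal blocks the two are identical up to a
common attenuation, but with the mixed 4 h/8 h collection pattern midpoint
regressors bias φ by up to ~0.1 h, while block-averaged regressors recover
the generating phase exactly (and return the unattenuated amplitude); point
samples without block information fall back to midpoint regressors.
Measured phase shift is diurnal acrophase minus night acrophase wrapped to
(−12, 12], so delays are negative.

## Evaluation

Prediction error is measured minus predicted, wrapped to (−12, 12] h. The
group summary reports mean ± SD of raw error, absolute mean error, range,
the fraction of subjects within ±30/60/120 min (inclusive thresholds),
Pearson r between measured and predicted, and a paired t-test implemented
as the one-sample t of the wrapped errors against zero (the only consistent
formulation on the circle, identical to the usual paired t away from the
wrap). Direction-of-shift accuracy counts sign agreement, with zero shifts
correct only against zero, and reports false-advance/false-delay counts.

The reaction-time consequence analysis takes any phase-binned RT profile
(uniform bins over 360°, 0° = CBTmin, 15°/h) and reports, per bin, the mean
absolute RT change under a ±Δ phase error with circular indexing, plus an
effect size. The published forced-desynchrony RT dataset is external to
this package, so the operation runs on user-supplied or synthetic profiles.
Effect-size denominator: the within-bin dispersion of the profile — the
original formula is not documented, so this interpretation is explicit and
configurable by supplying a different dispersion column.

## Synthetic cohorts

The generator emulates the field protocol: per subject, 2–14 diurnal days
(mean ≈ 7) with habitual sleep 23:16–07:23, then 3–5 consecutive night
shifts 20:00–08:30 with daytime sleep 09:20–15:57, evening shifts filling
the diurnal roster. Waking light is log-normal: indoor median 150 lux with
outdoor excursions (median 2000 lux, ~0.1 bouts/h of 30 min) on the diurnal
schedule, and on the night schedule a single log-normal with
μ = 3.9526, σ = 2.3362 on log-lux — the exact solution of the two field
quantile constraints (24% of waking epochs < 10 lux, 61% < 100 lux).
Activity is two-state Poisson (≈150 counts/min awake, ≈1 asleep, 0 in
zero-noise mode): the simplest process that exercises the scoring
thresholds. Urine profiles integrate a cosine excretion rate exactly over
the 4 h/8 h block pattern with optional multiplicative log-normal noise;
true acrophases are drawn at 3.97 ± 1.1 h (diurnal) with shifts of
−1.35 ± 1.0 h, mirroring the field cohort's moments. All generators are
deterministic per seed, and cohort output is byte-identical across reruns.

What the generator does not emulate: melatonin suppression by light,
seasonal/commute light structure, realistic sleep fragmentation, or any
coupling between a subject's true circadian phase and their generated light
exposure. Consequently the end-to-end tests establish that the pipeline is
internally consistent (cosinor closure at zero noise; ≥ 80% predicted
delays under night-shift light; direction accuracy on matched truths) — not
that the model's biology is validated on real shift workers.

## Problem sizes and defaults used in checks

Free-running-period runs use 30 simulated days (29 cycles); entrainment and
reference-integrator checks use 14 days; the end-to-end cohort properties
use 25 subjects with the schedule ranges above. These sizes put every
quantity well past its transient while keeping the whole suite quick to
run.

## Known limitations

- Single parameter set for all subjects: inter-individual variance in
  predicted phase is necessarily compressed relative to measured phase.
- Photopic lux input: wrist-worn photopic lux under-represents the
  short-wavelength (melanopic) sensitivity of the circadian system; the
  model may underestimate responses to dim indoor light.
- Phase-only validation: the pipeline scores acrophase timing, not
  amplitude, sleep quality, or homeostatic performance effects.
- The harmonic initialization transient (above) adds up to ~0.8 h of
  first-day phase error that decays with integration time; predictions
  anchored within a day of the start date inherit part of it.
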