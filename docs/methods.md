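# Methods

This note records the models implemented in `magstim`, the defaults and why
they were chosen, the numerical choices that matter, and what the synthetic
cohort does and does not establish about real measurements.

## Coil field model

The drive coil is a three-layer solenoid of 54 turns of 4 mm hollow copper
wire, 11 cm long, 27 cm inner winding diameter.  `build_loop_stack` expands
that schedule into one filamentary circular loop per turn:

* **Radial convention.** The inner winding diameter is read as naming the
  inner *surface* of the innermost wire layer, so layer k sits at wire-center
  radius `D_in/2 + d_wire/2 + k·d_wire` → 137/141/145 mm.  The drawing does
  not state this; the convention is configurable through `CoilGeometry`.
* **Axial convention.** The 18 turns of a layer are spread evenly over the
  full 11 cm with pitch `L/18` ≈ 6.1 mm, centered on z = 0, so the wire
  envelope spans exactly the stated length.  (Close-winding 18 turns of 4 mm
  wire would span only 72 mm, contradicting the stated length.)
* Each loop's field is evaluated with the standard complete-elliptic-integral
  expressions (closed form on axis).  The implementation is verified in the
  tests against direct Biot–Savart line integration to 10⁻⁶ relative at
  random field points.
* The hollow conductor is collapsed onto a filament at the wire center; the
  neglected current-distribution detail is far below the few-percent accuracy
  of interest.

**Known limitation.** The model is magnetostatic.  It yields 224.3 µT/A at
the coil center, whereas the finite-element reference for this geometry is
212 µT/A (measured: 214 at center, but 288 measured vs 272 simulated at
r = 100 mm, bracketing our 309).  All geometry conventions we examined
(wire-center vs inner-surface radii, pitch-centered vs end-inclusive spacing)
land in 222–227 µT/A, and the loop formula itself is exact, so the ~5%
difference is a property of the reference model (plausibly AC
current-redistribution/proximity effects, or winding spacing details absent
from the published geometry), not of the summation.  We report the honestly
computed magnetostatic value rather than adjusting the geometry to match.

## Drive circuit and pulse shaping

Tuned operation puts a capacitor bank in series with the coil; at resonance a
step-sinusoid voltage produces a current envelope `1 − e^{−t/τ_nat}` with
`τ_nat = 2L/R`.  Since R differs per capacitor configuration, the voltage
envelope is pre-distorted,

```
v_tuned(t) = V0 [1 − ((τ_des − τ_nat)/τ_des) e^{−t/τ_des}] sin(2πft),
```

to force a common current ramp `τ_des = 25/f` (25 cycles at every frequency);
untuned (≤ 700 Hz) drives apply the plain exponential envelope directly.
Shaping fidelity requires `τ_des ≥ τ_nat` (otherwise the envelope overshoots
V0; the code warns).

* **Inductance.** L is not published.  The default 0.87 mH is the
  least-squares value of `1/((2πf_res)²C)` over the high-frequency
  (capacitance, resonance) pairs of the bank; the pairs at and above 8 kHz
  individually imply 0.863–0.878 mH.  Below ~8 kHz the printed capacitances
  drift from this L (possibly a series/parallel reconfiguration); the bench
  therefore drives each configuration at the exact `1/(2π√(LC))` resonance.
* **Series resistances.** The per-configuration R values are not published.
  `BENCH_NATURAL_TAU_CYCLES` is a synthetic bench table of natural ramp-ups
  (in cycles), anchored at the two characterized conditions (12.7 cycles at
  4.04 kHz; 22.3 cycles at 35.4 kHz, the study maximum) and kept below the
  25-cycle target everywhere.  The shaping result is insensitive to the
  specific values, which only set how much pre-distortion is exercised.
* **Integration.** `simulate_current` uses fixed-step classical RK4 at the
  trace sample rate (default 256 samples/cycle; 64 minimum enforced), with
  the sampled drive voltage linearly interpolated to half-steps.  At 256
  samples/cycle the local error is ≪ the 1–2% envelope tolerances used in
  validation.  Envelope fits use the full trace; steady-state voltage
  amplitudes use a linear sin/cos quadrature fit over the final 25% of
  samples.
* **Phase convention.** Current lags voltage; fits report φ ∈ (−π, π] as a
  free parameter.  At resonance |φ| < 2°; untuned, φ ≈ −arctan(2πfL/R).

## Psychometric threshold estimation

The probability of a subject reporting a sensation at peak amplitude B (mT at
coil center) is logistic with threshold `B_th` (50% point) and width
`B_width`.  `fit_sigmoid` maximizes the Bernoulli likelihood by damped Newton
iterations on standardized amplitudes, with a tiny ridge (10⁻⁴ on the
standardized slope) so the objective stays bounded near separation —
standardization makes the estimates exactly equivariant under unit changes.
Perfectly separable data short-circuit to the midpoint rule (`B_th` = center
of the separating gap, `B_width = max(floor, gap/4)`, flagged): the
unpenalized MLE diverges there, and real titrations do produce near-separable
records (widths down to a few µT).  The width floor defaults to one tenth of
the titration fine step.

The virtual titration mirrors the experimental protocol: coarse ascent in
~10 mT steps below 1 kHz / ~5 mT above (start = one coarse step) until the
first reported sensation; then 24 fine pulses in an up/down staircase with
step = (first positive amplitude)/80, refitting the sigmoid after every
response.  Reaching the amplifier ceiling without a sensation yields a
censored record — a valid outcome, not an error.  Two guards matter in
practice: the fine staircase clips the running estimate to the explored
amplitude neighborhood (an ill-conditioned interim fit — e.g. one lucky
positive below many negatives — must not fling the next pulse to absurd
amplitudes), and a final estimate cannot exceed the ceiling actually probed.
The staircase rule and the 24-pulse count are package choices; the
experimental record suggests 10–30 pulses per titration but states no rule.

## Population statistics under censoring

Per-frequency thresholds across subjects are modeled N(mean, sd²).  Subjects
censored at the amplifier ceiling enter the cohort denominator only.
`pooled_cdf_fit` fits the Gaussian CDF to the empirical
fraction-of-cohort-stimulated curve: midpoint plotting positions
`(i − ½)/N` at the i-th smallest observed threshold, **plus one anchor point
per distinct ceiling** at `(#observed ≤ ceiling)/N` — the stimulated fraction
is known exactly there, and without that anchor the fit is badly
underdetermined at heavy censoring (Monte Carlo: mean recovered within
0.5 mT in ~57/100 cohorts without the anchor vs ~93/100 with it, against
~100/100 for the right-censored maximum-likelihood estimator, which is
implemented as `censored_mle` and used as the independent cross-check).
The sd floor is 10⁻³ mT.

Between-frequency comparisons use the two-sided independent-samples Student
t-test (Welch optional).  In the pipeline, censored subjects enter the
comparison at their censoring bound.  This is a deliberate, conservative
substitution: censoring removes exactly the highest thresholds, so an
observed-only test of the high-frequency rise has ~38% power at 5/8
censoring, while the bound substitution (which can only *understate* the
rise) restores ~94% power.  It also mirrors the experimental situation in
which censored subjects were stimulated nowhere below the amplifier maximum.

Bland–Altman test–retest summaries report the mean difference and
`mean ± 1.96·SD` limits with the population (ddof = 0) SD of the
differences, and per-pair percent changes relative to the first measurement.

## Strength-duration analysis

`fit_sdc` fits `B_rheo (1 + 1/(2 τ_chron f))` to pooled mean thresholds by
unweighted nonlinear least squares using only frequencies at or below the
cutoff (default 10 kHz, where the hyperbolic model is conventionally
applicable), initialized at `B_rheo = min(thresholds)`, `τ_chron = 200 µs`,
bounded positive.  Residuals are reported at *all* frequencies: systematic
positive residuals above ~25 kHz are the quantitative readout of the model's
high-frequency breakdown.  Plotted against the IEC effective duration
`t_eff = 1/(πf)` the hyperbola is exactly affine
(`B_rheo + B_rheo·π/(2τ_chron)·t_eff`), which the tests verify.

The generic IEC `t_eff` operator (amplitude difference of the first two
waveform extrema over the maximum slope between them) finds extrema by sign
changes of the discrete derivative, treating slopes below 10⁻³ of the maximum
as plateaus — so trapezoid plateaus register as peaks and the operator
returns the inter-plateau ramp time, while sampled sinusoids reproduce
`1/(πf)` to < 0.5% at ≥ 1024 samples/cycle.

Total-pulse-duration scaling uses
`B_norm(T) = 1 + α e^{−(T/β)^γ}` with α = 0.44, β = 4.32 ms, γ = 0.60, T
strictly in milliseconds (enforced at the interface).  Thresholds convert
between durations as `B·B_norm(T_target)/B_norm(T_measured)`; the infinite-
duration (continuous-wave, MPI-relevant) limit divides by `B_norm(T_measured)`
alone.  The conversion composes exactly and, for fixed 256-cycle pulses,
grows monotonically with frequency.

## Synthetic cohort: what it emulates, what it does not

Ground truth per subject is

```
B_i(f) = s_i · B_rheo (1 + 1/(2 τ_chron f)) · (1 + a · max(0, ln(f/f_k))^q)
```

* The logarithmic-power rise factor is an artifact choice: the experimental
  record motivates a minimum near 20–25 kHz and a ~39% rise to 88.1 kHz but
  offers mechanisms (ion-channel time constants, beta dispersion), not an
  equation.  The form is smooth, inactive below the knee, and calibrable with
  two parameters.  Defaults `B_rheo = 4.4 mT`, `τ_chron = 405 µs`,
  `f_k = 16.9 kHz`, `a = 0.1756`, `q = 2` place the population minimum at
  ~20 kHz and give `B(88.1 kHz)/B(25.3 kHz) = 1.390`; the calibration was
  fixed once from those two targets (closed-form solve for `a` at `q = 2`,
  grid-search verification) and is asserted by a test.  `a = 0` recovers the
  pure hyperbolic SDC and serves as the null control in the pipeline tests.
* Subject factors `s_i` are lognormal with median 1 and CV 0.15 (the observed
  between-subject CVs span 9.1–23.2% across frequencies); psychometric widths
  are 3% of the local threshold.
* Amplifier ceilings default to infinite except at 600 Hz, 700 Hz and
  88.1 kHz, where they sit at the population 75th / 37.5th / 37.5th
  percentiles — the quantiles whose expected censoring counts reproduce the
  observed pattern (2/8, 5/8, 5/8).
* Randomness: one master seed; each (subject, frequency, run) titration draws
  from its own `SeedSequence` spawn, so any single titration is reproducible
  in isolation.  Retest runs draw fresh response streams from the same truth
  (no drift term), consistent with ≤ 10% observed test–retest variability.

What passing the synthetic end-to-end tests shows: the estimation chain
(titration → censored pooling → SDC fit → duration scaling → comparison)
recovers a known truth of the right shape and magnitude, with the right
censoring behavior, in ≥ 80% of cohorts.  What it does not show: anything
about the biology of real thresholds between the sampled frequencies, the
true shape of individual curves, or demographic structure — the generator is
a stand-in, not a nerve model.

## Problem sizes used in validation

Circuit validation simulates 256-cycle pulses at 256 samples/cycle for all
ten tuned configurations; psychometric and population Monte-Carlo checks use
100–1000 replicates; the end-to-end replication runs 100 full cohorts
(8 subjects × 16 frequencies each).  The complete suite runs in about a
minute on one core.
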