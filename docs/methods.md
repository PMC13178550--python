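# Methods

## Scope and model overview

`thermosweat` implements the computational chain of a standardized-heat-load
exercise-thermoregulation study: participants walk on a treadmill at a fixed
rate of metabolic heat production per unit body surface area
(Hprod = 300 W·m⁻²) in a WARM (30 °C, 40 % RH) or HOT (40 °C, 30 % RH)
chamber, and the analysis asks how sweating — whole-body sweat rate (WBSR),
ventilated-capsule local sweat rate (LSR) and the sweating onset threshold —
varies with age and biological sex once body-size confounding is removed by
the Hprod/BSA standardization.

The package has four analysis layers plus a synthetic-study generator:

1. **Partitional calorimetry** (`heat_balance`). Steady-state heat budget in
   W·m⁻²: metabolic rate M from VO₂ and RER (substrate interpolation between
   19.62 kJ·L⁻¹ for fat and 21.13 kJ·L⁻¹ for carbohydrate), external work
   against gravity on the incline, convective and radiative exchange with
   coefficients hc = 6.51·v^0.391·(Pb/760)^0.55 and
   hr = 4εσ(Ar/BSA)·T̄³, respiratory losses as the standard two-term linear
   function of M, ambient temperature and vapour pressure, the evaporative
   requirement Ereq = Hprod − (C + R + Eres+Cres), and the environmental
   maximum Emax = ωmax(Psk,s − Pa)/(Re,cl + 1/(he·fcl)) with the Lewis
   relation he = 16.5·hc·(760/Pb)^0.45.  Saturation vapour pressure uses the
   Antoine equation with the standard water constants (mmHg form,
   A = 8.07131, B = 1730.63, C = 233.426), which tracks steam tables within
   0.3 % over 1–100 °C.  Ereq/Emax > 1 marks uncompensable heat stress.
   The budget is steady-state: no transient heat-storage term is modelled,
   matching the study design in which trial means are analysed.

2. **Sweat metrics** (`sweat_metrics`). WBSR from the pre/post nude-mass
   difference corrected for respiratory water loss (evaporative respiratory
   heat in absolute watts divided by the 2426 J·g⁻¹ latent heat) and for
   metabolic gas-exchange mass (VO₂·(1.977·RER − 1.429) g·min⁻¹, the STPD
   CO₂-out-minus-O₂-in densities).  LSR from capsule flow × absolute-humidity
   gain / covered area (0.5 L·min⁻¹, 4.0 cm² defaults), clamped at zero
   because influent air is anhydrous so negative excursions are sensor noise.
   Mean skin temperature uses the Ramanathan four-site weighting
   (0.3 chest, 0.3 shoulder, 0.2 thigh, 0.2 calf).  Resampling offers
   left-closed one-minute window means (onset analysis) and the minute mean
   at each five-minute mark (trajectory analysis).  The hydration gate is
   USG < 1.025, with 5 mL·kg⁻¹ of water prescribed otherwise.

3. **Onset detection** (`onset`). The onset threshold t₀ is the changepoint
   where the LSR–time relation departs from a line into an asymptotic rise:

       LSR(t) = a + b·t                               t ≤ t₀
       LSR(t) = a + b·t₀ + A·(1 − exp(−k(t − t₀)))    t > t₀

   Continuity at t₀ is enforced for identifiability; the rise is
   monoexponential by default with a logistic alternative behind a switch.
   Fitting profiles the conditionally linear parameters (a, b, A ≥ 0) over a
   t₀ grid at 0.1-min resolution crossed with a small grid of rate constants
   k, then refines all five parameters with bounded nonlinear least squares.
   Ties on a flat RSS profile break toward the smallest t₀.  An F-test
   against the single-line null (α = 0.05) converts non-improvement into an
   explicit "no onset detected" result rather than an error.  90 % CIs for
   t₀ come from a parametric bootstrap (500 resamples by default, seeded,
   refitting on a window around the estimate) or, for large simulation
   studies, a delta-method interval from the linearized fit — the pipeline
   and recovery harnesses use the delta method because bootstrap cost scales
   with the hundreds of series they process, and the two agree closely at
   study noise levels (empirical t̂₀ SD 0.18 min vs mean delta-method SE
   0.17 min at σ = 0.05 mg·cm⁻²·min⁻¹).

   The second stage regresses the fitted onsets on sex, centred age and
   their interaction.  Although each onset carries a CI, the between-
   participant onset scatter (SD ≈ 1 min) dominates the within-series
   estimation error, so pure inverse-CI-width weights would be strongly
   anti-conservative.  Weights are therefore random-effects style,
   wᵢ = 1/(seᵢ² + τ²), with τ² the between-participant variance estimated by
   the method of moments from an unweighted pilot fit — the meta-analytic
   treatment of a two-stage estimator.  Null simulations put the 90 %
   interval coverage of this model at ≈ 0.90.

4. **Hierarchical inference** (`inference`). The WBSR model is a normal
   linear model on sex, centred age (grand mean, 13 years for children) and
   their interaction, with participant random intercepts activated when any
   participant contributes repeat trials.  Priors are weakly informative
   normals — intercept 500 ± 200 g·h⁻¹, sex 0 ± 200, age 0 ± 100 (the
   interaction shares the age prior) — and half-normal priors (scale = the
   response SD) on the residual and random-intercept SDs.  Sampling is
   Gibbs with conjugate coefficient draws; scale parameters take
   slice-sampling steps (stepping-out on the log scale), and with random
   intercepts the scales are updated from the collapsed likelihood with the
   intercepts integrated out (per-participant covariance σ²I + τ²J) before
   the intercepts are redrawn — a blocked-Gibbs scheme that removes the
   u↔τ coupling which otherwise keeps τ's effective sample size in the tens.

   Trajectories (LSR or gastrointestinal temperature over exercise time)
   use a hierarchical generalized additive model: a cubic B-spline smooth of
   time (8 basis functions), a sex-specific deviation smooth, a linear-age
   time-varying coefficient and participant random intercepts.  The
   second-difference penalty on each smooth is expressed as a random-effect
   variance and sampled; a normal prior anchors the time-0 intercept
   (37.0 ± 1 °C for Tgi, 0.2 ± 0.2 mg·cm⁻²·min⁻¹ for LSR).  The full
   coefficient vector is conditionally Gaussian and drawn jointly by one
   Cholesky solve per iteration; scales are slice-sampled.  A weak proper
   ridge keeps the penalty null spaces identified.

   Summaries are posterior means with equal-tailed 90 % credible intervals
   and the probability of direction, Pd = 100·max(P(x>0), P(x<0)) ∈
   [50, 100] %, zeros split evenly.  Convergence uses rank-normalized
   split-R̂ and bulk ESS (via ArviZ); the WBSR model raises when any R̂
   exceeds 1.01.  Default chains: 2 × (500 warmup + 1000 kept) for WBSR,
   2 × (400 + 800) for the GAM.

## Synthetic-study generator

`synthetic.TruthParams` holds every latent quantity; all randomness flows
from one integer seed through numpy's PCG64, so a fixed seed reproduces a
study exactly.  The generator emulates:

- **Cohorts** sampled from the study-population distributions (boys
  13.5 ± 1.4 yr, 55.4 ± 14.8 kg, 1.65 ± 0.12 m; girls 13.3 ± 1.9,
  51.0 ± 9.1, 1.59 ± 0.09; adults analogous), truncated at ±3 SD and at the
  group age ranges; BSA is always derived from sampled mass and height.
- **Trials** with belt speed set by stature (5.0/5.5/6.0 km·h⁻¹ below
  1.55 m / to 1.70 m / above), RER ~ N(0.85, 0.05), and the treadmill
  incline and VO₂ solved by root-finding an ACSM-style walking-economy
  relation so the realized Hprod/BSA equals 300 W·m⁻² plus trial noise
  (SD 10 W·m⁻²).  Mean skin temperature is N(34.0, 0.5) °C in WARM and
  N(37.2, 0.5) °C in HOT; these unreported values were solved by hand from
  the heat-budget equations so that cohort-mean Ereq/Emax lands near the
  reported 1.1 (WARM) and 1.3 (HOT) with the reported dry-exchange signs,
  and they are configurable.
- **Mass ledgers** that close exactly: nude mass change equals integrated
  sweat (1.6 g·h⁻¹ per W of Ereq by default) + respiratory + metabolic mass
  loss before optional scale noise.
- **LSR series** at the 5-s capsule cadence: baseline 0.05, onset
  t₀ = 13.0 + 0.25·(age − 13) + 0.6·1[male] + N(0, 1) min on the chamber
  clock (10 min seated rest then 45 min walking, so the default onset falls
  3 min into exercise), monoexponential rise (k = 0.30 min⁻¹) to a plateau
  proportional to the trial's Ereq/Emax (0.72 per unit at the back, ×0.78
  at the arm, so HOT plateaus exceed WARM ones), plus AR(1) noise
  (ρ = 0.8 at 5 s, marginal SD 0.05 mg·cm⁻²·min⁻¹, a figure consistent with
  the ~19 % between-day CV reported for ventilated-capsule LSR).
- **Tgi trajectories** as a saturating rise (time constant 20 min) scaled by
  0.13 °C per W·kg⁻¹ of heat production.

What the generator does **not** emulate — and hence what passing recovery
tests cannot certify about real data: hygrometer drift and calibration
error, acclimatization and fitness effects, menstrual-cycle phase,
non-stationary baselines, dropout/missingness, and any nonlinearity of the
true age effects.  The generator draws from the same model families the
analyses fit, so recovery tests certify the estimation machinery, not the
model's adequacy for field data.

## Numerical choices and degenerate inputs

- Temperatures are °C at every interface; Kelvin appears only inside hr.
- Barometric pressure defaults to 760 mmHg; Re,cl is a resistance
  (m²·kPa·W⁻¹, value 0.01) so Emax is dimensionally consistent; g₀ is
  9.81 m·s⁻².  The Du Bois height exponent defaults to the canonical 0.725
  with the tabulated 0.72 selectable; both reproduce the cohort table to
  2 dp.
- Emax ≤ 0 (ambient vapour pressure at or above skin saturation) returns the
  non-positive value with a warning rather than raising.
- The onset fitter requires ≥ 15 points and 3 per segment; the slice sampler
  floors scales at 10⁻⁶ so an exactly interpolating fit cannot produce an
  improper conditional; flat LSR series yield "no onset detected".
- Resampling propagates empty windows as missing values.

## Problem sizes

The test and benchmark harnesses use: 1000 randomized budgets for the
conservation identity and 100 for oracle equivalence; 20 participants per
child group per condition (40 trials per condition) for generator/analyzer
consistency; 200 replicates for onset recovery (45 one-minute samples each);
100 replicates of 40 participants for covariate-effect recovery; 200 null
replicates for interval-coverage calibration; 2 × 20 000 iterations for the
AR(1) ESS check.  These sizes give Monte-Carlo standard errors comfortably
below the tolerances being checked while keeping a full run in minutes.

## Known limitations

- The GAM's age effect is linear in age by construction (a time-varying
  coefficient), matching the study design but unable to express nonlinear
  maturation effects.
- The two-stage onset analysis (fit each series, then regress onsets) is
  transparent and testable but does not propagate changepoint-location
  uncertainty jointly as a single hierarchical model would; the
  random-effects weighting recovers calibrated intervals in simulation.
- Posterior computations use this package's own Gibbs/slice samplers, not a
  general PPL; agreement is at the level of parameter recovery and interval
  calibration, not draw-by-draw parity with any other sampler.
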