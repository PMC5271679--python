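# Methods

## Induction forward model and fit

The single-turnover induction model treats PSII closure as sequential
photon capture with exciton sharing between neighbouring centres. Per
flashlet of dose *E* (quanta Å⁻²) the closed fraction advances by
ΔC = E σ_PSII (1 − C)/(1 − ρC), and the observed yield is
F = F0 + (FM − F0) C(1 − ρ)/(1 − ρC). At ρ = 0 this reduces to Poisson
target theory, C = 1 − exp(−σ_PSII D) for cumulative dose D; the package
verifies that limit to 10⁻³ relative for flashlet doses ≤ 0.001/σ. No
relaxation is modelled between flashlets: the default 128 µs train is well
below the 200–500 µs Qa→Qb electron-transfer time, so a closed centre
stays closed for the duration of the train.

Two conventions were genuinely open and are fixed as follows. The
fluorescence sample for flashlet *k* reflects the closure accumulated over
flashlets 1..k−1, so the first flashlet of a dark-adapted trace reads
exactly F0 (the alternative — sampling after the flashlet's own dose —
only shifts the dose axis by half a flashlet and changes no fitted
parameter beyond solver tolerance at 40 flashlets). The fourth fitted
parameter is the connectivity ρ; instruments and fitting codes differ on
this choice, and ρ is the standard fourth parameter of the
single-turnover literature this model comes from.

The fit is unweighted least squares (`scipy.optimize.least_squares`,
bounded 0 ≤ ρ ≤ 0.995, σ ≥ 0) with deterministic initialisation: F0 from
the first flashlet, FM from the trace maximum, σ from a through-origin
regression of −ln(1 − normalised rise) on cumulative dose, ρ = 0.2.
Confidence half-widths come from the linearised covariance
s²(JᵀJ)⁻¹ with Student-t quantiles at n − 4 degrees of freedom; FV/FM
uses the delta method. Monte-Carlo checks (noise sd 0.005 on yields of
order 1, 100 seeds) put the σ CI coverage at ~94%. Flat traces (relative
range < 10⁻³) are rejected as having no variable fluorescence rather than
returning a degenerate fit.

## Dose bookkeeping

Doses are carried in both photons m⁻² and quanta Å⁻² (1 m² = 10²⁰ Å²
exactly; 1 µmol photons = 6.022 × 10¹⁷ photons), so cross sections in
Å² quanta⁻¹ multiply directly into photons PSII⁻¹. Cumulative incident
dose through period *n* sums intensity × duration from period 2 onward:
the initial dark period is excluded by convention (it emits nothing under
the standard protocol, but the exclusion is explicit so that a protocol
with a lit first period still reproduces the convention). Delivered dose
accrues per period as incident dose × that period's measured σ_PSII′2s,
honouring acclimation-driven drift in the cross section.

## Treatment protocol and synthetic time courses

The standard protocol is ten 327 s periods: dark, growth irradiance,
seven treatment periods at the shift intensity/colour, and a terminal
20 µmol photons m⁻² s⁻¹ recovery period. The generator's forward model
is exactly the kinetics the fitting side inverts:

- yields decay as A·exp(−σᵢ·D) in cumulative incident dose over the
  dose-accruing periods, with A = (FM − F0)/FM;
- sustained NPQ depresses every treatment-period value by a constant
  offset (default 0.02) that relaxes fully in the recovery period;
- the recovery period is modelled as accruing no photoinactivation dose.
  At 20 µmol photons m⁻² s⁻¹ its contribution to the exponent is ≤ 0.5%
  of the treatment dose; treating it as zero makes the NPQ correction an
  exact inverse of the generator's depression, so noiseless full-pipeline
  recovery is exact rather than merely close. Real instruments do deliver
  that small dose; for measured data the effect is far below the CI of
  any fitted rate.

Measurement noise is additive Gaussian (default sd 0.01) on the F0′2s and
FM′2s levels; FV′2s/FM′2s and its 95% half-width follow by the delta
method for the ratio, floored at 10⁻³ to avoid infinite weights.
σ_PSII′2s gets multiplicative Gaussian noise (default 2% relative) and is
constant across periods by default — which makes Φᵢ = σᵢ/σ_PSII′2s an
exact identity — with an optional linear per-period drift to emulate
photoacclimation. All randomness flows from one seeded
`numpy.random.Generator` per preset.

The bundled presets describe a *Prochlorococcus*-like culture grown at
260 µmol photons m⁻² s⁻¹ and shifted to 1200 µmol photons m⁻² s⁻¹ of blue
(σᵢ = 1.23 × 10⁻⁴ Å² quanta⁻¹, σ_PSII′2s = σᵢ/Φᵢ ≈ 170.8 Å²) or red
light (σᵢ = 1.65 × 10⁻⁵, σ_PSII′2s ≈ 58.9 Å²); dark-adapted levels
F0 = 0.45, FM = 1.0 give a realistic cyanobacterial FV/FM of 0.55.
Excitation-pressure targets (0.60 blue, 0.45 red) set the synthetic FS
between F0′ and FM′. What the generator does *not* emulate: instrument
electronics (gain, PMT saturation), spectral weighting of dose by cellular
absorbance, PSII repair kinetics (the measurement design assumes repair is
blocked), and state transitions. Passing recovery tests therefore shows
the estimators invert the stated kinetics under the stated noise — not
that real traces obey those kinetics.

## Decay fits and the sustained-NPQ correction

Both decay fits are two-parameter (amplitude, rate) weighted nonlinear
least squares with analytic Jacobian, rate bounded at 0, initialised from
a log-linear regression of ln(yield) on dose. Points entering the fit are
the dose-accruing periods (growth + treatment) plus the initial dark
measurement anchoring zero dose; the recovery period is excluded. The
weight is 1/CI (the literal inverse of the 95% half-width), with 1/CI² as
a sensitivity option; weights are treated as relative, so scaling all CIs
by a constant leaves the point estimates unchanged. CIs on (amplitude,
rate) use the linearised covariance with weighted residual variance at
n − 2 degrees of freedom; R² is the weighted one.

The sustained-NPQ influence is max(0, yield_recovery − yield_final
treatment) and is added to every treatment-period yield (growth-period and
dark values are untouched; corrected values are capped below 1). A
missing recovery period raises an error that names the zero-correction
override rather than silently skipping the correction.

A caveat the implementation makes measurable: the correction's offset is
estimated from a single (noisy) recovery measurement and then applied to
all treatment points coherently. That correlated error is invisible to
per-point CIs, and CI coverage of σᵢ drops from ~91% (uncorrected fits of
noisy series) to ~57% when the noisy correction is applied. Coverage
claims in the test suite therefore refer to the weighted fit itself;
uncertainty on NPQ-corrected rates from noisy recovery measurements should
be interpreted cautiously (a bootstrap over the recovery measurement would
be the remedy, and is out of scope here).

## Excitation pressure

F0′ = F0 / ((FM − F0)/FM + F0/FM′2s) estimates the open-centre
fluorescence under actinic light from dark-adapted levels; 1 − qP =
1 − (FM′ − FS)/(FM′ − F0′). The pipeline reports the value after the
first treatment period (the series is nearly flat from the first exposure
onward); a flag returns the per-period series. Values outside [0, 1] are
clamped with a warning rather than rejected, since modest noise in FS or
FM′ routinely produces small excursions.

## Regressions

Rate-versus-intensity and rate-versus-pressure regressions use weighted
least squares (statsmodels WLS) with the same 1/CI weighting and relative
weights; "±" values are standard errors, intercepts carry a
significant-at-0.05 flag. The interaction test fits y ~ x × group for a
binary factor and reports the group and interaction p-values; under a
true null at realistic noise its type-I error measures ~4% at α = 0.05
over 500 replicates. Growth rates µ come from ordinary regression of
ln(RFU) on time in days.

## Energy budget

Electron return is σ_PSII′2s · qP · I and the inactivation event rate is
σᵢ · I, both via the exact 6.022 × 10⁻³ quanta Å⁻² s⁻¹ conversion. Cost
constants (1.96 × 10⁵ e⁻ per de novo PSII; 5.77 × 10³ e⁻ per PsbA+PsbD
turnover; 1.33 e⁻/ATP informational) are configuration with those
defaults; their derivation from protein composition is outside the
package's scope. qP is taken from the first treatment period,
consistent with the excitation-pressure convention. The bundled
*Synechococcus*-like budget scenario uses σ_PSII′2s = 250 Å²,
qP(I) = 1/(1 + I/Ek) with Ek = 300 µmol photons m⁻² s⁻¹, and
σᵢ(I) = 3.75 × 10⁻⁵ + 1.0 × 10⁻⁷·I — magnitudes typical of high-light
grown cells under blue light — and keeps repair comfortably viable across
150–1500 µmol photons m⁻² s⁻¹.

## Problem sizes and numerical choices

Default analyses are small by construction: 40-point induction traces,
9-point decay fits, tens of treatments per regression. Monte-Carlo
properties in the test suite use 100 seeds (CI coverage) and 500
replicates (type-I error, estimator bias), enough for the binomial
standard error on a 95% coverage estimate to be ~2%. Solver tolerances
are set to 10⁻¹⁵ so noiseless round trips recover generating parameters
to ≤ 10⁻⁶ relative; ties and degenerate inputs (flat traces, rising decay
series, collinear designs, missing recovery periods) raise typed errors
or pin parameters at bounds with warnings, as documented per module.

## Known limitations

- The NPQ-correction coverage caveat above.
- Weight = 1/CI follows the field's stated practice but is not the
  inverse-variance optimum; the 1/CI² option exists for sensitivity
  analysis, and with strongly heteroscedastic CIs the two give different
  point estimates.
- Connectivity ρ and σ_PSII are correlated in induction fits; at high ρ
  and coarse flashlet doses the linearised CIs become optimistic.
- Spectral quality enters only through which σᵢ/σ_PSII values are fitted;
  no absorbance-spectrum weighting of dose is performed.
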