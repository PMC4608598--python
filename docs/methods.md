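# Methods

This note documents the models, estimators and numerical choices behind
antioxkit, and what the simulation studies do and do not demonstrate.

## Scope

The package analyses four complementary antioxidant assays — DPPH radical
scavenging, hydroxyl-radical competition on 2-deoxyribose, beta-carotene
bleaching, and the cellular antioxidant activity (CAA) assay — together
with the validation arithmetic of a binary virtual screen (ROC AUC,
enrichment factor, hit rate).  Raw plate data for the reference compound
panel were never deposited, so the packaged reference tables are fixtures
for ordering and magnitude checks only; every quantitative claim about the
estimators is made on synthetic data with known ground truth.

## Signal reduction

* **DPPH.** Absorbance at 516 nm converts to radical concentration through
  the calibration line `[DPPH] = (A + 2.58e-3) / 12509` mol/L.  The
  response is `%DPPH remaining = Af/A0 * 100`.  `A0` is pooled — the mean
  of the control-series readings (the radical is stable without a
  scavenger, so every control reading measures the working solution),
  falling back to the mean of t = 0 readings.  `Af` is the mean over the
  trailing 10% of the incubation window, accepted as a steady state when
  the OLS slope over that tail is below 1e-5 AU/s; slower compounds are
  flagged rather than silently read early.  Incubation windows of 60 min,
  6 h and 24 h are explicit parameters, because reaction speeds in this
  chemistry span orders of magnitude.
* **2-deoxyribose.** The 532 nm TBARS signal receives a three-blank
  correction `A = A_meas - A_BL3 - (A_BL2 - A_BL1)`: BL2 − BL1 isolates
  heat-induced probe degradation and BL3 the compound's own degradation
  products.  Negative corrected values are kept (with a warning), since
  they are the signature of pro-oxidant behaviour.
* **Beta-carotene bleaching.** `%AOA = [1 - (As0-As10)/(Ac0-Ac10)] * 100`
  from the 0- and 10-minute readings; controls are matched by replicate
  where possible.  The kinetic statistic is `k' = slope(1/dA vs c) * A0`,
  with `dA` the per-series absorbance drop — the full competition constant
  is not computable because the beta-carotene/peroxyl rate constant has no
  literature value, but k' preserves the compound ordering since the
  missing factors are shared plate-wide.
* **CAA.** Trapezoidal areas under the DCF fluorescence curves; the score
  is `CAA = 100 - (SA/CA) * 100`.  No baseline subtraction: the score is a
  ratio, so a common multiplicative gain cancels, and additive baselines
  are the caller's responsibility.  Scores are reported per concentration;
  two-point designs get no half-maximal estimate.

## Dose-response model

EC50/IC50 values come from the five-parameter asymmetric logistic on
log10 dose,

    y(x) = D + (A - D) / (1 + 10^(B (log10 C - log10 x)))^E,

fitted by bounded trust-region least squares with an analytic Jacobian.
The reported EC50 is the **absolute criterion crossing** (the dose at
which the fitted curve equals 50%, or another criterion), obtained by
inverting the fitted curve in closed form — not the inflection parameter
C, matching the operational definition of EC50 in these assays.
Initialisation takes D and A from the lowest/highest-dose mean responses,
C from the dose nearest the half-range, B = E = 1; three jittered restarts
run when the first solve stalls with a poor fit.  With four dose levels
and five parameters the model is deliberately over-parameterised: the fit
interpolates the dose means and the optimiser stalls on flat directions
without meeting strict tolerances.  Such stalls are accepted as converged
when the projected gradient has collapsed by four orders of magnitude
relative to the starting point — every identified quantity (fitted values,
criterion crossing) is stable there even though individual parameters are
not.  Responses are never clipped: negative responses propagate and a
curve that cannot reach the criterion reports `crossing_found = False`
(qualifier `no_effect`, or `pro_oxidant` when every dose mean is
negative).

### Confidence intervals

Intervals are bootstrap-based with the seed mandatory whenever resampling
runs.  The default scheme resamples **pooled residuals**: residuals around
the fitted curve are centred, inflated by sqrt(N/dof) (dof = N minus the
number of independently fitted quantities, which is the number of dose
levels when the model over-parameterises them) to undo the mean-centering
bias, resampled onto the fitted values, and the curve refit.  The interval
is the symmetric t-interval `ec50 - bias_boot +/- t(dof, 0.975) * sd_boot`,
where `bias_boot` is the bootstrap's own bias estimate (mean of resampled
crossings minus the point estimate); the classic stratified
case-resampling percentile interval remains available as
``boot_scheme='case'``.  The reason for this default is structural: with
r replicates per dose, case resampling estimates each within-dose
variance with divisor r rather than r - 1 (a one-third deficit at
triplicates) and from only r observations, and its extreme percentiles
are unstable at feasible resample counts, so its 95% intervals run
systematically short at exactly the replication level plate assays use.
The packaged coverage study (in the test suite and the acceptance
script) measures the default scheme's coverage over 200 replicated
plates.

## DPPH kinetics

Pseudo-first-order decays are fitted in two regimes:

* excess DPPH:  `[DPPH](t) = [DPPH]0 - s*[AH]0*(1 - e^(-kobs t))` with the
  stoichiometric factor `s` (radicals consumed per antioxidant) defaulting
  to 1.  Only kobs is free; the initial concentrations are design values.
* excess antioxidant:  `[DPPH](t) = [DPPH]0 e^(-kobs t)`, fitted both
  nonlinearly and as the log-linear regression (the two agree to numerical
  precision on clean data and are cross-checked in the tests).

`second_order_constant` is the plain OLS slope of kobs against
concentration, intercept free.  For the **excess-antioxidant** regime that
slope against [AH]0 *is* k2.  For the **excess-DPPH** regime, however,
kobs tracks the DPPH concentration, which barely varies with the
antioxidant dose — there the pipeline regresses kobs on [AH]0 and takes
`k2 = intercept / [DPPH]0`: the extrapolation to zero antioxidant, where
pseudo-first-order behaviour is exact and the effective DPPH concentration
equals [DPPH]0.  Against the full second-order ODE this estimator is
accurate to <0.2% on clean data and a few percent at 0.002 AU noise,
whereas reading the slope in that regime estimates essentially zero.
The 60-minute and 24-hour constants are the same estimator over different
fit windows; on biphasic decays the shorter window necessarily yields the
larger constant.

## Competition kinetics (2-deoxyribose)

Under pure competition for the hydroxyl radical, 1/A is affine in the
scavenger concentration and

    k_S = slope * k_DR * [DR] * A0    (concentrations in mol/L).

`k_DR` — the rate constant of 2-deoxyribose itself with OH• — is a
**required input with no default**: the analyses this package mirrors use
it implicitly but never print the value, and inventing one would fabricate
a constant.  All outputs scale linearly in it (a pass-through contract
covered by tests).  Linearity is judged by a lack-of-fit F-test of the
linear against the quadratic model on replicate-averaged points at
alpha = 0.05; a rejection marks the compound *dual-mode* (consistent with
direct hydrogen-peroxide scavenging diminishing radical generation) and
leaves k_S undefined rather than reporting a biased slope.

## Synthetic data

The generators encode the study conditions: 70 uM initial DPPH (140 uM
stock diluted 1:1), triplicates, four dose levels (five for the
deoxyribose design, which needs the extra level for a meaningful
curvature test), 2.5 mM deoxyribose, a beta-carotene working solution at
absorbance 0.68 monitored for 10 min, and additive Gaussian noise of
0.002 AU on absorbance or 0.5% of the fluorescence plateau — noise levels
chosen once to produce confidence-interval widths comparable to the
reference tables.  Specific choices worth recording:

* **DPPH** traces integrate the second-order ODE (LSODA, rtol 1e-8) and
  map to absorbance through the calibration line.  The steady-state EC50
  of this generator is stoichiometric — with the antioxidant fully
  consumed, %remaining = 100 (1 - s c/[DPPH]0) — so a target EC50 fixes
  `s = [DPPH]0/(2 EC50)`.  Because the assay reads absorbance ratios and
  the calibration line has an additive offset, the measured crossing sits
  at `(1-f)([DPPH]0 - offset)/s`, slightly below the concentration-space
  value; `true_dpph_ec50` returns this exact operational truth.  The
  endpoint design reads coarsely through the decay and densely across the
  final plateau, so the steady-state endpoint averages several readings.
* **Deoxyribose** endpoints follow A(c) = A0/(1 + k_S c/(k_DR [DR])) with
  the blank components added back on top, so the analysis chain must undo
  them.  Dual-mode compounds get a quadratic term 3 (k_S c / (k_DR [DR]))^2
  in 1/A — curvature of the magnitude that makes such plots visibly bent.
  A negative k_S emulates a pro-oxidant (corrected absorbance above the
  control).
* **Beta-carotene bleaching** uses an amplitude-scaled bleach: the control
  decays exponentially with a 10-minute drop of 0.45 AU from 0.68, and a
  sample at dose c follows the same normalised trajectory scaled to the
  endpoint drop dA(c) = dA0/(1 + q c).  This makes 1/dA *exactly* affine
  in c — the model the k' analysis assumes — giving the generator a
  well-defined true k' = q A0/dA0 (a rate-scaled variant would be affine
  only to first order and smear the definition of truth).  Doses sit at
  (1/4, 1/2, 1, 2) x IC50 so the design tracks potency.
* **CAA** fluorescence follows F(t) = Fmax (1 - e^(-rho t)) with the
  sample rate scaled by a protection factor (below 1 protective, above 1
  pro-oxidant); the control rate 1.5e-4 /s over a 1 h window keeps the
  control curve far enough from saturation that strongly negative scores
  (to about -340) are representable.  `protection_factor_for_caa` inverts
  the closed-form area ratio for a target score.
* **Screens** draw binomial confusion counts at given sensitivity and
  specificity.

Every simulator is a deterministic function of its spec (seed mandatory);
same spec, byte-identical table.

What passing recovery tests shows: the estimators invert their own
generative models at realistic noise, designs and replication, with
near-nominal interval coverage.  What it does not show: robustness to
effects the generators omit — drifting baselines, pipetting error
correlated across a plate, compound absorbance overlapping the readout
wavelength, emulsion heterogeneity in the bleaching assay, or cellular
heterogeneity and cytotoxic losses in the CAA assay.

## Simulation study sizes

The packaged studies use 200 replicated plates for interval-coverage
checks (binomial SE about 2% at 90% coverage), 500 null simulations for
the type-I calibration of the linearity diagnostic, 200 seeds for its
power, 10–12 plates for averaged recovery errors, and 300 bootstrap
resamples per fit; these sizes put Monte-Carlo error comfortably below
the margins being tested while keeping the full suite runnable on a
laptop in minutes.

## Degenerate inputs and tie-breaks

* Flat series fit kobs = 0; constant competition or bleaching points give
  zero slopes (and k_S = k' = 0) rather than errors.
* A response curve entirely on one side of the criterion reports
  `crossing_found = False`; qualifiers distinguish `no_effect`,
  `pro_oxidant`, `insoluble` and `not_tested` in the results table.
* Zero control bleaching or a non-positive control area raises a
  degenerate-control error — the ratio definitions have no value there.
* Bootstrap resamples that fail to refit or to cross the criterion are
  dropped and counted (`n_boot_failed`); the interval is clamped to
  bracket the point estimate.
* The reported hit rate keeps full precision internally and rounds only
  in its display form.

## Known limitations

* The DPPH chemistry is treated as irreversible; partial reversibility
  would bias steady-state EC50 values upward, and no correction is
  attempted.
* The stoichiometric factor s is configurable but unknown for real
  compounds; k2 estimates in the excess-DPPH regime scale with it.
* k' is comparable only within a plate (shared A0 and radical flux); it
  is not an absolute rate constant.
* The lack-of-fit diagnostic has modest power at four dose levels; the
  five-level default design is the minimum at which curvature detection
  is reliable.
* The CAA model treats the cell population as homogeneous with a single
  effective DCF formation rate.
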