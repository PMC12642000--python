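# Methods

## Model structure and assumptions

The disposition model is a second-generation minimal PBPK for antibodies:
plasma, a lumped tight-tissue interstitium (muscle, skin, adipose, brain),
a lumped leaky-tissue interstitium (liver, kidney, heart and other highly
vascularised organs) and lymph. Transport is convective only: antibody
leaves plasma with the lymph filtrate at flow `L1 = (1 − f)·L` (tight) and
`L2 = f·L` (leaky), each reduced by the corresponding vascular reflection
coefficient (1 − σ1) or (1 − σ2); it returns through lymph reduced by the
lymphatic reflection coefficient (1 − σL). Elimination is linear from
plasma only. FcRn-mediated recycling and placental transfer are not
modelled mechanistically; their net effect is absorbed in the clearance
term. Intramuscular administration adds a first-order depot
(`ka`, bioavailability `F`). The system is linear and time-invariant
between dose events, which the implementation exploits twice: dose
superposition holds exactly, and an independent matrix-exponential closed
form of the same system serves as the oracle in the test suite (the
production simulator integrates the ODEs numerically with LSODA,
segmented at every dose start/end so infusion corners are exact).

Endogenous IgG is not represented by a synthesis term. Because the system
is linear, an endogenous steady state can be added to the exogenous
solution by superposition: plasma at the baseline concentration `C_base`,
tight at `C_base(1−σ1)/(1−σL)`, leaky at `C_base(1−σ2)/(1−σL)`, lymph at
`C_base[L1(1−σ1)+L2(1−σ2)]/L`. This is mathematically identical to an
explicit synthesis rate `CL·C_base` and directly testable (the no-dose
simulation holds every compartment constant to < 1e−6 over 100 days).

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| plasma volume | 2.6 | L | reference 70-kg adult |
| tight / leaky tissue volume | 8.11 / 4.37 | L | reference 70-kg adult |
| lymph volume | 5.2 | L | reference 70-kg adult |
| total lymph flow `L` | 2.9 | L/day | reference 70-kg adult |
| leaky flow fraction `f` | 2/3 | — | convention of the two-tissue antibody mPBPK framework; never reported for this system, exposed in config |
| σ1 / σ2 | 0.97 / 0.94 | — | IgG estimates on training IVIG data |
| σL | 0.2 | — | reference value |
| clearance | 0.045 | L/day at 70 kg | IgG estimate; scaled (BW/70)^0.75 |
| infusion duration | 4 | h | typical IVIG infusion; Cmax is insensitive to short durations because distribution over hours is negligible |
| anti-D `ka` | 0.25 | 1/day | placeholder (no published value shipped); configurable |
| anti-D `F` | 1.0 | — | placeholder; configurable |
| pregnancy BW gain | 23 % | — | third-trimester gain |
| trimester plasma volume | 2.78 / 3.30 / 3.67 | L at 70 kg | +7 % / +27 % / +41 % expansion |

All bodyweight terms — including the trimester plasma volumes — use the
subject's *current* bodyweight divided by 70. Applying the current-BW rule
uniformly (rather than pre-pregnancy BW for plasma volume only) is a
deliberate design choice: it keeps every volume on the same scaling rule,
and it is the variant consistent with the published cohort summary this
package reproduces (a pregnant subject's peak back-calculates to
`V_p ≈ 3.67·(BW_pregnant/70)`). Canonical internal units are g, L, day;
anti-D quantities (µg, ng/mL) are converted at the I/O boundary.

## Calibrated quantities

Endogenous IgG baselines per trimester and the trough sampling time are
not printed alongside the summary exposure table, so
`scripts/calibrate_baselines.py` fixes them once:

* nonpregnant baseline `b0 = 13.0 g/L` — the published nonpregnant trough
  level, read as baseline-dominated (and within the normal adult range);
* `trough_time = 28 days` — the standard 4-week IVIG dosing interval.
  Note the model cannot make the *absolute* 28-day trough equal the
  baseline-only published value while simultaneously showing a −8 % trough
  delta: with CL = 0.045 L/day the exogenous half-life is ≈ 7 weeks, so a
  baseline-only trough would need ≈ 280 days of washout, where the
  between-arm delta nearly vanishes. The percent deltas, not the absolute
  troughs, are the quantities this package targets;
* third-trimester baseline `b3 = 12.93 g/L` — solved (Brent root find) so
  the cohort's per-kg Cmax percent change equals −15 %; trimester 1–2
  baselines are linear interpolations (they do not enter the
  third-trimester experiment). The resulting near-equality of `b0` and
  `b3` is a calibration artefact: real third-trimester hemodilution lowers
  maternal IgG more than this. The remaining three exposure deltas
  (trough, and both equal-dose variants) are *predictions* of the
  calibrated model, not targets.

## Estimation

Naïve-pooled nonlinear least squares (no random effects): the paper-style
mean literature profiles carry no usable inter-individual information, and
the published parameter table reports single point estimates. The default
error model is log-additive (residual `log obs − log pred`), matching the
multiplicative fold-error statistics used for validation; proportional and
additive models are available. Optimisation is bounded trust-region
(`scipy.optimize.least_squares`), multi-started from 5 jittered initial
points (±20 %, seeded, first start unjittered), best objective wins.
95 % CIs and %CV come from the Gauss–Newton covariance
`s²(JᵀJ)⁻¹` with `s² = SSR/(n−p)` and t-quantiles. Anti-D parameters are
fitted on IV data with third-trimester physiology; `ka` is fixed from
config, never estimated.

Identifiability, measured by 1-D objective sweeps (`profile_sensitivity`):
both reflection coefficients are locally *stiff* directions — at σ ≈ 0.95
a small relative change in σ is a large relative change in permeability
(1 − σ) — while clearance is ~100× flatter per unit relative change over a
28-day window (exogenous half-life ≈ 7 weeks). The σ's are weakly
identified *jointly* (one compensates the other), which is why the
repeat-fit study below uses a longer design.

## Synthetic data

`generate_study` simulates the true model at the configured parameters and
applies multiplicative lognormal noise with unit mean and prescribed CV.
The default IVIG design mimics the training study (450 mg/kg, 70-kg
subject, 12 samples over 28 days, baseline included); the anti-D design is
300 µg IV or IM in a third-trimester subject on the ng/mL scale. What the
generator does **not** emulate: inter-individual parameter variability,
assay-specific error structure, sparse/irregular sampling, digitisation
error of figure-extracted data, or endogenous IgG turnover dynamics.
Passing round-trip tests therefore show self-consistency of the
implementation under its own error model — not predictive validity against
real clinical data, which would require the original digitized datasets.

## Numerical choices and problem sizes

* LSODA with rtol 1e−10 (simulation) / 1e−8 (inner fitting and cohort
  loops); atol scaled to 1e−12 × total dose. Oracle agreement is ~1e−11.
* Reported concentration series are clipped at zero (solver round-off can
  produce ~1e−15 negatives); raw amounts are retained on the profile for
  mass-balance diagnostics.
* AUC∞ integrates an AUC-augmented state to a finite horizon and closes
  the tail exactly by mass balance (`remaining bioavailable mass / CL`).
* Cmax search: for this linear model the peak is at end-of-infusion; the
  cohort simulation still samples the infusion window on a fine grid.
* Cohort experiment: n = 100 subjects × 2 arms (≈ 0.6 s). The repeat-fit
  calibration study runs 40 replicates at 10 % noise with 2 optimiser
  starts on a 16-point, 63-day design — the 28-day training window leaves
  clearance too weakly identified for a stable bias estimate, which is a
  genuine feature of IgG's slow elimination, not of the optimiser.
* Lognormal bodyweights are moment-matched (arithmetic mean 74, SD 18 kg,
  back-calculated from the published total-dose summary 37 ± 9 g at
  0.5 g/kg); with per-kg dosing the exogenous Cmax is exactly
  bodyweight-independent, so cohort percent deltas are stable to ±0.1 pp
  across seeds.

## Known limitations

* Linear clearance only: no FcRn saturation, no target-mediated
  disposition, no gestational-week-continuous physiology (trimester
  steps only), no explicit fetal/placental compartment (lumped into leaky
  tissue).
* Cohort variability comes from bodyweight alone; observed-cohort SDs of
  peak/trough concentrations will be underestimated.
* Anti-D absorption and disposition parameters ship as labelled
  placeholders pending real estimates; conclusions about anti-D exposure
  magnitudes should not be drawn from the defaults.
* Single-dose exposure only; steady-state multiple-dose regimens are out
  of scope.
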