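# igpbpk

Minimal physiologically based pharmacokinetic (mPBPK) modelling of
immunoglobulin exposure — intravenous immunoglobulin (IVIG) and anti-D
immunoglobulin — in nonpregnant and pregnant women.

Pregnant women are routinely excluded from PK studies, so IVIG is dosed in
pregnancy by extrapolation from standard adult regimens. This package
implements the modelling chain used to ask whether that is adequate: a
reduced antibody PBPK model, pregnancy-specific physiological scaling, and
a virtual-population simulation that quantifies how much lower third-
trimester exposure is under bodyweight-based (0.5 g/kg) versus flat
dosing. It is aimed at clinical pharmacologists and modellers working on
therapeutic-protein dosing in special populations.

## Model

Four compartments — plasma, lumped *tight* tissue (muscle, skin, adipose,
brain), lumped *leaky* tissue (liver, kidney, heart, …) and lymph — with
amounts `A_i`, volumes `V_i` and plasma concentration `C_p = A_p / V_p`:

```
dA_p/dt  = In(t) + ka·F·A_depot + L·C_lymph
           − L1(1−σ1)·C_p − L2(1−σ2)·C_p − CL·C_p
dA_1/dt  = L1(1−σ1)·C_p − L1(1−σL)·C_1          (tight)
dA_2/dt  = L2(1−σ2)·C_p − L2(1−σL)·C_2          (leaky)
dA_ly/dt = L1(1−σL)·C_1 + L2(1−σL)·C_2 − L·C_ly (lymph)
dA_d/dt  = −ka·A_d                              (IM depot)
```

Antibody enters the interstitium by convective lymph filtration (total
lymph flow `L = L1 + L2`, vascular reflection coefficients `σ1 = 0.97`,
`σ2 = 0.94`), returns through lymph (lymphatic reflection `σL = 0.2`) and
is cleared from plasma only (`CL = 0.045` L/day at 70 kg). Endogenous IgG
is handled by linear superposition of its steady state. Pregnancy scaling:
volumes and lymph flow ∝ BW/70, clearance ∝ (BW/70)^0.75, plasma volume
expanded by 7 % / 27 % / 41 % in trimesters 1–3, reflection coefficients
unchanged.

Model validation uses the average fold error
`AFE = 10^(mean log10(pred/obs))`, signed percent prediction error, and
the share of predictions within 0.5–2-fold of observations.

## Worked example

Two-arm virtual cohort (100 nonpregnant women, lognormal bodyweights
74 ± 18 kg; pregnant twins at +23 % bodyweight, third-trimester
physiology), single 0.5 g/kg IV infusion, trough at 28 days:

```bash
$ igpbpk popsim --out popsim.csv
Dose (g/kg): 0.5   dosing mode: per_kg
                          Nonpregnant Pregnant (third trimester) % Mean Change
Total Dose (g)              37.4 ± 10                    46 ± 12          23.0
Cmax (g/L)              26.4 ± 0.0013              22.4 ± 0.0006         -15.0
Cmax_adjusted (g/L)        26.4 ± 7.1                 18.3 ± 4.9         -30.9
Ctrough (g/L)             19.8 ± 0.17                18.8 ± 0.11          -5.3
Ctrough_adjusted (g/L)     19.8 ± 5.1                   15.3 ± 4         -22.9
```

Reading: with bodyweight-based dosing the pregnant arm receives 23 % more
drug, which largely offsets plasma-volume expansion and hemodilution —
peak concentration is only 15 % lower and the 28-day trough 5 % lower.
The `_adjusted` rows normalise every subject to the 70-kg total dose
(equal-total-dose, i.e. flat dosing): there the pregnant arm loses ~31 %
of Cmax and ~23 % of the trough. Bodyweight-based dosing therefore
compensates for most of the pregnancy-related exposure drop.

Round-trip parameter estimation on a synthetic noise-free 450 mg/kg
profile recovers the generating drug parameters:

```bash
$ igpbpk synth --noise-cv 0 --out train.csv
$ igpbpk fit --data train.csv --out fit.json
sigma_tight  = 0.97  (95% CI 0.97 - 0.97, %CV 0.00)
sigma_leaky  = 0.94  (95% CI 0.94 - 0.94, %CV 0.00)
clearance    = 0.045  (95% CI 0.045 - 0.045, %CV 0.00)
```

The same machinery is available as a library; the estimator is a
scikit-learn regressor:

```python
import igpbpk as ig

cfg = ig.default_config()
est = ig.MPBPKRegressor(physio=..., doses=[...], drug=...)
est.fit(times_days, concentrations)   # -> est.params_, est.ci95_
```

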