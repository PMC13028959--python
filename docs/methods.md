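# Methods

This note documents the model structure, the provenance of every
parameter, the numerical choices, what the synthetic-data generator does
and does not emulate, and the design decisions taken where more than one
reasonable construction existed.

## Disposition model

State variables are molar amounts (µmol) of dapagliflozin (DAP) in gut
lumen, fecal transit, cumulative feces, enterocytes, blood, gut tissue,
liver, kidney, lung, rest-of-body and cumulative urine, plus the
metabolite (D3G) in blood, kidney and cumulative urine — 14 states.
Internal bookkeeping is molar so that mass balance is exact in
DAP-equivalents; interfaces use mg (doses), ng/mL (plasma, via the molar
masses 408.87 g/mol for DAP and 585.03 g/mol for D3G), mM (glucose) and
g (cumulative glucose excretion).

**Absorption and the fecal route.** An oral dose is split at the dosing
instant: `F_gut = 0.84` into the absorbable lumen pool, `1 − F_gut` into
a fecal transit pool. The split is instantaneous rather than a pair of
competing first-order rates so that the bioavailable fraction — and with
it total exposure — is independent of absorption activity; this is the
behavior seen clinically, where food changes Cmax but not AUC. The
transit pool empties into cumulative feces at 0.05 h⁻¹, a cosmetic rate
that makes fecal time courses finite without altering the total. Lumen
drug is absorbed at `ka · f_absorption` into a small enterocyte pool
that hands drug to the portal inflow of the liver at a fast fixed rate
(6 h⁻¹, ~10 min transit; not rate-limiting). Routing the absorbed flux
through the portal inflow rather than through the partitioned gut-tissue
pool matters: gut tissue at Kp ≈ 26 with a ~21 L/h portal flow is a
~1.6 h low-pass filter, and forcing absorption through it would flatten
every oral peak regardless of `ka`, making the observed fed-state Cmax
drop (30–50%) unreachable. Gut tissue remains in the model as a
systemic distribution compartment.

**Distribution.** Flow-limited with instantaneous partitioning: each
organ exchanges `Q_i(C_blood − C_i/Kp_i)` with a lumped venous+arterial
blood pool. Transport of DAP and D3G in liver and kidney is treated as
fast and reversible relative to metabolism, so no transporter states are
carried. The partition coefficient is a single value `Kp = 25.52` for
the explicitly modeled organs (gut, liver, kidney, lung). The residual
rest-of-body compartment carries its own coefficient `Kp_rest`
(reference value 4.05, fitted): applying 25.52 to the ~65 L carcass
would imply a distribution volume above 1700 L, and the washout of such
a pool at the available perfusion bounds the terminal half-life above
~17 h — incompatible with the drug's 13 h half-life and ~100 L apparent
volume. The lung exchanges at full cardiac output in parallel with the
systemic organs; with a single well-mixed blood pool this only sets the
(fast) lung equilibration time.

**Metabolism and excretion.** DAP → D3G is irreversible
Michaelis–Menten with `Km = 479 µM` (kidney-microsome value, fixed) and
capacities `Vmax_li·(1−f_cirrhosis)·V_li` in liver and
`Vmax_li·f_ki_Vmax·V_ki` in kidney, driven by total tissue
concentration. Hepatic impairment also shunts the fraction
`f_cirrhosis` of hepatic inflow (arterial + portal + newly absorbed
drug) past the liver, representing portosystemic shunting. Urinary
excretion of DAP and D3G is first-order in the respective kidney amount,
scaled by `f_renal`. D3G formed in the liver is released to blood, does
not partition into tissues (Kp = 1), distributes between blood and
kidney only, and leaves renally. At clinical doses liver/kidney
concentrations sit far below Km, giving dose-linear kinetics; the
saturation bend becomes visible near the 500 mg top dose.

## Pharmacodynamics

Total plasma DAP drives a saturable reduction of the renal glucose
threshold, `RTG(C) = RTG0·(1 − Imax·C/(IC50 + C))`, and the excretion
rate is the filtered excess `GFR·max(0, FPG − RTG)`. A hard threshold
(no splay/TmG curve) is used because tubular reabsorption is not
modeled explicitly; an Emax-type drive was chosen over a linear one
because the dose–response of glucosuria saturates. `Imax` is capped at
0.9 on mechanistic grounds: SGLT2 carries ~90% of tubular glucose
reabsorption, so complete SGLT2 inhibition cannot abolish the
threshold. FPG is constant per scenario (no diurnal variation). The PD
layer is evaluated by trapezoidal quadrature of the UGE rate along the
solved plasma profile on the output grid; it is deliberately kept out
of the ODE state so that glucose settings cannot perturb solver step
selection — drug profiles are bitwise identical across FPG values.

## Parameters

Fixed from literature/structure: fractional volumes (gut 1.71%, kidney
0.44%, liver 2.10%, lung 0.76% of body weight; 1 kg ≈ 1 L), fractional
flows (gut 18%, kidney 19%, hepatic venous outflow 21.5%, lung 100% of
cardiac output), `Kp = 25.52`, `Km = 479 µM`, `F_gut = 0.84`, the
impairment factor maps, and molar masses.

Closure constants chosen here (single named constants, replaceable):
blood pool fraction `FVbl = 7.86%`; rest volume and flow close the
body exactly (`FVre = 1 − ΣFV ≈ 87%`, `FQre = 1 − FQh − FQki = 59.5%`);
hepatic arterial inflow `FQh − FQgu = 3.5%`; cardiac output 108 L/h at
70 kg, scaled linearly with body weight; `GFR_ref = 6.5 L/h`
(~108 mL/min) at `f_renal = 1`, not body-weight scaled.

Calibrated (shipped as `data/reference_parameters.json`, generated by
`scripts/fit_reference.py` with seeded multistart bounded least squares
on log-parameters): `ka = 0.69 h⁻¹`, `Vmax_li = 23.2 µmol/h/L`,
`f_ki_Vmax = 1000`, `k_DAPEX_ki = 1.04 h⁻¹`, `k_D3GEX_ki = 26.8 h⁻¹`,
`Kp_rest = 4.05`; PD `RTG0 = 10 mM`, `Imax = 0.90`, `IC50 = 4.8 ng/mL`.
Calibration targets were the headline facts (t½ 13 h, Tmax ~2.5 h,
F 78%, urinary unchanged 1.5%, fed Cmax reduction 38%, metabolite peak
delayed ~1 h) plus 24 h UGE magnitudes of ~70 g (diabetic) / ~35 g
(healthy) at 10 mg. Two compromises are worth knowing about. First, the
hard-threshold PD structure ties the diabetic-minus-healthy UGE
difference to the 2.5 mM glycemia gap times the threshold-suppression
time; with a 13 h half-life the suppression is long and shallow, so the
joint fit settles at ~95 g / ~27 g — bracketing, not matching, typical
clinical magnitudes. Second, the fitted kidney conversion operates near
flow limitation (extraction ~0.9), which is why `f_ki_Vmax` is large
and only weakly determined; its headline behavior is insensitive to
this (see identifiability below). The metabolite's plasma
concentrations run higher than a model with full D3G tissue
distribution would give, a direct consequence of confining D3G to
blood + kidney; no calibrated behavior depends on its absolute level.

## Numerics

LSODA via `scipy.integrate.solve_ivp`, rtol 1e-8 / atol 1e-10 for
reporting runs, restarted at every dose event so boluses are exact;
grid points coinciding with an event report the post-dose state. The
default output grid is 0.1 h. Mass balance holds to ~1e-13 relative;
state negativity beyond 1e-6 of the dose aborts with an error, smaller
solver noise is clipped. Inside calibration loops the tolerances are
relaxed to rtol 1e-6 / atol 1e-9 and scenarios are evaluated only on
their data grids; the optimizer's finite-difference step is fixed at
1e-3 in log10-parameter space, safely above the integration noise
floor (with scipy's default `sqrt(eps)` step the Jacobian degenerates
into noise and fits stall). NCA uses the linear-up/log-down trapezoid,
`C_last/λz` extrapolation, and picks the terminal window by best
adjusted R² over the last 3–10 points after Tmax. IV profiles need
dense early sampling (the bolus equilibrates out of the ~6 L blood pool
on a sub-0.1 h timescale); the bioavailability computation samples
0.01 h steps over the first hour for this reason. Sensitivities are
symmetric ±1% midpoint differences normalized to elasticities;
parameters with reference value zero report zero, readouts with zero
reference are flagged NaN rather than silently zeroed. Row filtering
drops |S| < 0.1 throughout; ordering is single-linkage on Euclidean row
distance (the linkage is specified, the metric is our choice).

## Synthetic studies and what they show

The generator emulates the *reporting structure* of curated clinical
studies — arms with a dosing protocol, a sampling grid, group size n,
and per-point mean ± SD — by simulating the model at known parameters
and drawing n mean-preserving lognormal deviates per point (default CV
20% plasma, 30% urine/UGE; seeded, one child stream per time course).
It does not emulate inter-individual physiological variability,
model-structure mismatch, assay limits of quantification, or dropout;
recovery tests therefore show that the estimator finds the truth when
the model is correct, not that the model is correct for real patients.
Canonical fixtures mirror the study classes of the literature:
dose-ranging (2.5–500 mg), renal four-arm (f_renal 1.00/0.69/0.32/0.19),
hepatic four-arm (f_cirrhosis 0/0.40/0.70/0.80), fed/fasted crossover,
and 7-day once-daily multidose.

Recovery oracles run at a documented synthetic truth
(`RECOVERY_TRUTH_DRUG/_PD`, kidney extraction ~0.55) in the identifiable
interior of the parameter space rather than at the reference values,
which sit in the flow-limited regime where the kidney-conversion scaling
is a sloppy direction (elasticity ~0.05; 10% data noise would amplify
into ~60% parameter spread there). At the synthetic truth, noiseless
dose-ranging data recover all five PK constants to ≪1% (best of 20
starts) and 10%-noise data stay within ~10%. Problem sizes used in the
shipped tests: 7 arms × 12 time points × 4 observables, 20 multistarts
noiseless / 10 with noise, fitting tolerances as above.

## Known limitations

- Typical-individual model: no inter-individual variability, age/sex
  physiology, or pediatrics; linear body-weight scaling only.
- No enterohepatic recirculation, no intestinal glucuronidation, no
  minor metabolites, no protein-binding submodel (PD is driven by total
  plasma concentration).
- PD omits SGLT1, insulin, plasma-glucose dynamics and natriuresis; the
  hard threshold has no splay.
- The fecal route's transit rate and the enterocyte hand-off rate are
  fixed conventions, not estimated.
- SBML export is not provided; the model lives as Python callables.
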