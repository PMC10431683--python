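# Methods

This note documents the model, its numerical treatment, the population
layer, the design choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Model structure and assumptions

The body is divided into venous and arterial plasma pools, liver,
kidney, muscle, a lumped rest-of-body compartment, and a lung with
three sub-compartments (lung blood, interstitial fluid, lung tissue).
States are drug amounts in mg; volumes in L; time in h; concentrations
in mg/L, identified with µg/mL for fluids and µg/g for tissues at
density 1 g/mL.

Assumptions:

- **Perfusion limitation** for liver, kidney, muscle and rest: tissue
  uptake is limited by blood flow, the tissue is well stirred, and
  venous outflow leaves at `C_T / P_T`.
- **Lung in series**: the lung blood sub-compartment receives the whole
  cardiac output from the venous pool and delivers it to the arterial
  pool. Lung blood does not exchange directly with lung tissue; the
  chain is blood ↔ IF ↔ tissue.
- **Free-drug transfer in the lung**: transfer fluxes are first order
  in the *unbound* source amounts: blood→IF `KBI·(1−PB)·A_LUB`,
  IF→blood `KIB·A_LUI`, IF→tissue `KIT·A_LUI`, tissue→IF
  `KTI·(1−PT)·A_LUT/PLU`. The IF is all free by definition (it is what
  a microdialysis probe samples). The placement of the lung partition
  coefficient `PLU` is a genuine ambiguity; see Design choices.
- **Two-step intramuscular depot**: a fraction `Frac = 0.1` of each
  dose enters a slow pool released at `Kdiss = 0.05/h` into the fast
  pool; the rest enters the fast pool directly and is absorbed into
  venous blood at `Kim = 7/h`. The alternative assignment (90% slow)
  would give an absorption half-time of ~14 h, inconsistent with the
  observed early plasma peak, so the fast-dominant split is used.
- **Organ-attached clearances**: renal elimination
  `KurineC·BW·C_K/PK` from the kidney and biliary `KbileC·BW·C_L/PL`
  from the liver, i.e. clearance acts on the venous-equilibrated organ
  concentration. Clearances scale linearly with body weight (their
  units are L/h/kg).
- **Reporting**: "plasma" is the venous pool; free plasma is
  `(1−PB)·C`. Muscle is simulated (it matters for mass balance) but is
  not a reporting endpoint. No oral/IV routes, no enterohepatic
  recirculation, no metabolites, no inter-species scaling.

The default parameter set describes a 25 kg nursery pig (cardiac
output 4.944 L/h/kg; flow fractions: muscle 0.2524, liver 0.3053,
kidney 0.1398, rest 0.3055 as the balancing remainder) and cefquinome
chemistry (partitions: lung 1.5, muscle 0.1, rest 0.1, liver 6,
kidney 15.2; plasma protein binding 0.188; lung-tissue binding 0.3;
clearances 0.01/0.3 L/h/kg; lung transfer 0.110/0.052/3.56/2.60 per h).
All defaults are embedded; a TOML file with `[physiology]` /
`[chemical]` tables can override any subset. Flow-fraction and
lung-sub-volume sums are checked (±1%) when parameters are loaded as a
study set, but deliberately not on every construction, because
one-at-a-time sensitivity perturbations and population sampling of
QKC intentionally unbalance them.

## Numerics

Between dose events the entire system — depots, tissues, cumulative
urine/bile, and nine AUC-accumulator states (time-integrals of each
reportable concentration) — is linear and time-invariant,
`dx/dt = A x`. The default integrator therefore propagates
`x(t+h) = e^{Ah} x(t)` with a cached matrix exponential per grid step
(default 0.05 h), restarting at each dose event with an instantaneous
addition to the depot pools. This is exact to machine precision at
grid nodes and makes a 1000-animal simulation day cost seconds. A
stiff LSODA route (analytic Jacobian, rtol 1e-8, atol 1e-10 mg) is
retained behind `method="lsoda"`; the test suite checks both engines
against a directly evaluated `e^{At} x₀` oracle (≤1e-5 relative) and
against each other, along with mass balance (≤1e-6 relative at every
output time), superposition of repeated doses (≤1e-6) and equilibrium
tissue:blood ratios reaching the partition coefficients when
clearances are off.

Reported AUCs come from the accumulator states (exact at grid nodes,
linear interpolation between); series built outside the simulator fall
back to trapezoidal quadrature. %T>MIC integrates the indicator
`[C_free > MIC]` with threshold crossings located by linear
interpolation between grid points, verified against a 0.001-h Riemann
sum. Degenerate inputs (zero dose, zero baseline AUC in a sensitivity
ratio, zero perturbation, windows outside the simulated span, empty
ensembles) raise explicit errors rather than returning NaNs.

## Sensitivity analysis

`NSC = (Δr/r)/(Δp/p)` with a forward 10% increase per parameter
(central differences optional) on 24-h AUCs; `|NSC| > 0.25` flags a
parameter influential. The equation-as-printed reading "p/Δp = 10%"
is taken as a typo for Δp/p = 0.10, the standard protocol. The roster
covers the 29 perturbable scalar inputs: the three "calculated"
remainders (rest-flow QRC, rest-volume VRC, lung-tissue sub-volume
VLUT) are derived, and QLUC is structurally 1. When a fraction with a
calculated sibling is perturbed, the remainder re-balances (QRC for
flows, VRC for organ volumes, VLUT for lung sub-volumes); without
this, the ~0.3% flow-sum imbalance of the printed table leaks into
every flow NSC and scrambles the influential set. The screen at
defaults flags QCC, QKC and KurineC for plasma exposure, each
partition coefficient for its own tissue only, and KBI/KIT/KTI/PT
(plus the lung sub-volumes) for the interstitial fluid, with
NSC(PT → lung-IF AUC) ≈ −0.27.

## Population layer

The eleven influential parameters carry between-animal distributions:
normal for physiology (QCC, QKC; CV 0.30), lognormal for chemistry
(PL, PK, PM, PR, PLU at CV 0.20; KIT, KTI, KurineC, PT at CV 0.30).
Lognormals are parameterised by natural-scale mean and CV via
`σ² = ln(1+CV²)`, `µ = ln(mean) − σ²/2`, which reproduces the
reference 2.5th/97.5th truncation bounds to ±0.01 for every row — the
only available check on the parameterisation. Draws outside the
central 95% are rejected and redrawn (clipping would create
probability atoms at the bounds, which matters for the 99th-percentile
residue rule); a Kolmogorov–Smirnov test against the analytic
truncated CDF guards the sampler. Parameters are sampled
independently; flows are *not* renormalized after sampling QKC
(documented caveat), and body weight is fixed at 25 kg. Percentiles
are empirical linear-interpolation order statistics; with n = 1000 the
99th percentile is the interpolated ~990th order statistic, and the
estimator choice is stated because that tail quantile is
estimator-sensitive. All randomness flows from one seed through
deterministically spawned child streams, so every table is
reproducible byte-for-byte.

## Dosage evaluation

%T>MIC is computed per virtual animal over the *first 24-h dosing day*
(q24h: one dose at 0 h; q12h: doses at 0 and 12 h), always relative to
24 h so once- and twice-daily rows are comparable; whether the source
analysis used day 1 or steady state is not stated, and first-day is
the parsimonious reading. The plasma matrix uses the free *arterial*
concentration (the arterial pool is the reference in the
target-attainment formulation); MIC defaults are 1 µg/mL
(clinical breakpoint for *H. parasuis* / *S. suis*) and 0.25 µg/mL
(reference for *P. multocida* / APP).

The lung matrix needs care. The model has two lung read-outs: the
slow, accumulating IF sub-compartment (what microdialysis calibrates)
and the equilibrium lung biophase `PLU·(1−PB)·C_art`. The reported
population %T>MIC table behaves exactly like the latter — its lung
rows sit a constant ~3 percentage points above the plasma rows, the
signature of a trace 1.5× free plasma decaying at the plasma rate,
and the slow IF sub-compartment cannot exceed a 1 µg/mL MIC at the
label dose at all, whereas the reference table reports double-digit
percentages there. The dosage module therefore uses
`matrix="lung_pelf"` (the equilibrium biophase) as its default lung
matrix, with `"lung_if"` selectable. The IF sub-compartment remains
the lung endpoint for sensitivity analysis and microdialysis
calibration, where it is the quantity actually probed.

## Residues and withdrawal interval

Total liver and kidney concentrations (µg/g) are simulated for the
population; the WDI is the smallest whole day d (evaluated at
`last dose + 24·d` h) at which the empirical 99th percentile is at or
below the MRL in *both* tissues (liver 0.1, kidney 0.2 µg/g — the
EU/China limits; the liver is limiting at these parameters). The
label regimen is five daily 2 mg/kg doses; the extra-label regimens
default to five days of twice-daily dosing (10 doses q12h) with the
literal five-dose reading available through the regimen argument —
the distinction turns out to be immaterial because the slow depot
pool saturates after about five doses. At defaults the label WDI is
2 days and the 3 mg/kg twice-daily WDI is 3 days. The 5 mg/kg
twice-daily regimen lands on the boundary: the day-3 99th-percentile
liver residue computes to ≈0.108 µg/g, 8–11% above the 0.1 limit, so
the rule returns 4 days where a model whose liver tail ran a few
percent lower would return 3. Within the reconstruction uncertainty
of the transfer formulation this margin is not meaningful, and the
package reports what it computes rather than adjusting any parameter
to move it.

## Synthetic data

The generator emulates the structure of the observed studies — a
single-dose plasma profile, five-day liver/kidney residue sampling,
and the 14-point dialysate schedule (0.25–11.25 h) — by simulating
each animal (optionally with population-sampled parameters),
evaluating at the design's sampling times, applying multiplicative
lognormal assay noise (unit mean; default CV 0.20) and handling
values under the 0.05 µg/mL LLOQ by censoring or dropping. Dialysate
observations are `RR × C_IF`, round-tripping with the recovery
correction. It emulates assay error and between-animal variability
only: no assay drift, carryover, probe degradation, sparse/irregular
designs, or model misspecification. Passing recovery tests therefore
show the estimation machinery is correct and well-conditioned on
data generated by the model itself — they do not show the model is
structurally right for real pigs. The published validation statistics
against real digitized datasets are out of reach without those
datasets; the metrics themselves (R², MAPE bands, twofold rule) are
implemented and exercised on synthetic data.

Calibration minimizes log-scale residuals (residue data span orders
of magnitude) over all quantifiable observations with equal weight,
by bounded trust-region least squares; below-LLOQ records are
excluded. The identifiable-subset recovery checks use plasma + lung-IF
+ lung-biophase observations because, in the default formulation, KTI
and PLU enter the IF dynamics only through the ratio `KTI·(1−PT)/PLU`
— the biophase trace is what separates them.

## Known limitations

- The differential equations are a documented reconstruction of an
  unpublished implementation; topology-level ambiguities (PLU
  placement, lung-blood↔tissue path, venous vs arterial "plasma") are
  resolved by explicit, switchable choices validated against the
  published sensitivity pattern.
- The IF sub-compartment at the default transfer rates rises and
  decays much more slowly than observed dialysate profiles (the
  source analysis itself notes its lung peak is overestimated); its
  24-h AUC and sensitivity behaviour, not its shape, are the
  calibrated features.
- Fixed 25 kg body weight: conclusions do not transfer to market-age
  pigs.
- The residue rule uses empirical percentiles, not a
  tolerance-limit regression on the terminal slope as some regulatory
  algorithms do; that would be an extension.
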