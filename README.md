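# ceqpbpk — population PBPK of intramuscular cefquinome in swine

Cefquinome is a fourth-generation cephalosporin used against swine
respiratory tract infections (*Actinobacillus pleuropneumoniae*,
*Haemophilus parasuis*, *Pasteurella multocida*, *Streptococcus suis*).
Raising the label dose improves efficacy but risks violative residues in
edible tissues. `ceqpbpk` implements a population physiologically based
pharmacokinetic (pop-PBPK) pipeline for a ~25 kg nursery pig that
answers both questions at once: **which dosage regimen reaches the
PK/PD target in the infected lung**, and **how many days after the last
dose the liver and kidney residues fall below their maximum residue
limits (MRLs)**.

It is a library for pharmacokineticists and veterinary-drug risk
assessors, with a thin `ceqpbpk` CLI for the standard analyses and
narrative scripts under `examples/`.

## The model

Six compartments — venous/arterial plasma, liver, kidney, muscle, lung
and a lumped "rest of body" — connected by blood flows
`Q_T = Q_TC · QCC · BW`. All tissues except the lung are
perfusion-limited and well stirred:

    dA_T/dt = Q_T · (C_art − C_T / P_T)

with partition coefficients `P_T`. The lung carries the whole cardiac
output in series (venous → lung blood → arterial) and is
permeability-limited, split into lung blood, interstitial fluid (IF)
and lung tissue; only unbound drug crosses, at first-order rates
`KBI·(1−PB)`, `KIB`, `KIT` and `KTI·(1−PT)/PLU`. The IF sub-compartment
holds free drug — what a microdialysis probe samples.

An intramuscular dose splits into a fast depot pool (absorbed at
`Kim = 7/h`) and a slow pool (`Frac = 0.1`, released at
`Kdiss = 0.05/h`) whose ~14 h half-life controls the residue tail.
Elimination is renal (`KurineC·BW·C_K/PK`) and biliary
(`KbileC·BW·C_L/PL`).

On top of the deterministic core:

- **Monte Carlo population** — the influential parameters (found by a
  normalized-sensitivity screen, `|NSC| > 0.25`) get truncated
  normal/lognormal between-animal distributions; 1000 virtual pigs are
  simulated per question.
- **%T>MIC dosage evaluation** — fraction of the 24-h dosing day with
  free concentration above the MIC, in plasma and in the lung biophase,
  with population percentiles and probability of target attainment
  (targets: 25–40% gram-positive, 40–50% gram-negative).
- **Withdrawal interval (WDI)** — first whole day after the last dose
  on which the population's 99th-percentile liver and kidney residues
  are below the MRLs (liver 0.1 µg/g, kidney 0.2 µg/g).
- **Microdialysis & NCA** — probe recovery/retrodialysis arithmetic,
  interstitial-fluid correction `C_ISF = C_dialysate / RR`, and
  non-compartmental analysis (Cmax, AUC, λz, MRT).
- **Synthetic data & calibration** — a generator that emulates the
  observed study designs (lognormal assay noise, LLOQ censoring) and
  bounded least-squares parameter fitting with R², MAPE and the WHO
  twofold rule as validation metrics.

Because the full system (depots, tissues, elimination, AUC
accumulators) is linear and time-invariant between dose events, the
default integrator propagates the exact matrix-exponential solution —
a 1000-animal day costs a couple of seconds on one core. A stiff LSODA
route is available and cross-checked in the tests.

## Worked example

```python
from ceqpbpk import DosingRegimen, auc, default_params, simulate

phys, chem = default_params()            # 25 kg pig, default drug parameters
series = simulate(phys, chem, DosingRegimen(dose_per_kg=2.0), t_end=24.0)
print(series.trace("plasma").max())      # 4.342 ug/mL  (Cmax at 0.25 h)
print(auc(series, "plasma", 0, 24))      # 8.847 ug*h/mL
print(series.mass_balance_error())       # 3.1e-14
```

A single 2 mg/kg label dose peaks at **4.34 µg/mL** in plasma within 15
minutes and yields a 24-h plasma AUC of **8.85 µg·h/mL**; the mass
balance closes to machine precision. Running
`python examples/04_population_dosage.py` (n = 200) prints the dosage
grid, e.g. for MIC 0.25 µg/mL in the lung biophase:

```
 dose_mg_per_kg schedule      matrix  p10  p50  p90
            2.0     q24h   lung_pelf 18.4 24.6 32.4
            4.0     q12h   lung_pelf 45.4 63.3 90.2
...
  2 mg/kg q24h (lung): PTA = 0.01
  4 mg/kg q12h (lung): PTA = 0.96
```

— the once-daily label dose leaves almost no animal above the 40%
gram-negative target, while the same or higher daily dose split q12h
attains it in most of the population; this is the quantitative case for
twice-daily extra-label dosing. `examples/05_withdrawal_interval.py`
prints the matching food-safety answer: a **2-day withdrawal interval**
for the label regimen, limited by liver.

The other examples cover microdialysis calibration + NCA (`02`), the
sensitivity screen (`03`) and parameter recovery on synthetic data
(`06`). The same analyses are available from the shell:

```bash
ceqpbpk simulate --dose 2 --t-end 24 --out sim.csv
ceqpbpk dosage-table --n 1000 --seed 1 --out table.csv
ceqpbpk wdi --n 1000 --seed 1 --out wdi.json
```

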