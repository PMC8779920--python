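# levpbpk

Physiologically based pharmacokinetic (PBPK) modelling of levetiracetam
(LEV), the renally cleared BCS-class-I antiepileptic, for people who need to
reason about rapidly dissolving oral formulations and pediatric dosing
without commercial PBPK software: formulation scientists comparing
instant-dissolving tablets against a reference product, and clinical
pharmacologists designing or repairing pediatric regimens against the
5–19 µg/mL therapeutic window.

The package couples a nine-compartment gut transit/dissolution/absorption
model (stomach → small-intestinal segments → colon, absorption rate
`ka_n = A_n·2·Peff/R_n` per segment) to a whole-body perfusion-limited
disposition model (`dA_t/dt = Q_t(C_art − C_t·Rbp/Kp_t)` per tissue, lung in
series, renal + hepatic clearance split 66/34). Tissue:plasma partition
coefficients come from the tissue-composition (Berezhkovskiy-type) equation,
giving a steady-state volume `Vss = (V_plasma + Σ Kp_t·V_t)/BW`. On top sit
non-compartmental analysis (linear-up/log-down AUC, best-fit λz, MRT),
average-bioequivalence statistics (TOST / 90% CI of the geometric mean
ratio, parallel and 2×2 crossover), a virtual crossover trial engine over
sampled Chinese-adult physiologies, and pediatric regimen design including
missed-dose remediation. Seeded generators for dissolution profiles, dog PK
studies and clinical-like profiles make every stage testable offline.

See `docs/methods.md` for the model equations, parameter provenance, design
choices and known limitations.

## Worked example

Validate the adult model against the six published clinical regimens
(IV 1500 mg infusion; oral 250–1500 mg tablets):

```
$ levpbpk validate
  regimen parameter  observed  predicted  pe_percent
  iv-1500      cmax    50.800  43.504158   14.361894
  iv-1500     auc0t   367.200 358.663869    2.324654
  iv-1500   auc0inf   370.700 370.902160    0.054535
  ...
oral-1500      cmax    35.300  30.096777   14.740007
oral-1500     auc0t   402.300 341.405930   15.136483
oral-1500   auc0inf   408.300 353.488332   13.424361
accuracy gate: PASS -> levpbpk_out/validation.csv
```

Every simulated Cmax and AUC lands within the 20% accuracy gate of its
observed value (Tmax is reported but not gated); the IV AUC(0–∞) matches to
0.05% because the adult clearance is itself derived from that cohort's
dose/AUC/weight (1500 / 370.70 / 64.19 ≈ 0.063 L/h/kg).

Rank remedial doses for a 6-year-old (22.26 kg) who missed the 60-h dose of
a 280 + 222.6 mg q12h regimen and plans to remediate at 72 h:

```
$ levpbpk dose-design -c src/levpbpk/data/examples/child-6y-remediation.yaml
steady state: trough 9.78, peak 21.61 ug/mL; in window 79% of the interval
chosen remedial dose: 300.0 mg
report: levpbpk_out/child-6y/dose_design.json
```

300 mg is selected because it equals the maintenance dose plus the decayed
remnant of the missed dose (≈ 301 mg by superposition); 275 mg fails to
return the profile to the reference trough and 350 mg overshoots the
reference peak. (The absolute trough/peak values run higher than the
published pediatric figures — the published pediatric clearance and
concentration spans are mutually inconsistent; `docs/methods.md` discusses
this.)

The same functionality is available as a library:

```python
from levpbpk import (build_adult_physiology, load_compound_profile,
                     kp_for_physiology, assemble_model, simulate, DoseEvent)

lev = load_compound_profile()
subject = build_adult_physiology(64.19, 1.70, 23.7, "M")
model = assemble_model(lev, subject, kp_for_physiology(lev, subject), "adult")
profile = simulate(model, [DoseEvent("iv_infusion", 1500, 0.0, 0.75)],
                   None, [0, 0.25, 0.75, 1.5, 4, 8, 12, 24, 36])
```

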