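# Methods

`levpbpk` is a mechanistic pharmacokinetic model of levetiracetam (LEV), a
renally cleared, freely soluble, highly permeable (BCS class I) antiepileptic.
It couples a compartmental absorption-and-transit description of the gut to a
whole-body perfusion-limited PBPK model, and layers three applications on
top: validation against published adult concentration–time parameters,
virtual bioequivalence of two rapidly dissolving tablet products, and
therapeutic-window dose design for children.

## Physiologies

Adult subjects are scaled from a 70-kg reference-man table of tissue volumes
and blood-flow fractions (`data/reference_physiology.csv`): volumes scale
linearly with body weight, blood flows and cardiac output with
weight^0.75. Total blood is 0.07 L/kg (haematocrit 0.45; plasma 0.0385 L/kg),
split 2:1 between venous and arterial pools. The reference table describes an
adult male; female subjects carry +10% adipose and −10% muscle. Pediatric
subjects (0.5–15 y; ages outside that span warn and extrapolate) derive
height from weight and BMI (`h = sqrt(w/BMI)`), use the same allometry, and
additionally carry a body-water uplift: total body water is interpolated
linearly from 0.75 at birth to the adult 0.60 at age 12, and tissue water
fractions are multiplied by `water(age)/0.60` (capped so fractions still sum
to ≤ 1). Virtual populations sample age, weight and BMI uniformly within the
configured ranges, with an exact `round(n·ratio)` male count and a NumPy
`default_rng(seed)` so identical seeds give identical subject lists.

The gut is nine compartments in fixed order — stomach, duodenum, two jejunal
and three ileal segments, caecum, colon — with fasted-state defaults: gastric
emptying 0.25 h, small-intestinal transit 3.3 h split across the six
segments, caecum + colon 13 h; pH rises 1.3 → 7.4 along the small intestine;
radii fall from 1.6 cm (duodenum) to 1.0 cm (distal ileum), with wider
caecum/colon. Luminal volumes scale linearly with weight, radii with its cube
root; transit times are age-independent.

## Tissue partitioning and Vss

Tissue:plasma partition coefficients use the tissue-composition
(Berezhkovskiy-type, non-ionized) equation over fractional water, neutral
lipid and phospholipid per tissue:

    Kp = [P·f_nl + (0.3P + 0.7)·f_ph + f_w]_tissue /
         [P·f_nl + (0.3P + 0.7)·f_ph + f_w]_plasma · fup/fut,

with `fut = 1/(1 + 0.5(1−fup)/fup)`. LEV (pKa 16.1) is un-ionized at any
physiological pH, so no ionic terms are needed, and with fup = 0.97 the
binding correction is nearly unity. For the neutral-lipid phase the default
partition coefficient is the vegetable-oil:water value from the Leo
correlation `log Pvo:w = 1.115·logP − 1.35`, applied to **all** tissues; the
plain octanol coefficient for lean tissues is available as a switch. For a
hydrophilic compound like LEV the octanol variant drives lean-tissue Kp above
1 and predicts Vss ≈ 0.72 L/kg, outside the literature range (0.5–0.7 L/kg);
the vegetable-oil variant gives lean Kp 0.47–0.86 with adipose lowest and
Vss = (V_plasma + Σ Kp·V)/BW ≈ 0.61 L/kg for the adult and ≈ 0.67 L/kg for a
6-year-old (the pediatric rise comes entirely from the body-water uplift).
logP (0.8) rather than logD (0.9) is the default lipophilicity input, with a
switch. The composition table ships as packaged text and can be overridden by
path.

## Oral absorption

Within each gut compartment, undissolved drug releases into solution
following the fitted Weibull in vitro profile, applied as a time-since-dose
hazard and capped by a luminal solubility term (1 − C/Cs). The packaged
profiles release >85% by 2.5 min and completely by 5 min, so release is never
rate-limiting; the solubility default is the freely-soluble 104 mg/mL figure
(the source table prints the solubility with an impossible unit, g/mol — we
treat that as a typo). Precipitation is a structural no-op for this compound
but the cap provides the hook. Both luminal pools transit first-order at
1/T_n; dissolved drug is absorbed at

    ka_n = A_n · 2·Peff / R_n,

zero in the stomach. `A_n` is a relative absorptive surface-area
amplification (duodenum 1.0 declining to 0.004 in caecum/colon), reflecting
the proximal concentration of mucosal folds and villi; its profile was set
once from the reported regional absorption pattern (duodenum ≈ 50%,
jejunum 1 ≈ 36%, jejunum 2 ≈ 8% of a 1500-mg dose). The in vitro (Caco-2
type) permeability 9.6×10⁻⁶ cm/s is mapped to the human effective scale by a
single calibrated log10 shift (+2.02, i.e. Peff ≈ 1.0×10⁻³ cm/s), fitted once
so the adult 1500-mg simulation absorbs 96.7% of the dose, stored in the
compound profile and never refit per run. Mass balance
(lumen + absorbed + exited = dose) holds to 0.1% of dose at every output
time.

## Disposition

Each tissue is one well-stirred compartment,
`dA_t/dt = Q_t(C_art − C_t·Rbp/Kp_t)`, with the lung in series between the
venous and arterial pools and gut + spleen draining through the portal vein
into the liver. State variables are tissue amounts (mg); reported plasma
concentration is venous blood / Rbp (1.11), and 1 mg/L ≡ 1 µg/mL. Clearance
is plasma-referenced: 0.063 L/h/kg for adults (derived from the printed IV
dose/AUC/weight; the 0.96 mL/min/kg literature value is exposed separately)
and 0.053 L/h/kg for children, times body weight. 66% is renal, implemented
at the kidney driven by the arterial plasma concentration; the remainder is
removed at the liver inlet (first-pass extraction ≈ 1.5%, consistent with
near-complete oral bioavailability). Driving both eliminations by inlet
concentrations makes `AUC(0–∞) = Dose/CL` hold exactly for IV dosing, which
the tests verify to 0.5% against the integrator.

Integration uses LSODA with rtol 1e-8, atol 1e-10 mg; every dose event
(bolus, infusion start/end, oral administration) restarts the integrator.
Oral doses enter the stomach pool and reset the dissolution clock; because
the fitted release is near-complete within minutes, the pool is empty long
before the next dose and multiple-dose profiles superpose to 0.1% (exactly,
for shape-1 Weibull release). An independent matrix-exponential solution of
the same linear system, constructed separately in the tests, agrees to 0.1%.

## NCA and validation

AUC uses linear-up/log-down trapezoids (AUMC analogously); λz is the
log-linear slope over the terminal window (≥3 points strictly after Tmax)
maximizing adjusted R², ties to fewer points; AUC(0–∞) adds C_last/λz;
absent terminal decline yields NaN fields rather than an exception.
Prediction error is `100·|pred − obs|/obs` (the absolute value follows the
quantity's name in the source; its printed formula omits the bars). The
validation harness simulates the six published adult regimens — IV 1500 mg
as a 45-min infusion (the observed Tmax of 0.711 h identifies the infusion
duration) and oral 250–1500 mg — on a clinical-style sampling grid to 36 h,
using each cohort's printed body weight, and passes when every Cmax and AUC
error is ≤ 20% (Tmax is reported, not gated). With the packaged defaults the
worst gated error is ≈ 17% (oral-1000 AUC, a cohort whose apparent clearance,
0.077 L/h/kg, sits well above the IV-derived 0.063).

## Bioequivalence

TOST via the 90% CI of the geometric mean ratio on log-transformed Cmax/AUC.
Parallel designs use the pooled two-sample interval plus a one-way ANOVA
p-value; 2×2 crossover designs use the period-difference estimator (equal
weight on the two sequence means, sequence-stratified pooled variance,
df = n−2). Zero within-design variance degenerates the CI to the exact ratio
with a warning. The virtual trial simulates every sampled subject under both
products (same physiology, different dissolution input), runs NCA, and
applies the crossover TOST against 85–120% limits at 1000 mg (the published
analysis does not print its dose; the reported Cmax ≈ 25 µg/mL implies
1000 mg). Between-subject variability comes solely from the sampled
physiologies; an identical-formulation trial is therefore exactly degenerate
at GMR 100%.

## Pediatric regimen design and missed doses

Regimens are loading + maintenance q12h schedules simulated for 7 days;
steady-state trough/peak come from the final dosing interval (steady state =
trough change < 1% between successive intervals), judged against the
5–19 µg/mL pediatric monotherapy window. `find_regimen` scans ascending
maintenance then loading dose and returns the first candidate inside the
window, or the least-violating one.

**Known limitation.** The published pediatric inputs are mutually
inconsistent: 0.053 L/h/kg clearance with Vss ≈ 0.6 L/kg implies an average
steady state of ≈ 15 µg/mL at 10 mg/kg q12h, whereas the published pediatric
simulations show troughs of 3–4 µg/mL (which would require roughly half the
exposure). This package follows the printed clearance; consequently its
10 mg/kg troughs sit near 10 µg/mL, inside the window rather than below it,
and the corresponding window-direction tests fail by design rather than
being tuned to pass. The missed-dose arithmetic is unaffected because it is
scale-free (see below).

Remediation of a dose missed at 60 h with a replacement at 72 h compares each
candidate against the no-miss reference: a candidate is acceptable when the
post-remediation curve never exceeds the reference steady-state peak (2%
numerical tolerance) and returns to within ±10% of the reference profile by
the next scheduled dose; among acceptable candidates the one minimizing the
integrated |deviation| from the reference wins. Under the printed clearance
the exact-superposition replacement dose is maintenance + missed-dose
remnant = 222.6 + 222.6·e^(−ke·12) ≈ 301 mg, which is why 300 mg is chosen
while 275 mg under- and 350 mg overshoots — reproducing the published
ranking independently of the absolute concentration scale.

## Synthetic data

The generators are first-class, seeded code: fast/slowed Weibull dissolution
profiles (truth td 1.3 min, shape 1.2; ≤2% multiplicative noise; points where
the true curve is ≥99% released report as complete); dog study datasets whose
one-compartment group truths are back-calculated from the published group
means (ke from half-life, V/F from dose/AUC/ke, ka refit to the group Cmax on
the sampling schedule — the published Tmax values are not simultaneously
satisfiable in a one-compartment model and are left free) with mean-preserving
lognormal between-subject variability (default CV 10%, n = 3/group); and
clinical-like adult profiles (mono-exponential IV, Bateman oral with
ke = 1.35·Cmax/AUC so the peak is attainable) whose NCA reproduces the
observed Cmax/AUC within 5%. None of these touch the PBPK machinery, so they
double as independent oracles for the NCA module. They emulate noise-free or
lognormally varying ideal kinetics only — no assay noise, no BLQ censoring,
no dropout — so green tests on them demonstrate the statistics and the
round-trip plumbing, not robustness to real bioanalytical artefacts.

## Problem sizes and tolerances

Default runs: 36-h single-dose grids (clinical-style, 15 points), 7-day
regimen grids at 30-min resolution, 24-subject virtual trials, 200-replicate
TOST power checks. ODE tolerances rtol 1e-8 / atol 1e-10; Weibull fits by
bounded least squares with a ±5-percentage-point fit-quality warning and a
2-point non-monotonicity tolerance on measured profiles. All randomness
flows through explicit integer seeds.
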