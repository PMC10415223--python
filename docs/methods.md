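# Methods

## Model structure and assumptions

The disposition model is a whole-body PBPK system of 16 perfusion-limited
organ compartments plus arterial and venous blood pools, with the lung in
series with total cardiac output. Organ mass balances are written in drug
amounts (mg); venous outflow concentration of organ *i* is
C_i·B:P/Kp_i, where Kp_i is the tissue:plasma partition coefficient and
B:P the blood:plasma concentration ratio. Splanchnic organs (spleen,
stomach, small and large intestine, pancreas) drain through the portal
vein into the liver, whose arterial supply is the hepatic-arterial flow
carried on the physiology. The infusion enters the venous pool at
dose/duration during the infusion window. The observation compartment is
venous plasma (clinical assays report plasma), converted from venous
blood via B:P.

Assumptions worth stating explicitly:

- **Perfusion-limited (well-stirred) organs.** The reference platform for
  this drug class combines a composition-based partition model with a
  cellular-permeability model; permeability values for cefepime are not
  published, so this package uses the standard perfusion-limited
  simplification. The main consequence is a nearly mono-exponential
  decay after distribution: terminal half-life ≈ ln2·V/CL with V close
  to Vss, which for this drug lands in the reported 2–2.3 h window
  anyway.
- **Linear, renal-only elimination.** No hepatic clearance is modeled
  (none is reported for cefepime); elimination is a single plasma
  clearance attached to the kidney. The elimination rate is driven by
  kidney-*inflow* (arterial) plasma concentration rather than outflow
  plasma. With outflow-referenced clearance, dose/AUC would understate
  the nominal clearance by the kidney extraction ratio (≈18% at 8.8 L/h
  against a kidney plasma flow of ≈41 L/h), breaking the dose/AUC = CL
  identity that the published predicted AUC/CL pairs obey. Inflow
  referencing makes the identity exact for the linear model.
- **Drug confined to plasma within blood.** A polar permanent zwitterion
  is assumed not to enter erythrocytes: Kp(red cell) = 0 and
  B:P = 1 − HCT (0.55 at HCT 0.45). B:P therefore rises slightly in
  anemic CKD subjects.

## Partition coefficients

Kp values follow the Rodgers–Rowland tissue-composition framework:
Kp = fu·Kpu with

Kpu = f_EW + (X/Y)·f_IW + lipid terms + RA·(1/fu − 1 − L_p)

where f_EW/f_IW are extracellular/intracellular water fractions, X and Y
the ionized-species sums at intracellular (7.0) and plasma (7.4) pH, RA
the tissue:plasma albumin ratio, and L_p the drug's binding to plasma
lipids. Branches for neutral, acid, base and zwitterion drugs are
implemented; the branch is part of the drug parameter set and
overridable.

Cefepime carries a permanently cationic quaternary ammonium and a
carboxylate (pKa 4.06; the second constant 13.2 corresponds to a proton
that never dissociates at physiological pH). The zwitterion branch
therefore takes the net-neutral zwitterion as the permeant reference
species: X/Y ≈ 1 (no ion trapping, since both compartments hold ≥99.9%
zwitterion), and neutral-lipid partitioning is set to zero because
charge-separated, betaine-like species have distribution-relevant
lipophilicity orders of magnitude below the neutral-species log P. What
remains is distribution into total tissue water plus
extravascular-albumin binding. With the packaged composition table this
yields Kp ≈ 0.44 (muscle), 0.11 (adipose), 0.47 (kidney) and a
whole-body Vss of 0.35 L/kg — consistent with the ≈0.22 L/kg reported
for cefepime and well inside the hydrophilic-drug band asserted in the
tests (0.1–0.5 L/kg).

Tissue compositions and albumin ratios are literature values compiled
from the published composition tables of the partition-coefficient
method; they ship as a versioned TSV inside the package.

## Physiology and population scaling

The reference adult is an ICRP-style organ table (volumes and flows for
a 70 kg male), linearly volume-rescaled so total organ volume equals
body weight at unit density, with flows scaled by (BW/70)^0.75. Cardiac
output is defined as the sum of non-lung organ flows, so the circulatory
loop closes by construction. Defaults: HCT 0.45 (male) / 0.40 (female),
GFR 120 mL/min, plasma protein binding factor (PBF) 1.0, gastric
emptying time (GET) 15 min. GET is carried and reported for fidelity to
the disease parameterization but has no effect on IV simulations.

Disease and age transforms are pure functions on the physiology:

- **Moderate CKD** (CrCL 31–60 mL/min): GET 20.625 min, PBF 0.9265,
  HCT 0.433; GFR defaults to the band midpoint 45.5 mL/min (overridable —
  the per-patient values behind the source study are not reported);
  clearance scales by GFR/120. Organ flows unchanged.
- **Severe CKD** (11–30 mL/min): GET 24.375 min, HCT 0.398, PBF 0.837,
  renal blood flow 0.17 L/min, hepatic-arterial flow 0.16 L/min (the
  kidney and liver organ flows are set to these absolute values and
  cardiac output recomputed); GFR defaults to 20.5 mL/min.
- **Obesity**: GFR = 143·BSA/1.73 mL/min with Du Bois BSA
  (0.007184·W^0.425·H^0.725); HCT and plasma binding unchanged;
  non-adipose organs stay at the size expected for normal
  weight-for-height (BMI 25) and the excess weight is assigned to
  adipose. The weight-specific renal clearance is referenced to normal
  weight-for-height, which reproduces the modest clearance increase
  (≈8.8 → 9.1 L/h) reported for obese subjects; per-total-kg referencing
  would nearly double clearance, which no clinical data support.
- **Pediatrics** (2 months–18 y): organ volumes scale linearly with
  weight; the eleven literature organ flows (large intestine 0.43, heart
  0.35, liver 0.53, spleen 0.29, skin 0.23, small intestine 1.4, stomach
  0.10, pancreas 0.08, muscle 0.88, kidney 1.4, brain 1.85 L/min, given
  at 70 kg-equivalent size) and GFR scale by (W/70)^0.75. Absolute
  clearance follows the same 0.75-power allometry, i.e. per-kg clearance
  gains a (W/70)^-0.25 factor; at school-age weights this gives
  0.16–0.20 L/h/kg, matching the reported pediatric predictions. The
  literature flow set exceeds adult cardiac output when summed at 70 kg;
  because cardiac output is defined as the flow sum, the loop remains
  consistent, but these flows should be read as a published
  parameterization, not as measured pediatric hemodynamics.

Virtual populations draw age and weight uniformly over the ranges each
study reports (only ranges are published), assign sex to match the
reported number of females, and back-calculate height from weight and a
cohort BMI draw (healthy/CKD 20–27, obese 31–45, pediatric 14–19), since
the study table omits height. Inter-individual variability beyond
anthropometrics is deliberately off by default so that qualification
runs are driven by documented inputs only. Each subject's unbound
fraction is recomputed from their PBF via
fu' = 1/(1 + PBF·(1 − fu)/fu) and their Kp set rebuilt from fu'.

## Numerics

- Integration: LSODA (stiff-capable) with rtol 1e-8, atol 1e-10 mg,
  restarted at every infusion on/off boundary so discontinuities never
  cross a solver step. Mass balance (infused = in body + eliminated)
  holds to ~1e-15 relative.
- Output grid: 0.05 h over 0–12 h for adults; 0–48 h for CKD, where the
  terminal half-life reaches ~12 h.
- NCA: Cmax/tmax with earliest-time tie-breaking; AUC by
  linear-up/log-down trapezoids (pure linear available; log segments
  with nonpositive endpoints fall back to linear and are logged); λz by
  log-linear regression over the post-peak tail with the best adjusted
  R² among candidate tails of ≥3 points; AUC0–∞ = AUC0–t + C_last/λz
  with the extrapolated fraction reported and warned above 20%.
- Percentiles: linear-interpolation empirical quantiles (quantile
  conventions differ between tools; this one is stated).
- Fold-ratio statistics keep full precision; two-decimal display
  rounding is separate. The two-fold band is inclusive at both ends.

## Synthetic observed data

The clinical profiles behind the published tables are digitized figure
means and are not deposited; the synthetic module emulates their
structure: simulate a small cohort, sample at a sparse clinical schedule
(default 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8, 12 h), multiply each
point by exp(ε) with ε ~ N(0, ln(1+CV²)) (proportional log-normal
residual, default CV 15% — typical for digitized mean PK data), and
average across subjects. Everything is seeded and regenerates
bit-identically from (spec, seed).

What passing the recovery loop does and does not show: it demonstrates
that the pipeline (simulate → sparse sampling → NCA → fold ratios) is
self-consistent — ratios converge to 1 as CV → 0 and concentrate around
1 as CV/√n under noise. It does not validate the model against real
digitized data, which carry digitization error, inter-study assay
differences and model misspecification that the generator deliberately
does not emulate (no below-LOQ censoring, no assay bias).

## Problem sizes

The test suite and the acceptance script use 100 virtual subjects for
the healthy population clearance (the study design's virtual-cohort
size), 6–12 subjects per synthetic study, 20 replicate seeds for the
recovery experiment, and single-subject runs for dose-proportionality,
infusion-duration and disease-severity checks. The full suite runs in
well under a minute of simulation time on one CPU.

## Known limitations

- CKD and pediatric concentration *values* are not expected to match the
  published predictions exactly: those depend on a proprietary
  physiology database and on unreported within-band GFR choices. The
  package therefore checks directions (clearance falls and half-life
  rises with CKD severity; shorter infusions raise Cmax) and bands
  (healthy t½ 1.8–2.6 h) at the simulator level, and reproduces the
  published numbers exactly only where the published tables themselves
  are the input.
- Single-dose IV infusion only (the qualification studies are all
  single-dose); no oral or intramuscular routes, no metabolites
  (N-methylpyrrolidine pathway), no target-site (CSF) predictions, no
  dialysis, no below-LOQ handling.
- Some printed summary cells in the source tables do not recompute from
  their own observed/predicted pairs (truncated ratios, one duplicated
  column block, one arithmetic/geometric mean labeling inconsistency).
  The fixtures preserve the tables as printed, flag the anomalous block,
  and the reproduction targets only the statistics that recompute.
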