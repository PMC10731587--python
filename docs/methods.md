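# Methods

`erythrosim` is a quantitative systems pharmacology (QSP) model of human
erythropoiesis and its disruption in chronic kidney disease (CKD), together
with the pharmacology of the two drug classes used against renal anemia —
erythropoiesis-stimulating agents (ESAs: epoetin alfa/rHuEPO, darbepoetin
alfa) and oral prolyl-hydroxylase inhibitors (PHIs: vadadustat,
daprodustat) — and an adaptive dose-titration trial engine.

## The physiological model

Nine ODE state variables close one feedback loop (time unit: hours):

| state | units | role |
|---|---|---|
| HIFα | a.u. | hypoxia-inducible factor α subunit |
| EPO_plasma, EPO_periphery | ng/mL | endogenous erythropoietin, central/peripheral |
| EPOR_free, EPO·EPOR | molecules/mL | free receptor and ligand–receptor complex on CFU-E progenitors |
| progenitors, precursors | cells/mL | CFU-E stage; marrow reticulocytes |
| retics_plasma, RBC | cells/mL | circulating reticulocytes and erythrocytes |

Hemoglobin is an observable, `Hb = (MCH_retic·retics + MCH_RBC·RBC) ×
1e-10` (pg/mL → g/dL).

The loop: Hb sets active prolyl hydroxylase,

    PHD = PHD_basal / (1 + PHI_effect) · Hbeffect(Hb),

with `Hbeffect` an increasing, saturating Hill function normalised to 1 at
the healthy reference Hb (13.5 g/dL); PHD degrades HIFα
(`dHIF/dt = k_prod − HIF·PHD·k_mod`); HIFα drives renal EPO production
through a steep Hill term (exponent `n2 = 8`, reflecting the near-switch
recruitment of EPO-producing cells under hypoxia); plasma EPO is cleared
non-specifically, exchanges with a peripheral compartment, and binds EPOR
on progenitors in molecule units; the complex is internalised
(target-mediated disposition) and its recycling is the only source of free
receptor, which makes **free receptor + complex exactly conserved** — the
receptor total is fixed per virtual patient at ~1,000 EPOR per
steady-state progenitor. The EPO·EPOR complex suppresses progenitor
apoptosis through a bounded Hill factor `f < 1` (apoptosis rate
`k_baseline_deg · (1 − f)`), and surviving cells mature progenitor →
precursor → circulating reticulocyte → RBC as first-order transfers.

Both equation-reading ambiguities of the PHD expression are implemented;
the multiplicative ("ratio") form is the default and the additive variant
sits behind `PhysioParams.phd_form = "additive"`.

## Drug models

**ESAs** — SC doses enter a depot drained at `ka` into plasma (IV doses go
to plasma directly) scaled by a lumped bioavailability; the plasma drug
shares the endogenous EPO elimination and distribution rates and binds
EPOR with drug-specific on/off rates; complex internalisation is common to
both ESAs. The darbepoetin on-rate is an *in-vivo potency* constant, not a
biophysical affinity: it (together with an effective bioavailability of
0.8) absorbs what makes the sparse Q2W schedule clinically equivalent to
weekly epoetin at the 200 IU : 1 µg conversion. rHuEPO absorption is
flip-flop limited (terminal phase set by `ka`), which carries the 16-h
plasma Tmax; darbepoetin's slower `ka` gives the 3–4× longer terminal
half-life.

**PHIs** — two-compartment oral PK with a discrete absorption lag;
daprodustat adds a saturable (Michaelis–Menten) clearance that makes its
AUC superlinear in dose. The pharmacodynamic effect is a Hill function of
the central concentration that enters the PHD expression, raising HIFα and
hence *endogenous* EPO.

## Calibration

All rate constants are estimated against printed clinical anchors by
deterministic bracketed 1-D root-finding (no stochastic optimiser), in a
fixed order (`calibration.calibrate_reference`, ~2–3 min, memoised):

1. Hb→PHD Hill exponent and `k_mod` from the HIFα half-life window
   (5 min at Hb 14 → 8 min at Hb 9 g/dL); HIF production normalised so
   HIF_ss = 1 at the reference Hb.
2. Healthy baseline: progenitor production ↔ Hb 13.5 g/dL; maximal EPO
   production ↔ plasma EPO ≈ 0.083 ng/mL (~10 mIU/mL); the survival-Hill
   midpoint is pinned at 10× the baseline complex (this multiple controls
   how long a weekly ESA pulse saturates progenitor survival and is what
   lets the reticulocyte response *peak and then fade* under continued
   dosing).
3. rHuEPO `ka` ↔ 16-h Tmax.
4. Survival ceiling `f_emax` ↔ healthy Hb 16.4 g/dL after 4 weeks of
   40,000 IU QW; precursor maturation rate ↔ reticulocyte peak on day 10
   (two outer passes).
5. Darbepoetin `ka` ↔ terminal-half-life ratio 3.5.
6. CKD stages: the EPO-production axis is *fixed small* per stage (CKD
   anemia is EPO deficiency — circulating EPO stays near the healthy
   level despite anemia because the renal hypoxia response is lost), the
   progenitor axes follow a declared profile, and the RBC-degradation
   axis is solved to the stage Hb targets 12.3 / 10.8 / 9.5 / 8.6 g/dL
   (CKD 1.5/3/4/5). This choice is what gives ND cohorts a clinically
   strong response to ~10,000 IU/week ESA doses: the drug is a large
   signal relative to a deficient endogenous EPO.
7. Darbepoetin on-rate ↔ the ND trial's mean Hb gain (+2.1 g/dL on
   60 µg Q2W, CKD 4 reference).
8. Vadadustat Emax ↔ the phase-2 ND trial's mean end Hb (10.8 g/dL),
   solved at *trial level* on a fixed internal cohort (n = 24, seed 1234)
   — the same top-down calibration the virtual populations are built for.
   Daprodustat Emax uses a fixed-dose CKD 4 anchor (+0.83 g/dL, 4 mg QD).

`calibration.check_anchor_suite` re-simulates each anchor and reports
observed vs target; all shipped anchors must pass before any parameter set
is used downstream.

## Virtual patients and populations

A reference VP is a parameter set solved to a drug-free steady state
(scalar bracketed solve on the Hb fixed point, receptor total iterated to
self-consistency, polished by a full Newton root with the conservation law
substituted for the degenerate receptor equation; residual < 1e-8
relative). Populations are built by accept/reject sampling: seven
disease-relevant parameters receive lognormal variability (median at the
reference; CVs 0.05–0.30, chosen to reproduce the ~0.7–1.0 g/dL baseline
Hb spread of trial cohorts), each candidate is re-solved to its own steady
state, and candidates are kept when baseline Hb falls in the trial entry
band (reported mean ± 2 SD). ND cohorts mix CKD 3/4/5 by
largest-remainder apportionment of the reported stage fractions and are
ESA-naive. HD cohorts are CKD 5 only; each candidate is carried to
baseline by a simulated rHuEPO run-in (pattern drawn uniformly from
3,500–4,800 IU TIW or 4,650 IU QW, 17–21 weeks) and accepted on its
end-of-run-in Hb, so the HD baseline is an *on-therapy* state that decays
when the ESA is withdrawn. Residual run-in drug is dropped at trial start
(short washout assumed); the persisting RBC mass is what matters at these
timescales.

## Trial engine

`run_trial` simulates each VP between scheduled assessments and applies an
ordered-rule titration protocol at each one: safety hold first (dose
withheld above the hold threshold, resumed one ladder step below the
pre-hold dose once Hb falls below the resume threshold), then the first
matching rule among rapid-rise step-downs, band-based step-down/up, and a
default maintain. During the fixed-dose phase only the hold may fire.
Decisions are pure functions of the assessment-time Hb history, so stored
dose traces replay exactly. Shipped protocols: a generic ESA protocol
(target 12–12.9 g/dL, hold at 13 — the early-2000s Hb targets of the
epoetin/darbepoetin calibration trials), the phase-2 vadadustat ND
protocol (150/300/450/600 mg QD, hold at 12 g/dL by default — the
modified threshold that matches the trial's Hb data; the published 13 g/dL
is a flag away), the phase-3 vadadustat HD protocol (band 10–11, hold
above 11, resume one tablet lower), and the epoetin validation design
(band 11–11.9, 25%-step ladders, no increases for 4 weeks, week-23 TIW →
10,000 IU QW switch). For weekly/TIW arms the in-band down-step is
anticipatory (11.6 g/dL) because part of the response to recent doses has
not yet reached the blood at assessment time; a Q2W arm assessed biweekly
sees each dose's full effect and titrates at the band edge (11.9).

## Numerical choices

LSODA with hard restarts at every dose event; default rtol 1e-8 with
per-state absolute tolerances scaled to typical magnitudes (population
trials use rtol 1e-6). Negative excursions beyond 1e-6 of a state's
typical scale abort the run. PHI lag times shift the dose event rather
than adding transit compartments. Peak times (Tmax, reticulocyte peak) are
refined by parabolic interpolation on the output grid.

## What the synthetic data do and do not establish

The virtual populations emulate *parametric* inter-patient variability in
disease mechanism; they contain no iron status, inflammation, compliance,
dropout, dialysis blood loss, demographic covariates or assay noise.
Passing trial-endpoint checks therefore establishes that the calibrated
mechanism plus protocol logic reproduces cohort-mean Hb dynamics — not
that the model predicts individual patients or safety outcomes. Body
weight is a fixed 70 kg default (the sources do not report weights).

## Known limitations

* The epoetin-validation TIW arm's published *simulated* percent change
  (12.33% at 44 weeks) implies a mean end Hb ~0.2 g/dL *below* the
  11–11.9 g/dL band that arm titrates to; a controller that faithfully
  pursues the band ends inside it, and this package reports 17–19% for
  that arm. The other two arms land within tolerance.
* Endogenous EPO rises with anemia severity within a stage; across-stage
  EPO levels are not constrained and are not monotone.
* The receptor pool does not track progenitor expansion under therapy
  (conservation is built into the published receptor-recycling structure).
* Diurnal EPO variation, iron/hepcidin dynamics and CKD progression over
  years are out of scope.
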