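# Methods

`mammosim` is a discrete-event microsimulation of the UK NHS triennial
breast-screening programme, built to compare two reading strategies for
screening mammograms — standard practice (two independent human readers)
against a single human reader plus an AI second reader — on lifetime
discounted costs and QALYs from the NHS perspective.

## Model structure

Each woman is simulated from age 19 to death. Time advances on the 3-year
screening grid anchored at age 50:

* **Carcinogenesis.** An annual age-specific hazard governs the first
  appearance of cancer cells from age 19; a woman has at most one tumour.
* **Tumour growth.** Volume grows logistically between a 0.25 mm starting
  diameter and a 128 mm asymptote, with spherical diameter–volume
  conversion. The per-year volumetric rate is drawn once per woman from a
  lognormal with mean 1.07 and SE 0.00208. Read as the logistic rate
  constant, this gives a diameter doubling time of 3 ln 2 / 1.07 ≈ 1.9
  years in the exponential regime, matching published continuous-growth
  estimates of the time to grow from 10 mm to 20 mm (≈1.7 y); read instead
  as a per-year volume multiplier it would imply centuries from onset to
  clinical size, which is not a usable screening model.
* **Screening.** Invitations at ages 50, 53, …, 68; each is attended with a
  fixed probability (default 0.60, see *Calibrated defaults*). An attended
  study is read independently by the arm's two readers; with cancer the
  abnormal probability is sensitivity × a breast-density multiplier
  (VDG 1–4 → 1/0.91/0.81/0.69), without cancer it is 1 − specificity.
  Concordant calls stand; discordant calls go to one arbitration read
  (sensitivity 1.0, specificity 0.95, not density-penalised — arbitration
  reviews the study with both first reads in hand). An abnormal final call
  triggers recall to triple assessment whose biopsy is perfect, so recall
  always resolves the truth. Sensitivity is size-independent by design.
* **Symptomatic pathway.** Mid-way through every 3-year cycle an undetected
  invasive tumour presents symptomatically with the stage-specific
  proportion (NPI I/II/III = 0.53/0.80/0.87 per interval; advanced tumours
  use the NPI III value; in-situ disease is asymptomatic). The checks run
  from age 20.5, before screening eligibility: women who present before 50
  enter care outside the programme and are excluded from the screened
  cohort (conditioning the cohort on reaching 50 undiagnosed, ~2 % of
  women). Post-programme checks continue until death, so cancers arising or
  missed after 68 can still surface.
* **Staging and survival.** At the first classification event (screen
  detection or symptomatic presentation) the tumour is in-situ (DCIS) with
  probability 0.09, otherwise an NPI class is drawn from a size-conditional
  table and an advanced stage supersedes with a size-conditional
  probability. Survival from classification is exponential with the stage
  mean in years (NPI I/II/III 5.413/4.023/2.465; advanced 0.527/0.537/0.849
  by age band <50/50–70/>70); DCIS follows background mortality only.
  Death age is the minimum of the natural and cancer death ages.
* **Economics.** Costs and QALYs accrue from age 50 only, discounted to age
  50 at 3.5 %/y (NICE reference case; the source analysis does not print
  its rate). Screening episodes cost acquisition (£184) + reading labour
  (SP £11.80 = 2 × £5.90; AI arm £10.62 = £5.90 + £4.72) + one human
  arbitration read when discordant + £314 triple assessment on recall +
  £52.90 oncologist and £148.40 MRI on diagnosis. Locum outsourcing
  replaces a configurable fraction of human reads at £10.30 (the £5.90
  in-house rate plus the £4.40 per-reader census premium). Treatment
  streams: DCIS one-off £8,968; NPI first-year cost then years 2–9 annual
  cost while alive; a cancer death replaces the final year with six months
  of advanced care (£14,984) plus six months of pro-rata palliative care
  (£14,827 spread over its 372 reference days). Utilities: age-band values
  while cancer-free or cured; stage "at 12 months" for the first year, then
  "from 12 months" to year 9; cancer deaths spend their last year at the
  advanced utility (0.74) and last six months palliative (0.51). The AI arm
  additionally carries (set-up + maintenance × service-years)/reference
  cohort per patient (£35,000/100,000 = £0.35 base case).

## Common random numbers and streams

All natural-history randomness — density, natural death age, onset age,
growth rate, the uniforms behind every stage draw, a standardised Exp(1)
survival draw, attendance, symptomatic uniforms — lives in one stream
shared by both arms, so a woman's disease trajectory is bit-identical
across arms and any outcome difference is caused by reading. Each arm has
its own independent reading stream; the PSA parameter stream is separate.
Streams are derived from the master seed with fixed spawn keys, so adding a
new purpose never perturbs existing streams. Stage and survival draws are
pre-drawn uniforms mapped through diameter-dependent probabilities at the
moment of classification, which keeps them common across arms even when
the arms classify at different ages.

## Probabilistic sensitivity analysis

Each PSA iteration draws one parameter set — Beta by method of moments from
(mean, SE) for probabilities and utilities; lognormal with
σ = (ln hi − ln lo)/3.92 and the location matching the printed mean for
costs; Dirichlet blocks (density, NPI rows, symptomatic and advanced
proportions) jointly with concentration = proportions × n_eff (default 100,
since no sample sizes are published) — and runs a fresh cohort with an
iteration-specific seed. Reader sensitivities/specificities and all fixed
rows stay at their means. Both first-order (cohort) and second-order
(parameter) noise are therefore re-sampled per iteration. One cost row
(DCIS, mean £8,968, CI £9,692–£10,471) prints its mean outside its CI; the
package logs a warning once and uses the printed values.

## Decision analytics

ICER is the ratio of mean incremental cost to mean incremental QALYs, with
its cost-effectiveness-plane quadrant attached (a south-west ratio is
"cost-effective" when *above* the threshold). NMB = λ·QALYs − Cost at
λ = £20,000/QALY. The CEAC reports the fraction of iterations with positive
INMB across a £0–£50,000 grid. The jackknife CI applies leave-one-out
pseudo-values to the ratio of means over PSA iterations; when the QALY
difference straddles zero the interval is honest but explosive, which is
the statistic's behaviour, not a defect. The maximum reimbursable price is
found by bisection on mean INMB as a function of the AI per-study price;
because the price enters linearly through the discounted attended-study
count and common random numbers keep the pathway price-invariant, the
search closure reprices a single PSA run exactly.

## Calibrated defaults (synthetic stand-ins)

The national input tables are not bundled; the package generates synthetic
stand-ins and accepts drop-in `age,rate` CSVs.

* **Mortality**: Gompertz–Makeham hazard from age 50 (zero before 50,
  closure at 110), slope 0.105/y and Makeham term 3e-4 — the shape of the
  UK female life table — with the level solved so life expectancy at 50 is
  37.0 years (ONS-scale). Simulated mean age at death 87.0.
* **Incidence**: smooth unimodal hazard over ages 19–89 (Gaussian in age,
  peak 60, width 14) scaled so cumulative carcinogenesis risk is 0.125
  (the familiar 1-in-8 lifetime figure) within 1e-3.
* **Staging tables**: monotone NPI-membership-by-size and
  advanced-by-size tables on clinical size bands (<10, 10–15, 15–20,
  20–30, 30–50, ≥50 mm), with NPI I falling and NPI III/advanced rising in
  size. The probabilities are synthetic; the real size-conditional tables
  can be supplied as CSV.
* **Attendance** 0.60: not printed in the source; chosen so a woman
  accumulates ≈3 discounted AI-read studies over her screening lifetime,
  consistent with the headline price arithmetic (an INMB of ≈£2.70 at
  £4.72/study vanishing at £5.50/study).

Event ages are drawn by treating each tabulated year as a constant
continuous hazard (λ = −ln(1−p)), which reproduces the annual
probabilities exactly and makes sampling exactly invariant to splitting
the horizon.

## What the synthetic data do and do not show

The generator reproduces the *level* of mortality and incidence and the
*direction* of the staging gradients, but not the empirical fine structure
of the national tables (period-by-age mortality curvature, the real
size-conditional NPI distribution). Passing tests therefore demonstrate
that the machinery — pathway logic, accounting identities, CRN discipline,
decision statistics — is correct under realistic conditions; they do not
validate the model against observed UK detection rates, which the model is
in any case not designed to predict.

Two structural consequences of the published parameterisation are worth
stating plainly, because they dominate scaled comparisons:

1. **Survival means bind hard.** Read as exponential means in years (the
   only stated reading), the stage survival parameters imply that ~87 % of
   diagnosed women die of their cancer, an average loss of ≈5.5 discounted
   QALYs per diagnosed woman and ≈0.5 per cohort member. Mean cohort QALYs
   therefore sit near 15.3, below what the headline results of the source
   analysis suggest; the two cannot be reconciled with the printed values.
2. **Within-stage lead time.** Survival is anchored at the classification
   event, so a missed tumour recaptured one cycle later *at the same stage*
   restarts the same survival clock later and gains life-time. Because
   episode sensitivity is high (~0.94 with perfect-sensitivity arbitration)
   and the symptomatic proportions recapture misses within ~1 cycle,
   tumours are classified at sub-millimetre sizes where stage boundaries
   are rarely crossed, and the lead-time gain slightly outweighs the
   stage-progression loss: the marginally less sensitive arm shows a small
   *positive* QALY increment (≈+1e-4). Sensitivity-degradation scenarios
   consequently do not lose enough health benefit to offset their reading
   savings in this implementation.

## Numerical choices

Continuous discounting for utility streams (annuity with ln(1+r)
divisor), discrete factors for point cash flows; ties between cancer and
natural death resolve to natural; diameters outside the staging support
clamp to the nearest band with a warning; degenerate Beta/lognormal inputs
raise named errors; the bisection price search brackets [0, 50] with £0.01
tolerance. Desk-scale defaults (10,000 women × 200 iterations for the base
case, 5,000 × 60 for scenario comparisons) keep a full analysis within a
few minutes on one CPU; cohort size, iterations and every parameter above
are configurable.

## Known limitations

No QALY decrement for false positives (deliberate, matching the source
analysis's exclusion — which also removes the only channel by which
specificity could affect QALYs); no DCIS progression to invasive disease;
no treatment-pathway detail below the stage label; one cohort rather than
annually refreshed population dynamics; no radiographer/radiologist
staffing-mix scenarios.
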