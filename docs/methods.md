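# Methods

## Scope and design

`coiburden` is a single-base-year, prevalence-approach cost-of-illness
model: all costs attributable to the prevalent diagnosed NASH population
in one year (2018, GBP) are counted, with no disease-progression dynamics
— the snapshot, not a Markov cohort, is the object of study. Undiagnosed
patients incur no costs by assumption: a diagnosis is what triggers
management, monitoring and the associated resource use. Comorbidity costs
are out of scope.

All rates are carried internally as fractions and all money as 2018 GBP;
percent and rounded displays exist only at the reporting boundary
(`reporting.ReportSpec`). This removes the classic percent/fraction bug
class by construction.

## State space and populations

Nine states: F0, F1, F2, F3, F4 CC, DCC, HCC, LT, DEATH, in fixed order.
Adults are partitioned into 5-year age bands 18–19, 20–24, …, 90+ by sex.
Age-threshold rules (transplant age cap 70, working age below the
retirement age 66) compare the band's *lower bound*; annuity horizons use
the band *midpoint* as the expected age. Both conventions are deterministic
and applied uniformly.

The prevalent table is the product form
`total × stage share × age share|stage × sex share`, so every marginal
reproduces its input distribution exactly. Decedents are carried as a tenth
population column with diagnosis probability 1, which keeps the published
population-table layout reproducible and feeds the mortality-linked cost
heads (forgone income, funerals, YLL).

Attributable mortality is stored *per prevalent case*
(`0.00023 / 0.041 ≈ 0.0056` deaths per case-year, back-derived from the
headline 0.023%-of-adults figure under the 4.1% prevalence rate) so that
deaths — and with them YLL, forgone income and funeral costs — scale with
the prevalence scenario, as the published scenario results do. The CVD
share of attributable deaths is 60%; the remainder is liver-related.

## Costing conventions

**Health system.** `total[s,c] = unit[s,new,c]·N_new[s] + unit[s,mon,c]·N_mon[s]`
for F0–HCC. Transplant-year accounting: in-year transplants incur the
initial-year cost, the monitored post-transplant stock the subsequent-year
cost (booked under secondary care). The medical-research pool is a fixed
total spread uniformly per diagnosed person — totals are scenario-invariant
while per-person values fall as the diagnosed population grows. Payer
totals are fractions of the grand total (0.79/0.15/0.06). Diagnostics
accrue to both patient statuses; the newly-diagnosed year instead carries a
2.2× cost ratio in the synthetic schedule, representing the diagnostic
work-up.

**Productivity (human capital).** The participation reduction is read as a
percentage-point drop in the employment rate among ESLD patients, so each
induced exit is valued at a full year of average weekly earnings (AWE × 52)
without a second employment-rate factor. Absenteeism/presenteeism weeks
apply to employed working-age patients (hence AWE × employment rate); the
survey informing the week losses covered F0–F4 CC only, so F4 CC values are
extrapolated to DCC/HCC/LT when unset. Forgone income per decedent is the
discounted annuity of expected annual earnings from the band midpoint to
retirement. Bearer attribution: government recoups the effective-tax share
(default 0.22) of all lost earnings; employers bear after-tax on-the-job
losses (sick-pay absenteeism, presenteeism) plus replacement frictions;
individuals bear the after-tax participation and forgone-income losses.
This is the standard convention and reproduces the published
employers > individuals > government ordering.

**Other costs.** Care applies to ESLD stages only, evenly across age and
sex. Informal care uses the opportunity-cost method (hours × carer wage).
Welfare transfers (PIP, ESA as claim-shares of diagnosed ESLD; CA from the
care-receiving population) are *excluded* from economic-cost totals —
transfers are redistribution, not resource use — but enter the deadweight
loss base together with forgone tax and (by default, flag-controlled)
government health expenditure, at a DWL rate of 0.20. Funeral costs count
only the bring-forward differential `unit × (1 − (1+r)^{−L})`, zero at
r = 0 or L = 0, with L the life-table remaining expectancy at the death
age — the same horizon the YLL machinery uses.

**Burden.** YLD weights each diagnosed person-year by the stage disability
weight (DCC 0.178, HCC 0.296; F0–F4 CC and LT 0 — LT's zero weight is a
consistency choice with the published wellbeing tables and is
configurable). YLL uses the discrete annual annuity
`(1 − (1+r)^{−L})/r`, r = 3%, no age-weighting; its r→0 limit is L.
DALY = YLD + YLL; wellbeing = DALY × VSLY (£60,000). Per-person wellbeing
in living stages is therefore exactly weight × VSLY, scenario-invariant.

## Parameters that matter

| Parameter | Default | Units | Why it matters |
|---|---|---|---|
| prevalence rate | 0.022 / 0.041 | fraction of adults | scales every population and most costs linearly |
| diagnosis probability | 0.02/0.02/0.165/0.5825/1… | per stage | gates who is costed; top driver after prevalence |
| mortality per prevalent case | 0.00023/0.041 | deaths per case-year | drives YLL, forgone income, funerals |
| discount rate | 0.03 | per year | YLL, forgone income, funeral differential |
| VSLY | 60,000 | GBP/DALY | linear in all wellbeing outputs |
| effective tax rate | 0.22 | fraction | government bearer share; DWL base |
| DWL rate | 0.20 | fraction | efficiency loss per pound of distortion base |
| retirement age | 66 | years | working-age window and annuity horizons |

## The synthetic generator

The analysis's input tables are not in print, so `coiburden.synthetic`
builds smooth, parsimonious stand-ins labelled illustrative: a pyramid flat
to the early 50s then exponentially tapering; stage mass declining
F0 → HCC (0.35, 0.27, 0.18, 0.115, 0.074, 0.009, 0.0007, 0.0008) with
Gaussian age humps shifting older in later stages; a quadratic age-humped
earnings curve (peak ~£625/week at 47) with a humped employment profile;
a life table declining linearly from 65 remaining years at 18; an
illustrative unit-cost schedule whose stage levels were chosen so the
whole-model per-person health cost lands near the published range. The
published scalars are embedded verbatim. A seeded ±2% jitter on the table
shapes makes the generator seed-sensitive while keeping bundles bit-exactly
reproducible per seed.

`calibrate_uk_like` alternates two linear knobs — the adult-population
total (which scales DALYs exactly) and the joint earnings/health unit-cost
scale (which scales most economic components) — against the published
aggregate anchors (economic £4.215bn, 174,564 DALYs for the higher/base
run), converging in two iterations to ≤0.2% error; achieved values are
recorded in the bundle metadata. Problem sizes throughout the test suite
are deliberate: full-scale bundles (~10⁶ prevalent cases, vectorised) for
calibration checks, and a ~120,000-adult bundle (~1,200 diagnosed cases)
wherever a cell-by-cell enumeration oracle is compared at 10⁻⁹ relative
precision.

What passing tests show — and do not. The generator emulates the *shape*
of UK inputs, not their values: agreement with the published aggregate
anchors is a calibration outcome, not a validation of the stand-in tables,
and per-person figures that depend on the unpublished life table and
earnings levels (e.g. per-person health cost, discounted life-years per
death) sit above the published figures. The exact identities (per-person
wellbeing = weight × VSLY; conservation across components, payers and
bearers; pool invariance) hold regardless of inputs and are what the test
suite pins down.

## Numerical choices

- Discounting is a discrete annual annuity throughout; fractional horizons
  are allowed (band midpoints), negative horizons clamp to zero.
- Sensitivity perturbs parameters multiplicatively with clipping to their
  domain: probabilities clip to [0, 1] (a probability of 1 stays 1 at
  +10%), week losses to [0, 52], rates strictly below 1. Tornado ties break
  on parameter name, so orderings are reproducible.
- Degenerate inputs: zero diagnosed population with a positive research
  pool is an error (nothing to spread it over); all prevalence mass at or
  above the transplant age cap is an error (renormalisation undefined);
  per-person values report 0 for unpopulated stages.
- Config round-trips are bit-exact on the serialised decimal
  representation; CSV side-files are read with round-trip float parsing.

## Known limitations

- No disease progression, incidence dynamics or projections beyond the
  base year; incidence enters only as the newly-diagnosed split fraction.
- The printed productivity component shares sum to 120% in the source
  material; component shares here are treated as qualitative calibration
  only (ordering, not values).
- Lower/higher diagnosis-probability scenarios have no published values
  and must be user-supplied; the generator ships the base profile only.
- The death-stage per-person wellbeing depends on the unpublished life
  table and is reported as computed, not matched.
- Welfare eligibility is not modelled; claims are parameterised shares.
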