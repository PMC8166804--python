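# coiburden

A prevalence-approach cost-of-illness and burden-of-disease model for
**diagnosed non-alcoholic steatohepatitis (NASH)** in the UK adult
population, 2018 base year.

NASH — the progressive, inflammatory subset of non-alcoholic fatty liver
disease — moves through nine states: fibrosis grades F0–F3, compensated
cirrhosis (F4 CC), decompensated cirrhosis (DCC), hepatocellular carcinoma
(HCC), liver transplant (LT), and death within the base year. Early-stage
disease is largely asymptomatic, so most prevalent cases are undiagnosed;
only diagnosed patients incur costs in the model. The package is aimed at
health economists and modellers who want a tested, reusable implementation
of this accounting: given a parameter bundle it produces stage-resolved
economic costs, DALYs and monetised wellbeing costs, with scenario and
one-way (tornado) sensitivity analysis.

## The model

For a single base year, prevalence rates (lower 2.2% / higher 4.1% of
adults) are spread over stage, age band and sex; a per-stage probability of
diagnosis (2.0%, 2.0%, 16.5%, 58.25% for F0–F3; 100% from F4 CC onwards)
yields the diagnosed population, split by per-stage incidence fractions
into newly-diagnosed and in-monitoring patients. On top of this population
state the model computes:

- **Health-system costs** — per-person annual unit costs by stage, patient
  status and category (primary care, secondary care, diagnostics,
  pharmaceuticals); transplant-year accounting with initial- and
  subsequent-year costs; a pooled medical-research spend; a payer split
  (government 79% / individuals and families 15% / other 6%).
- **Productivity costs** (human-capital approach) — reduced workforce
  participation in end-stage liver disease, absenteeism and presenteeism
  weeks valued at expected earnings `AWE × employment rate`, forgone income
  of decedents as a discounted annuity to retirement, and search/hiring/
  training frictions; decomposed over government (lost tax), employers and
  individuals.
- **Other economic costs** — formal and informal care (opportunity-cost
  method), welfare transfers (PIP, ESA, Carer's Allowance; face values
  excluded from cost totals), deadweight loss
  `DWL = rate × (forgone tax + transfers + government health spend)`, and
  funeral costs brought forward, `unit × (1 − (1+r)^{−L})`.
- **Burden and wellbeing** — `YLD = person-years × disability weight`
  (DCC 0.178, HCC 0.296), `YLL = deaths × (1 − (1+r)^{−L})/r` with r = 3%
  and L the remaining life expectancy, `DALY = YLD + YLL`, monetised at a
  VSLY of £60,000.

The published input *tables* (ONS demography and earnings, NHS reference
costs, PSSRU/DWP values, the life table) are not available in print, so the
package ships a synthetic UK-like generator whose scale knobs are
calibrated to the published aggregate anchors; all published *scalars*
above are embedded verbatim.

## Worked example

```python
from coiburden import CostOfIllnessModel

model = CostOfIllnessModel.from_synthetic(seed=42)   # calibrated bundle
results = model.fit(prevalence="higher", diagnosis="base")
print(results.summary())
```

```
Cost of illness: diagnosed NASH (prevalence approach)
============================================================
Scenario:            prevalence=higher, diagnosis=base
Prevalent cases:     1,690,496
Diagnosed cases:     335,002 (19.8% of prevalent)
Attributable deaths: 9,430
------------------------------------------------------------
Economic costs (GBP million)
  health_system               323.7
  productivity              3,622.6
  carer                        21.5
  other                        20.6
  deadweight_loss             222.1
  total                     4,210.6
------------------------------------------------------------
DALYs total:         174,564 (YLD 3,041 + YLL 171,523)
Wellbeing total:     GBP 10,473.8 million
Per diagnosed person: economic GBP 12,569, wellbeing GBP 31,265
============================================================
```

Reading this: of ~1.69 million synthetic prevalent cases under the higher
prevalence scenario, 19.8% carry a diagnosis and so incur costs. The
economic total (£4.21bn) is dominated by productivity losses; the burden
side is dominated by years of life lost to the ~9,430 attributable deaths.
Per-person wellbeing costs for DCC and HCC are exactly
`0.178 × £60,000 = £10,680` and `0.296 × £60,000 = £17,760` in every
scenario.

The counterfactual and tornado analyses hang off the same objects:

```python
cf = model.counterfactual(prevalence="higher")   # 100% diagnosis
cf.economic_total / results.economic_total       # ~3.0
model.sensitivity(["prevalence_rate", "weekly_earnings", "vsly"])
```

A CLI mirrors this surface: `coiburden synth --seed 42 --out bundle/`,
`coiburden run --config bundle/config.yaml --prevalence higher --out out/`,
`coiburden counterfactual --config ...`, `coiburden tornado --config ...`.

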