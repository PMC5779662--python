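# hivcea

Cost-utility and value-of-information analysis of **directly administered
antiretroviral therapy (DAART)** versus **self-administered ART (SAART)**
for people living with HIV at high risk of non-adherence in sub-Saharan
Africa.

Adherence-support programmes that observe ART dosing are expensive; whether
they are worth funding from a health-system perspective depends on how much
extra health they buy per dollar. `hivcea` implements a lifetime Markov
cohort model of HIV disease progression and wraps it with the full
health-economic toolkit — deterministic and probabilistic sensitivity
analysis, cost-effectiveness acceptability curves, and expected value of
perfect (and partial perfect) information — for analysts who want to
reproduce, stress-test or extend the published decision analysis.

## The model

Patients occupy one of five health states defined by CD4 count: state I
(CD4 > 500), II (350–500), III (200–350), IV (≤ 200, AIDS) and death
(absorbing). Each one-year cycle the cohort is multiplied by a transition
matrix **P**; everyone starts in state I at age 20 and is followed to
age 100.

- **Treatment effect.** DAART modifies the SAART matrix through a relative
  risk RR (base 1.29, 95% CI 1.12–1.48): transitions to better states are
  multiplied by RR, transitions to worse alive states by 1/RR, and the stay
  probability takes the residual so rows remain stochastic. Per-state HIV
  death risks are strategy-invariant by default (DAART still averts deaths
  by holding patients in low-mortality states); the
  `rr_adjusts_death` switch applies 1/RR to death transitions as well.
- **Background mortality.** Age-specific all-cause mortality is overlaid as
  a competing risk: `p_death = 1 − (1 − p_bg)(1 − p_death_HIV)`, with all
  other entries scaled by `(1 − p_bg)`.
- **Payoffs.** Each state carries an annual cost (US$2014) and a utility
  weight; DAART adds US$964/year in every alive state. Cycle payoffs use
  trapezoidal half-cycle correction and are discounted at 3%:

  `V = Σ_k (1+r)^−k · ½(x_{k−1} + x_k)·v`

  where `x_k` is the occupancy vector and `v` the payoff vector. The
  incremental cost-effectiveness ratio is `ICER = ΔC/ΔE` (US$/QALY),
  compared against the WHO-CHOICE willingness-to-pay threshold of
  US$5,086/QALY.
- **Uncertainty.** PSA draws transition rows from Dirichlet distributions,
  utilities from Beta, costs from Gamma (method of moments against the
  published ranges read as 95% intervals) and RR from a lognormal. Decision
  uncertainty is summarised by the CEAC (probability that DAART has the
  higher net monetary benefit `λ·E − C`) and by EVPI/EVPPI scaled to the
  ~1.6 million patients per year to whom the decision applies.

## Worked example

```python
from hivcea import CostUtilityModel

model = CostUtilityModel.from_paper()   # bundled published input set
results = model.fit()
print(results.summary())
```

```
Cost-utility analysis: DAART vs self-administered ART
=============================================================
Strategy       Cost (US$)       QALYs    Incr. costIncr. QALYs
-------------------------------------------------------------
SAART               6,113        9.77             -         -
DAART              17,322       10.84        11,209      1.08
-------------------------------------------------------------
ICER: 10,418 US$/QALY
WTP threshold: 5,086 US$/QALY -> DAART is not cost-effective
(start age 20, horizon to age 100, discount 3%, half-cycle correction on)
```

DAART buys 1.08 extra quality-adjusted life years per patient at an extra
lifetime cost of US$11,209 — about US$10,400 per QALY, double the
WHO-CHOICE threshold. How sure can we be, and what would resolve the
uncertainty?

```python
psa = model.psa(n=10_000, seed=20140123)
print(psa.ceac([5086.0, 9000.0, 18000.0]).probability_alt_cost_effective)
# [0.0083 0.3161 0.9048]

print(round(model.threshold().threshold_price_closed_form, 2))
# 500.06

from hivcea.voi import EffectivePopulation, evpi_per_patient, population_evpi
pop = EffectivePopulation()              # 24.4M x 37% on ART x 17.4% high-risk
evpi = evpi_per_patient(psa, 5086.0)     # 7.19 US$/patient
print(round(population_evpi(evpi, pop) / 1e6, 1))
# 299.4
```

At the WHO-CHOICE threshold DAART is cost-effective in under 1% of draws;
it would need a ~50% break-even price cut (to below US$500/year) to change
the decision. Even so, perfect information would be worth roughly
US$300 million to the region over 50 years — mostly attributable to the
uncertain effectiveness RR (`results.evppi(psa, "effectiveness", 9000.0)`).

A `hivcea` console command exposes the same analyses
(`hivcea base-case`, `structural`, `tornado`, `threshold`, `psa`, `voi`,
`synth`, `run-all`), each writing CSV outputs plus a run manifest.

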