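# Methods

## Model structure

The decision problem compares two ways of delivering antiretroviral therapy
to HIV-positive adults at high risk of non-adherence: self-administered ART
(SAART, the comparator) and directly administered ART (DAART), in which
dosing is observed by a provider at an annual programme cost. Health is
described by five states keyed to CD4 count — I (> 500), II (350–500),
III (200–350), IV (≤ 200/AIDS) — plus absorbing death. The cohort is
homogeneous, starts in state I at age 20, and is propagated in one-year
cycles to age 100 (by which point under the default inputs the surviving
fraction is far below 0.1%, so results are insensitive to the exact
terminal age; the horizon is configurable).

Transition probabilities for the SAART arm come from a published follow-up
cohort and are supplied as the sixteen off-diagonal annual probabilities;
the stay probability of each row is the residual mass, the only completion
consistent with a row-stochastic matrix. Improvement ("reverse
progression") transitions are allowed; a structural scenario removes them,
reassigning the removed mass to the stay probability.

## Treatment effect

DAART's effectiveness enters as a relative risk RR (base 1.29, 95% CI
1.12–1.48) applied to the SAART matrix each cycle: transitions to strictly
better states are multiplied by RR and transitions to strictly worse
*alive* states by 1/RR, with the stay probability recomputed as the
residual. An adjustment that would push a row out of the probability
simplex raises an explicit infeasibility error rather than renormalising
silently.

Whether the per-state HIV **death** transitions should also be divided by
RR is genuinely open: death is "a worse state", but the RR is estimated
from virologic/adherence outcomes that speak to movement between CD4
strata, and per-state case fatality conditional on stratum is plausibly
delivery-mode-invariant. The package's default leaves death risks
unadjusted (`rr_adjusts_death = False`): a survival benefit still arises
mechanically because DAART holds more of the cohort in states with low HIV
mortality (0.022/year in state I vs 0.106/year in state IV). The
alternative reading is one switch away. The default is also the variant
whose incremental QALY gain (≈1.1) and decision-uncertainty profile agree
with the published base-case table, acceptability curve and break-even
price; under the death-adjusted variant the QALY gain roughly doubles and
the intervention appears far more favourable.

## Background mortality

Age-specific all-cause (non-HIV) mortality is a step function of age
(tabulated at 5-year intervals, ages 10–80; the last value is held beyond
80). It is overlaid on the RR-adjusted matrix each cycle as a competing
risk: the death entry becomes `1 − (1 − p_bg)(1 − p_HIV)` and every alive
entry, stay included, is scaled by `(1 − p_bg)`. An additive overlay can
exceed 1; the multiplicative-survival form cannot. Order of composition is
RR first, mortality second: the RR describes HIV progression, background
mortality is strategy-independent.

## Payoffs, discounting, conventions

Each alive state accrues an annual HIV-care cost (US$2014) and a utility
weight; DAART adds its annual programme cost (US$964 base) in every alive
state-cycle, reflecting a continuous adherence-support service. Cycle
payoffs use the trapezoidal half-cycle correction — cycle k weights the
average of the boundary occupancies, `½(x_{k−1} + x_k)` — and are
discounted at 3%/year for both costs and QALYs.

Two timing conventions are implemented because source publications rarely
state theirs. The default, `discount_from = "second"`, discounts cycle k by
`(1+r)^−k` (the end-of-cycle spreadsheet convention); `"first"` leaves the
first cycle undiscounted, `(1+r)^−(k−1)`. The two differ by a uniform
factor 1/(1+r) on each arm's totals, so the ICER is invariant to the
choice; strategy-level costs/QALYs shift by ~3%.
`convention_sensitivity()` reports the base case across the
discount-timing × half-cycle × horizon grid so users can see exactly how
much rides on these conventions (on the default inputs: nothing
decision-relevant).

## Sensitivity and probabilistic analysis

*One-way:* all 26 inputs (16 transitions, 4 state costs, 4 utilities, the
DAART price, RR, the discount rate) are varied one at a time by ±25%, or to
published scenario endpoints for the DAART price (723–1205) and RR (1.12
worst case, 1.49 best case — the published one-way text uses 1.49 where the
input table caps the CI at 1.48; both are kept, the table value in the
fixture and 1.49 as the one-way override). Utilities cap at 1; transition
perturbations are absorbed by the stay probability and truncated at
feasibility (flagged) if the stay mass would go negative. *Threshold:* the
incremental cost is affine in the DAART price with slope equal to
discounted alive person-time, so the break-even price has a closed form
that the grid evaluation is checked against.

*PSA:* 10,000 draws by default, seeded (default seed 20140123, always
logged). Families follow standard practice for each parameter type:

- **Dirichlet** per alive transition row (rows sum to 1 by construction).
  Concentrations are the base row times an effective sample size n_eff. A
  Dirichlet row has a single free concentration scale and cannot match four
  independent ranges, so n_eff is fitted to the row's most uncertain
  published entry — the one with the largest implied sd (range width/3.92)
  — and the other entries' spreads are then implied. A row with only two
  outcomes degrades to a Beta on its single exit probability.
- **Beta** for utilities and **Gamma** for costs, by method of moments with
  mean = base value and sd = range width/3.92. Published ranges are read as
  95% intervals throughout; nothing in the source states what they are, and
  this uniform reading is the conventional one. The published cost ranges
  for states I/II are inconsistent with their base values (likely a copy
  error); sampling keeps the base value as the mean and uses the printed
  width for spread, preserving the printed base case while still
  quantifying uncertainty. Zero-width ranges degenerate to point masses.
- **Lognormal** for RR with log-mean ln(1.29) — the meta-analytic point
  estimate of a ratio is a median on the log scale — and log-sd
  (ln 1.48 − ln 1.12)/3.92.

Both arms share each draw's progression matrix, costs and utilities; only
the sampled RR and DAART price differ between arms (common random numbers,
minimising the variance of the increments). Draws failing validation are
rejected and redrawn with a logged count (in practice the families make
rejection impossible on the default inputs). The per-draw cohort runs are
vectorised across draws; tests pin the vectorised path to the scalar
engine draw by draw.

## Value of information

Net monetary benefit is `λ·E − C`; dividing by λ gives the health-unit
version and changes no arg-max, and the monetary form matches
dollar-denominated reporting. Per-patient EVPI is
`E_θ[max_s NMB_s(θ)] − max_s E_θ[NMB_s(θ)]` over the PSA draws. Population
EVPI multiplies by the effective population: 24.4 million people living
with HIV × 37% on ART × 17.4% at high risk ≈ 1.6 million patients/year,
summed over a 50-year treatment lifetime at 3%
(`Σ_{t=0}^{49} annual/(1.03)^t`; the source states no formula and this is
the standard annuity construction).

EVPPI uses a single-loop linear metamodel: each strategy's NMB is
regressed (OLS) on the sampled parameters of one group — effectiveness
{RR}, cost {DAART price}, utility {4 utilities}, probabilities {16
transitions}, plus a separate `treatment_cost` group for the state care
costs — and fitted values stand in for conditional expectations. The
estimate is clipped to [0, EVPI] with the raw value retained. A two-loop
nested Monte-Carlo estimator implemented in the test suite bounds the
metamodel's approximation error on a model that is exactly linear.

## Synthetic data

The generator produces random valid input sets with the same statistical
shape as the published one: Dirichlet-sampled rows with diagonal stay mass
in [0.4, 0.8], utilities decreasing and costs increasing with severity
(both orderings can be disabled for adversarial tests), RR in [1.0, 1.6],
an age-increasing mortality table, and ±25% auto-generated ranges. These
emulate the *structure* the analysis assumes, not any real population:
passing on synthetic sets demonstrates that the machinery (engine,
analyses, distribution fits) is correct for arbitrary valid inputs, not
that the published parameter values are right. Degenerate cases (identity
dynamics, certain death, RR = 1, zero costs/utilities/discount) have exact
closed-form outcomes used as oracles.

## Verification

- The cohort engine is cross-checked against an independent individual-level
  microsimulation pushed through the same per-cycle matrices (3-standard-
  error agreement on the bundled set and 20 synthetic sets).
- Row-stochasticity is fuzz-tested through every matrix transform;
  serialization round-trips; sampled means are checked against each
  family's analytic mean.
- Replication tests assert the published base case, scenario ICERs, CEAC
  points and population EVPI at documented tolerances (±20% for
  deterministic quantities given the unstated conventions; ±5 percentage
  points for CEAC values; a factor of two for population EVPI).

## Known limitations

- The published results are not fully internally consistent at the stated
  3% discount rate: with the package's default conventions the base-case
  costs/QALYs, the acceptability curve at the WHO-CHOICE threshold and the
  US$500 break-even price reproduce well, while the printed base-case and
  structural ICERs and the worst-case-RR one-way ICER do not fall within
  ±20% under any implemented convention combination. The corresponding
  replication tests are left failing by design; the convention-sensitivity
  table documents the spread.
- No HIV transmission dynamics, no individual-level heterogeneity or
  adherence-state substructure, no currency conversion (all money is
  US$2014 as supplied), and no EVSI/research-portfolio analysis.
- The printed partial-EVPI dollar values in the source are reported on an
  unstated scale and are not replication targets; the package reports its
  own per-patient and population EVPPI.
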