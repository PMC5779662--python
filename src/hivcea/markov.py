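"""Cohort engine: strategy matrices, cohort traces and discounted outcomes.

Each one-year cycle an alive patient can stay, move to a better or worse CD4
state, or die.  DAART modifies the SAART transition matrix through its
effectiveness relative risk RR: transitions to strictly better states are
multiplied by RR, transitions to strictly worse states (death included) by
1/RR, and the stay probability takes the residual.  Age-specific background
(non-HIV) mortality is then overlaid as a competing risk.  Discounted costs
and QALYs are accumulated with a trapezoidal half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InfeasibleAdjustmentError, OutOfRangeError
from .parameters import (
    ALIVE_STATES,
    N_STATES,
    HealthState,
    ModelParameters,
    MortalityTable,
    TransitionMatrix,
)

__all__ = [
    "StrategySpec",
    "CohortTrace",
    "EconResult",
    "apply_relative_risk",
    "background_mortality_at",
    "combine_background_mortality",
    "cycle_matrix",
    "run_cohort",
    "accumulate_outcomes",
    "evaluate_strategy",
    "saart_strategy",
    "daart_strategy",
]

_DEATH = int(HealthState.DEATH)


@dataclass(frozen=True)
class StrategySpec:
    """A treatment strategy: an added annual cost and a progression RR."""

    name: str
    intervention_annual_cost: float = 0.0
    relative_risk: float = 1.0

    def __post_init__(self):
        if self.intervention_annual_cost < 0:
            raise OutOfRangeError(f"{self.name}.intervention_annual_cost", "must be >= 0")
        if self.relative_risk <= 0:
            raise OutOfRangeError(f"{self.name}.relative_risk", "must be > 0")


def saart_strategy() -> StrategySpec:
    return StrategySpec("SAART", 0.0, 1.0)


def daart_strategy(params: ModelParameters) -> StrategySpec:
    return StrategySpec(
        "DAART", params.daart_annual_cost, params.treatment_effect.relative_risk
    )


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions at cycle boundaries t = 0..T (rows)."""

    occupancy: np.ndarray
    start_age: float

    def __post_init__(self):
        occ = np.asarray(self.occupancy, float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise OutOfRangeError("trace", f"expected (T+1)x{N_STATES}, got {occ.shape}")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def death_column(self) -> np.ndarray:
        return self.occupancy[:, _DEATH]


@dataclass(frozen=True)
class EconResult:
    """Total discounted cost (US$2014) and QALYs for one strategy."""

    strategy: str
    discounted_cost: float
    discounted_qalys: float
    trace: CohortTrace


def apply_relative_risk(
    matrix: TransitionMatrix, rr: float, adjust_death: bool = True
) -> TransitionMatrix:
    """RR-adjust a transition matrix (better x RR, worse x 1/RR, stay residual).

    ``adjust_death=True`` treats the per-state HIV death transition as a
    "worse state" and divides it by RR too; with ``False`` only transitions
    among the alive CD4 strata are adjusted and death risks stay put.
    """
    if rr <= 0:
        raise OutOfRangeError("rr", "relative risk must be > 0")
    p = matrix.probabilities.copy()
    worse_end = N_STATES if adjust_death else _DEATH
    for origin in ALIVE_STATES:
        o = int(origin)
        row = p[o].copy()
        row[:o] *= rr                 # transitions to strictly better states
        row[o + 1 : worse_end] /= rr  # transitions to strictly worse states
        off_sum = row.sum() - row[o]
        if np.any(row > 1 + 1e-12) or off_sum > 1 + 1e-9:
            raise InfeasibleAdjustmentError(
                f"rr={rr} makes row {origin.name} non-stochastic "
                f"(off-diagonal sum {off_sum:.6f})"
            )
        row[o] = 1.0 - off_sum
        p[o] = row
    return TransitionMatrix(p)


def background_mortality_at(mortality: MortalityTable, age: float) -> float:
    """Step-function lookup of background mortality; holds the last value."""
    ages = mortality.ages
    if age < ages[0]:
        raise OutOfRangeError("age", f"{age} below first tabulated age {ages[0]}")
    idx = int(np.searchsorted(ages, age, side="right")) - 1
    return float(mortality.probabilities[idx])


def combine_background_mortality(
    matrix: TransitionMatrix, p_bg: float
) -> TransitionMatrix:
    """Overlay background mortality as a competing risk.

    For each alive row the new death probability is
    ``1 - (1 - p_bg)(1 - p_death_hiv)`` and every non-death entry (stay
    included) is scaled by ``(1 - p_bg)``, keeping the row stochastic.
    """
    if not 0 <= p_bg <= 1:
        raise OutOfRangeError("p_bg", "background mortality must lie in [0, 1]")
    p = matrix.probabilities.copy()
    alive = [int(s) for s in ALIVE_STATES]
    p[np.ix_(alive, alive)] *= 1.0 - p_bg
    for o in alive:
        p[o, _DEATH] = 1.0 - (1.0 - p_bg) * (1.0 - matrix.probabilities[o, _DEATH])
    return TransitionMatrix(p)


def cycle_matrix(
    params: ModelParameters, strategy: StrategySpec, age: float
) -> TransitionMatrix:
    """Per-cycle matrix: RR adjustment first, background mortality second."""
    m = apply_relative_risk(
        params.saart_matrix, strategy.relative_risk, params.econ.rr_adjusts_death
    )
    return combine_background_mortality(
        m, background_mortality_at(params.mortality, age)
    )


def run_cohort(params: ModelParameters, strategy: StrategySpec) -> CohortTrace:
    """Propagate the cohort from start_age to max_age, all starting in State I."""
    econ = params.econ
    n_cycles = int(round(econ.max_age - econ.start_age))
    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[0, HealthState.STATE_I] = 1.0
    base = apply_relative_risk(
        params.saart_matrix, strategy.relative_risk, econ.rr_adjusts_death
    )
    for t in range(n_cycles):
        p_bg = background_mortality_at(params.mortality, econ.start_age + t)
        m = combine_background_mortality(base, p_bg)
        occ[t + 1] = occ[t] @ m.probabilities
    return CohortTrace(occ, econ.start_age)


def _discount_factors(rate: float, n_cycles: int, discount_from: str) -> np.ndarray:
    k = np.arange(1, n_cycles + 1, dtype=float)
    exponent = k - 1.0 if discount_from == "first" else k
    return (1.0 + rate) ** -exponent


def accumulate_outcomes(
    trace: CohortTrace, params: ModelParameters, strategy: StrategySpec
) -> EconResult:
    """Discounted lifetime cost and QALYs from a cohort trace.

    With half-cycle correction, cycle k's payoff weights the trapezoidal
    occupancy ``(occ[k-1] + occ[k]) / 2``; without, the start-of-cycle
    occupancy ``occ[k-1]``.  Cycle k is discounted per the configured timing
    convention (first cycle undiscounted by default).
    """
    econ = params.econ
    occ = trace.occupancy
    n = trace.n_cycles
    mid = 0.5 * (occ[:-1] + occ[1:]) if econ.half_cycle_correction else occ[:-1]

    cost_per_state = params.state_values.annual_cost.copy()
    cost_per_state[: _DEATH] += strategy.intervention_annual_cost
    cycle_costs = mid @ cost_per_state
    cycle_qalys = mid @ params.state_values.utility

    dfc = _discount_factors(econ.discount_rate_costs, n, econ.discount_from)
    dfq = _discount_factors(econ.discount_rate_qalys, n, econ.discount_from)
    return EconResult(
        strategy=strategy.name,
        discounted_cost=float(cycle_costs @ dfc),
        discounted_qalys=float(cycle_qalys @ dfq),
        trace=trace,
    )


def evaluate_strategy(params: ModelParameters, strategy: StrategySpec) -> EconResult:
    """Run the cohort and accumulate discounted outcomes for one strategy."""
    return accumulate_outcomes(run_cohort(params, strategy), params, strategy)
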