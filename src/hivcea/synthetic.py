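"""Random, valid parameter sets with the structure the analysis assumes.

Generated sets mirror the published model's statistical shape — ordered
severity states with an absorbing death state, diagonal-dominant stochastic
rows, costs increasing and utilities decreasing with severity, RR slightly
above one, an age-increasing background mortality table and range-style
uncertainty intervals — so the engine, deterministic analyses, PSA and VOI
can all be property-tested away from the published fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .parameters import (
    ALIVE_STATES,
    N_STATES,
    EconSettings,
    HealthState,
    ModelParameters,
    MortalityTable,
    ParameterRange,
    StateValues,
    TransitionMatrix,
    TreatmentEffect,
    PARAMETER_NAMES,
    get_value,
)

__all__ = ["SyntheticSpec", "generate", "degenerate_cases"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration for one synthetic parameter set.

    Only the five-state structure (four severity strata plus death) of the
    domain types is supported; ``n_states`` exists to make that contract
    explicit.
    """

    n_states: int = 5
    seed: int = 0
    stay_mass_range: tuple[float, float] = (0.4, 0.8)
    cost_scale: float = 500.0
    utility_ordering: bool = True
    rr_range: tuple[float, float] = (1.0, 1.6)

    def __post_init__(self):
        if self.n_states != N_STATES:
            raise ValueError("only the five-state structure is supported")
        lo, hi = self.stay_mass_range
        if not 0 <= lo <= hi < 1:
            raise ValueError("stay_mass_range must satisfy 0 <= lo <= hi < 1")
        lo, hi = self.rr_range
        if not 0 < lo <= hi:
            raise ValueError("rr_range must be positive and ordered")
        if self.cost_scale <= 0:
            raise ValueError("cost_scale must be > 0")


def _auto_ranges(params: ModelParameters) -> dict[str, ParameterRange]:
    """±25% ranges around base, clipped to natural bounds."""
    ranges = {}
    for name in PARAMETER_NAMES:
        base = get_value(params, name)
        lo, hi = 0.75 * base, 1.25 * base
        if name.startswith(("transition.", "utility.")) or name == "econ.discount_rate":
            hi = min(hi, 1.0)
        ranges[name] = ParameterRange(lo, hi)
    return ranges


def generate(spec: SyntheticSpec) -> ModelParameters:
    """Draw one fully valid parameter set; reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    p = np.zeros((N_STATES, N_STATES))
    p[HealthState.DEATH, HealthState.DEATH] = 1.0
    for origin in ALIVE_STATES:
        o = int(origin)
        stay = rng.uniform(*spec.stay_mass_range)
        exit_mass = 1.0 - stay
        shares = rng.dirichlet(np.ones(N_STATES - 1))
        dests = [d for d in range(N_STATES) if d != o]
        p[o, dests] = exit_mass * shares
        p[o, o] = stay
    matrix = TransitionMatrix(p)

    utilities = np.zeros(N_STATES)
    raw = rng.uniform(0.2, 1.0, size=len(ALIVE_STATES))
    utilities[: len(ALIVE_STATES)] = (
        np.sort(raw)[::-1] if spec.utility_ordering else raw
    )
    costs = np.zeros(N_STATES)
    raw_c = spec.cost_scale * rng.lognormal(0.0, 0.5, size=len(ALIVE_STATES))
    costs[: len(ALIVE_STATES)] = np.sort(raw_c) if spec.utility_ordering else raw_c

    rr = float(rng.uniform(*spec.rr_range))
    daart_cost = float(spec.cost_scale * rng.lognormal(0.5, 0.3))

    ages = np.arange(10, 85, 5, dtype=float)
    increments = rng.uniform(0.0005, 0.01, size=ages.size)
    mort = np.minimum(np.cumsum(increments), 0.95)
    mortality = MortalityTable(ages, mort)

    params = ModelParameters(
        saart_matrix=matrix,
        state_values=StateValues(costs, utilities),
        daart_annual_cost=daart_cost,
        treatment_effect=_effect(rr),
        mortality=mortality,
        econ=EconSettings(),
        ranges={},
    )
    return replace(params, ranges=_auto_ranges(params))


def _effect(rr: float) -> TreatmentEffect:
    return TreatmentEffect(rr, max(rr * 0.85, 1e-6), rr * 1.15)


def degenerate_cases() -> dict[str, ModelParameters]:
    """Edge-case suite with closed-form outcomes.

    ``identity``: no HIV transitions, no background mortality, zero discount
    — the cohort sits in State I forever.  ``certain_death``: every alive
    state dies within one cycle.  ``rr_one``: DAART with RR = 1 (arms differ
    only by price).  ``zero_costs`` / ``zero_utilities`` / ``zero_discount``:
    the respective payoff channel switched off on a generated set.
    """
    base = generate(SyntheticSpec(seed=12345))
    zero_mort = MortalityTable(base.mortality.ages, np.zeros_like(base.mortality.probabilities))
    no_discount = replace(
        base.econ, discount_rate_costs=0.0, discount_rate_qalys=0.0
    )

    identity_matrix = np.eye(N_STATES)
    certain = np.zeros((N_STATES, N_STATES))
    certain[:, HealthState.DEATH] = 1.0

    cases = {
        "identity": replace(
            base,
            saart_matrix=TransitionMatrix(identity_matrix),
            mortality=zero_mort,
            econ=no_discount,
        ),
        "certain_death": replace(
            base,
            saart_matrix=TransitionMatrix(certain),
            mortality=zero_mort,
            econ=no_discount,
        ),
        "rr_one": replace(base, treatment_effect=_effect(1.0)),
        "zero_costs": replace(
            base,
            state_values=StateValues(
                np.zeros(N_STATES), base.state_values.utility
            ),
            daart_annual_cost=0.0,
        ),
        "zero_utilities": replace(
            base,
            state_values=StateValues(
                base.state_values.annual_cost, np.zeros(N_STATES)
            ),
        ),
        "zero_discount": replace(base, econ=no_discount),
    }
    return cases
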