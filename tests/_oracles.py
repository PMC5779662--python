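"""Independent oracles used to cross-check the cohort engine and the VOI
metamodel: an individual-level microsimulation pushed through the same
per-cycle matrices, and a two-loop nested Monte-Carlo EVPPI estimator.
Both recompute outcomes from first principles rather than reusing the
package's accumulation code paths.
"""

from __future__ import annotations

import numpy as np

from hivcea.markov import StrategySpec, cycle_matrix
from hivcea.parameters import HealthState, ModelParameters

_DEATH = int(HealthState.DEATH)


def microsimulate(
    params: ModelParameters,
    strategy: StrategySpec,
    n_patients: int,
    seed: int,
) -> dict:
    """Simulate individual patients and accumulate discounted payoffs.

    Returns means and Monte-Carlo standard errors of per-patient discounted
    cost and QALYs, applying the same trapezoidal half-cycle and discounting
    conventions as the cohort engine but through independent per-patient
    bookkeeping.
    """
    rng = np.random.default_rng(seed)
    econ = params.econ
    T = int(round(econ.max_age - econ.start_age))

    cost_per_state = params.state_values.annual_cost.copy()
    cost_per_state[:_DEATH] += strategy.intervention_annual_cost
    utility = params.state_values.utility

    k = np.arange(1, T + 1, dtype=float)
    expo = k - 1.0 if econ.discount_from == "first" else k
    dfc = (1.0 + econ.discount_rate_costs) ** -expo
    dfq = (1.0 + econ.discount_rate_qalys) ** -expo

    states = np.zeros(n_patients, dtype=np.int64)  # everyone starts in State I
    cost_acc = np.zeros(n_patients)
    qaly_acc = np.zeros(n_patients)
    for t in range(T):
        m = cycle_matrix(params, strategy, econ.start_age + t).probabilities
        cum = np.cumsum(m, axis=1)
        u = rng.random(n_patients)
        new_states = (u[:, None] > cum[states]).sum(axis=1)
        if econ.half_cycle_correction:
            c = 0.5 * (cost_per_state[states] + cost_per_state[new_states])
            q = 0.5 * (utility[states] + utility[new_states])
        else:
            c = cost_per_state[states]
            q = utility[states]
        cost_acc += dfc[t] * c
        qaly_acc += dfq[t] * q
        states = new_states

    return {
        "cost": float(cost_acc.mean()),
        "cost_se": float(cost_acc.std(ddof=1) / np.sqrt(n_patients)),
        "qalys": float(qaly_acc.mean()),
        "qalys_se": float(qaly_acc.std(ddof=1) / np.sqrt(n_patients)),
    }


def nested_mc_evppi(
    a: float,
    b: float,
    c: float,
    n_outer: int,
    n_inner: int,
    seed: int,
) -> tuple[float, float]:
    """Two-loop EVPPI for the linear benchmark NMB_alt = a + b*theta + c*eps.

    The reference strategy has NMB 0; theta is the parameter of interest and
    eps independent residual uncertainty, both standard normal.  Returns the
    nested Monte-Carlo EVPPI estimate and its outer-loop standard error.
    """
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(n_outer)
    inner = np.empty(n_outer)
    for i in range(n_outer):
        eps = rng.standard_normal(n_inner)
        inner[i] = np.mean(a + b * theta[i] + c * eps)
    per_outer = np.maximum(inner, 0.0)  # max over {reference 0, alternative}
    overall_best = max(0.0, float(inner.mean()))
    evppi = float(per_outer.mean()) - overall_best
    se = float(per_outer.std(ddof=1) / np.sqrt(n_outer))
    return evppi, se
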