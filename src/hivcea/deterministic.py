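"""Deterministic analyses: base-case ICER, structural scenario, one-way
sensitivity with tornado ordering, threshold analysis over the DAART price,
and a convention-sensitivity report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import InfeasibleAdjustmentError
from .markov import (
    EconResult,
    StrategySpec,
    daart_strategy,
    evaluate_strategy,
    saart_strategy,
)
from .parameters import (
    ALIVE_STATES,
    ModelParameters,
    ParameterRange,
    TransitionMatrix,
    get_value,
    with_value,
    PARAMETER_NAMES,
)

__all__ = [
    "IcerResult",
    "TornadoEntry",
    "ThresholdResult",
    "compute_icer",
    "base_case",
    "structural_scenario",
    "one_way_sensitivity",
    "paper_one_way_overrides",
    "threshold_analysis",
    "convention_sensitivity",
]


@dataclass(frozen=True)
class IcerResult:
    """Incremental cost-effectiveness of an alternative vs a reference strategy.

    ``icer`` is NaN when incremental QALYs are zero or a dominance flag
    applies; ``dominance`` is one of None, ``"alternative_dominant"``
    (cheaper and more effective), ``"alternative_dominated"`` (dearer and
    less effective) or ``"undefined"`` (zero QALY increment).
    """

    cost_ref: float
    cost_alt: float
    qaly_ref: float
    qaly_alt: float
    incremental_cost: float
    incremental_qalys: float
    icer: float
    dominance: str | None


def compute_icer(reference: EconResult, alternative: EconResult) -> IcerResult:
    """ICER of ``alternative`` vs ``reference`` with dominance handling."""
    dc = alternative.discounted_cost - reference.discounted_cost
    dq = alternative.discounted_qalys - reference.discounted_qalys
    dominance: str | None = None
    if dq == 0:
        icer = math.nan
        dominance = None if dc == 0 else "undefined"
    else:
        icer = dc / dq
        if dc <= 0 and dq > 0:
            dominance = "alternative_dominant"
        elif dc >= 0 and dq < 0:
            dominance = "alternative_dominated"
    return IcerResult(
        cost_ref=reference.discounted_cost,
        cost_alt=alternative.discounted_cost,
        qaly_ref=reference.discounted_qalys,
        qaly_alt=alternative.discounted_qalys,
        incremental_cost=dc,
        incremental_qalys=dq,
        icer=icer,
        dominance=dominance,
    )


def base_case(params: ModelParameters) -> tuple[EconResult, EconResult, IcerResult]:
    """Evaluate both strategies and the DAART-vs-SAART ICER."""
    ref = evaluate_strategy(params, saart_strategy())
    alt = evaluate_strategy(params, daart_strategy(params))
    return ref, alt, compute_icer(ref, alt)


def structural_scenario(
    params: ModelParameters,
) -> tuple[ModelParameters, IcerResult]:
    """No-reverse-progression scenario.

    Every transition to a strictly better state is zeroed, with the removed
    mass added to the stay probability; under DAART the RR then only affects
    worsening transitions.
    """
    p = params.saart_matrix.probabilities.copy()
    for origin in ALIVE_STATES:
        o = int(origin)
        p[o, o] += p[o, :o].sum()
        p[o, :o] = 0.0
    modified = replace(params, saart_matrix=TransitionMatrix(p))
    _, _, icer = base_case(modified)
    return modified, icer


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter_name: str
    low_input: float
    high_input: float
    icer_at_low: float
    icer_at_high: float
    flagged: bool = False  # perturbation truncated at feasibility

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def paper_one_way_overrides() -> dict[str, ParameterRange]:
    """Published one-way scenarios for the two headline parameters.

    The DAART price is varied over its published range and the RR over the
    literature extremes quoted in the one-way analysis (1.12 worst case,
    1.49 best case, the latter exceeding the tabulated interval by 0.01).
    """
    return {
        "cost.daart": ParameterRange(723.0, 1205.0),
        "effect.rr": ParameterRange(1.12, 1.49),
    }


def one_way_sensitivity(
    params: ModelParameters,
    relative_delta: float = 0.25,
    overrides: dict[str, ParameterRange] | None = None,
) -> list[TornadoEntry]:
    """ICER under one-at-a-time perturbation of every model input.

    Each of the 26 named parameters (16 transition probabilities, 4 state
    costs, 4 utilities, DAART cost, RR, discount rate) is set to base x (1 -
    delta) and base x (1 + delta) — or to the endpoints of its override range
    — with everything else at base.  Utilities are capped at 1; transition
    perturbations the stay mass cannot absorb are truncated at feasibility
    and flagged.  Entries are sorted by tornado spread, widest first.
    """
    if not 0 <= relative_delta < 1:
        raise ValueError("relative_delta must lie in [0, 1)")
    overrides = overrides or {}
    entries = []
    names = [n for n in PARAMETER_NAMES]
    for name in names:
        base_val = get_value(params, name)
        if name in overrides:
            lo, hi = overrides[name].low, overrides[name].high
        else:
            lo = base_val * (1 - relative_delta)
            hi = base_val * (1 + relative_delta)
        icers = []
        flagged = False
        inputs = []
        for v in (lo, hi):
            v, was_flagged = _cap(params, name, v)
            flagged |= was_flagged
            inputs.append(v)
            _, _, icer = base_case(with_value(params, name, v))
            icers.append(icer.icer)
        entries.append(
            TornadoEntry(name, inputs[0], inputs[1], icers[0], icers[1], flagged)
        )
    entries.sort(key=lambda e: (-(e.spread if math.isfinite(e.spread) else math.inf)))
    return entries


def _cap(params: ModelParameters, name: str, value: float) -> tuple[float, bool]:
    """Clip a perturbed value to its natural bounds; flag truncations."""
    if name.startswith("utility."):
        return (min(value, 1.0), value > 1.0)
    if name == "econ.discount_rate":
        capped = min(max(value, 0.0), 0.5)
        return capped, capped != value
    if name.startswith("transition."):
        value = max(value, 0.0)
        try:
            with_value(params, name, value)
            return value, False
        except InfeasibleAdjustmentError:
            # shrink to the largest feasible value (stay probability -> 0)
            feasible = None
            lo_v, hi_v = 0.0, value
            for _ in range(60):  # bisection on feasibility
                mid = 0.5 * (lo_v + hi_v)
                try:
                    with_value(params, name, mid)
                    lo_v = mid
                    feasible = mid
                except InfeasibleAdjustmentError:
                    hi_v = mid
            return (feasible if feasible is not None else 0.0), True
    return max(value, 0.0), False


@dataclass(frozen=True)
class ThresholdResult:
    """DAART price threshold analysis at a willingness-to-pay ceiling."""

    price_grid: np.ndarray
    icer_at_price: np.ndarray
    threshold_price_grid: float  # largest grid price with ICER <= wtp (NaN if none)
    threshold_price_closed_form: float
    wtp: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"annual_daart_price": self.price_grid, "icer": self.icer_at_price}
        )


def threshold_analysis(
    params: ModelParameters,
    price_grid: np.ndarray | None = None,
    wtp: float | None = None,
) -> ThresholdResult:
    """ICER as a function of the annual DAART price, and the break-even price.

    Incremental QALYs do not depend on the price and the incremental cost is
    affine in it, so alongside the grid evaluation the exact break-even price
    solves ``wtp = (dC0 + price * A) / dQ`` for the accrual factor ``A``
    (discounted alive person-time under DAART).
    """
    if price_grid is None:
        price_grid = np.arange(0.0, 1500.0 + 1e-9, 10.0)
    price_grid = np.asarray(price_grid, dtype=float)
    if price_grid.size == 0 or np.any(np.diff(price_grid) <= 0):
        raise ValueError("price_grid must be nonempty and strictly increasing")
    wtp = params.econ.wtp_threshold if wtp is None else float(wtp)
    if wtp <= 0:
        raise ValueError("wtp must be > 0")

    ref = evaluate_strategy(params, saart_strategy())
    rr = params.treatment_effect.relative_risk
    alt0 = evaluate_strategy(params, StrategySpec("DAART", 0.0, rr))
    alt1 = evaluate_strategy(params, StrategySpec("DAART", 1.0, rr))
    accrual = alt1.discounted_cost - alt0.discounted_cost  # $ per $1/yr of price
    dc0 = alt0.discounted_cost - ref.discounted_cost
    dq = alt0.discounted_qalys - ref.discounted_qalys

    icers = (dc0 + price_grid * accrual) / dq
    below = price_grid[icers <= wtp]
    grid_answer = float(below[-1]) if below.size else math.nan
    closed_form = (wtp * dq - dc0) / accrual
    return ThresholdResult(price_grid, icers, grid_answer, float(closed_form), wtp)


def convention_sensitivity(params: ModelParameters) -> pd.DataFrame:
    """Base-case results under the documented convention switches.

    Crosses the discount-timing convention, the half-cycle correction and two
    terminal ages, reporting strategy costs/QALYs and the ICER for each
    combination; quantifies how much of the base case hinges on conventions
    the underlying publications rarely state.
    """
    rows = []
    for discount_from in ("first", "second"):
        for hcc in (True, False):
            for max_age in (80, 100):
                p = replace(
                    params,
                    econ=replace(
                        params.econ,
                        discount_from=discount_from,
                        half_cycle_correction=hcc,
                        max_age=max_age,
                    ),
                )
                ref, alt, icer = base_case(p)
                rows.append(
                    {
                        "discount_from": discount_from,
                        "half_cycle_correction": hcc,
                        "max_age": max_age,
                        "cost_saart": ref.discounted_cost,
                        "qalys_saart": ref.discounted_qalys,
                        "cost_daart": alt.discounted_cost,
                        "qalys_daart": alt.discounted_qalys,
                        "icer": icer.icer,
                    }
                )
    return pd.DataFrame(rows)
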