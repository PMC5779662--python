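"""Model inputs for the DAART vs SAART cost-utility analysis.

Everything the decision model consumes is defined, validated and serialized
here: the five-state annual transition matrix (CD4-based states I-IV plus
death), per-state annual treatment costs and utility weights, the annual cost
of directly administered ART (DAART), its effectiveness relative risk versus
self-administered ART (SAART), the age-specific background mortality table,
economic settings (discounting, horizon, willingness-to-pay threshold) and
range-style uncertainty intervals for every varied parameter.

The published input set ships as the package fixture
(``data/paper_2014_fixture.yaml``); :func:`paper_fixture` returns it parsed
and validated.  Only off-diagonal transition probabilities are published; the
diagonal (stay) probability of each row is the residual mass
(:func:`residual_stay_probability`).
"""

from __future__ import annotations

import copy
import enum
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .exceptions import (
    InfeasibleAdjustmentError,
    NonStochasticRowError,
    OutOfRangeError,
    SchemaError,
)

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "TransitionMatrix",
    "StateValues",
    "TreatmentEffect",
    "MortalityTable",
    "EconSettings",
    "ParameterRange",
    "ModelParameters",
    "residual_stay_probability",
    "load_parameters",
    "serialize_parameters",
    "paper_fixture",
    "get_value",
    "with_value",
    "PARAMETER_NAMES",
]

#: Tolerance for row-stochasticity checks.
ROW_TOL = 1e-9

FIXTURE_NAME = "paper_2014_fixture.yaml"


class HealthState(enum.IntEnum):
    """CD4-count based HIV health states; lower index = better health.

    STATE_I: CD4 > 500 (asymptomatic); STATE_II: 350 < CD4 <= 500;
    STATE_III: 200 < CD4 <= 350; STATE_IV: CD4 <= 200 (AIDS); DEATH is
    absorbing.
    """

    STATE_I = 0
    STATE_II = 1
    STATE_III = 2
    STATE_IV = 3
    DEATH = 4


ALIVE_STATES: tuple[HealthState, ...] = (
    HealthState.STATE_I,
    HealthState.STATE_II,
    HealthState.STATE_III,
    HealthState.STATE_IV,
)

N_STATES = len(HealthState)

# YAML keys for states, in index order.
_STATE_KEYS = ("I", "II", "III", "IV", "death")
_STATE_FROM_KEY = {k: HealthState(i) for i, k in enumerate(_STATE_KEYS)}


def residual_stay_probability(off_diagonals) -> float:
    """Stay probability completing a transition row to sum to one.

    ``off_diagonals`` is the collection of per-cycle probabilities of leaving
    the state (to any other state including death).  The published tables list
    only these; the probability of remaining in the state is ``1 - sum``,
    clamped to [0, 1] when within ``ROW_TOL`` of the bounds.
    """
    total = float(np.sum(np.asarray(list(off_diagonals), dtype=float)))
    stay = 1.0 - total
    if stay < -ROW_TOL:
        raise NonStochasticRowError(
            "transition_row", f"off-diagonal probabilities sum to {total}, exceeding 1"
        )
    return float(min(1.0, max(0.0, stay)))


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 annual transition matrix over the health states."""

    probabilities: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "probabilities", np.asarray(self.probabilities, dtype=float)
        )
        self.validate()

    def validate(self) -> None:
        p = self.probabilities
        if p.shape != (N_STATES, N_STATES):
            raise SchemaError("transitions", f"expected 5x5 matrix, got {p.shape}")
        if np.any(p < -ROW_TOL) or np.any(p > 1 + ROW_TOL):
            bad = np.argwhere((p < -ROW_TOL) | (p > 1 + ROW_TOL))[0]
            raise NonStochasticRowError(
                f"transitions[{_STATE_KEYS[bad[0]]}->{_STATE_KEYS[bad[1]]}]",
                f"probability {p[tuple(bad)]} outside [0, 1]",
            )
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9 * max(1, N_STATES)):
            row = int(np.argmax(np.abs(sums - 1.0)))
            raise NonStochasticRowError(
                f"transitions[{_STATE_KEYS[row]}]", f"row sums to {sums[row]}, not 1"
            )
        death = p[HealthState.DEATH]
        expected = np.zeros(N_STATES)
        expected[HealthState.DEATH] = 1.0
        if not np.allclose(death, expected, atol=ROW_TOL):
            raise NonStochasticRowError(
                "transitions[death]", "death must be absorbing: row (0,0,0,0,1)"
            )

    @classmethod
    def from_off_diagonals(
        cls, rows: Mapping[HealthState, Mapping[HealthState, float]]
    ) -> "TransitionMatrix":
        """Build the matrix from off-diagonal probabilities; diagonals are residual."""
        p = np.zeros((N_STATES, N_STATES))
        p[HealthState.DEATH, HealthState.DEATH] = 1.0
        for origin in ALIVE_STATES:
            offs = rows.get(origin, {})
            for dest, prob in offs.items():
                if dest == origin:
                    raise SchemaError(
                        f"transitions[{_STATE_KEYS[origin]}]",
                        "diagonal entries are residual and must not be supplied",
                    )
                p[origin, dest] = float(prob)
            p[origin, origin] = residual_stay_probability(
                [p[origin, d] for d in HealthState if d != origin]
            )
        return cls(p)

    def off_diagonals(self) -> dict[tuple[HealthState, HealthState], float]:
        out = {}
        for origin in ALIVE_STATES:
            for dest in HealthState:
                if dest != origin:
                    out[(origin, dest)] = float(self.probabilities[origin, dest])
        return out

    def __eq__(self, other):
        # serialization stores only off-diagonals; the reloaded stay mass is
        # recomputed as a residual, so compare to addition rounding error
        return isinstance(other, TransitionMatrix) and np.allclose(
            self.probabilities, other.probabilities, rtol=0, atol=1e-12
        )


@dataclass(frozen=True)
class StateValues:
    """Annual cost (US$2014) and utility weight per state; death is (0, 0)."""

    annual_cost: np.ndarray
    utility: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "annual_cost", np.asarray(self.annual_cost, float))
        object.__setattr__(self, "utility", np.asarray(self.utility, float))
        self.validate()

    def validate(self) -> None:
        if self.annual_cost.shape != (N_STATES,) or self.utility.shape != (N_STATES,):
            raise SchemaError("state_values", "need one cost and one utility per state")
        if np.any(self.annual_cost < 0):
            raise OutOfRangeError("costs", "annual costs must be >= 0")
        if np.any(self.utility < 0) or np.any(self.utility > 1):
            raise OutOfRangeError("utilities", "utilities must lie in [0, 1]")
        if self.annual_cost[HealthState.DEATH] != 0:
            raise OutOfRangeError("costs[death]", "death accrues no cost")
        if self.utility[HealthState.DEATH] != 0:
            raise OutOfRangeError("utilities[death]", "death has utility 0")

    def __eq__(self, other):
        return (
            isinstance(other, StateValues)
            and np.array_equal(self.annual_cost, other.annual_cost)
            and np.array_equal(self.utility, other.utility)
        )


@dataclass(frozen=True)
class TreatmentEffect:
    """DAART vs SAART effectiveness relative risk with its 95% interval."""

    relative_risk: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (0 < self.ci_low <= self.relative_risk <= self.ci_high):
            raise OutOfRangeError(
                "effect.rr",
                f"need 0 < ci_low <= rr <= ci_high, got "
                f"({self.ci_low}, {self.relative_risk}, {self.ci_high})",
            )


@dataclass(frozen=True)
class MortalityTable:
    """Age-specific annual background (non-HIV) death probability, step function."""

    ages: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, float))
        object.__setattr__(self, "probabilities", np.asarray(self.probabilities, float))
        self.validate()

    def validate(self) -> None:
        if self.ages.ndim != 1 or self.ages.shape != self.probabilities.shape:
            raise SchemaError("mortality", "ages and probabilities must align")
        if len(self.ages) == 0:
            raise SchemaError("mortality", "table must be nonempty")
        if np.any(np.diff(self.ages) <= 0):
            raise OutOfRangeError("mortality.ages", "ages must be strictly increasing")
        if np.any(self.probabilities < 0) or np.any(self.probabilities > 1):
            raise OutOfRangeError("mortality", "probabilities must lie in [0, 1]")

    def __eq__(self, other):
        return (
            isinstance(other, MortalityTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.probabilities, other.probabilities)
        )


@dataclass(frozen=True)
class EconSettings:
    """Discounting, cohort horizon, willingness-to-pay and convention switches.

    ``discount_from`` selects the discounting timing convention: ``"second"``
    (default) discounts every cycle end-of-cycle (factor ``(1+r)^-k`` for
    cycle k, the textbook spreadsheet convention), ``"first"`` leaves the
    first cycle undiscounted (factor ``(1+r)^-(k-1)``).

    ``rr_adjusts_death`` controls whether the DAART effectiveness relative
    risk also divides the per-state HIV death probabilities.  By default it
    does not: the RR describes movement between the alive CD4 strata, and a
    strategy still averts deaths by holding the cohort in states with lower
    HIV mortality.  Setting it to ``True`` treats death as just another
    "worse state" whose transition is divided by RR.
    """

    discount_rate_costs: float = 0.03
    discount_rate_qalys: float = 0.03
    start_age: int = 20
    max_age: int = 100
    cycle_length: float = 1.0
    half_cycle_correction: bool = True
    wtp_threshold: float = 5086.0
    discount_from: str = "second"
    rr_adjusts_death: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("discount_rate_costs", "discount_rate_qalys"):
            r = getattr(self, name)
            if not (0 <= r <= 0.5):
                raise OutOfRangeError(f"econ.{name}", f"rate {r} outside [0, 0.5]")
        if not self.start_age < self.max_age:
            raise OutOfRangeError("econ.start_age", "start_age must be < max_age")
        if self.cycle_length != 1:
            raise OutOfRangeError("econ.cycle_length", "cycle length is fixed at 1 year")
        if self.wtp_threshold < 0:
            raise OutOfRangeError("econ.wtp_threshold", "must be >= 0")
        if self.discount_from not in ("first", "second"):
            raise SchemaError("econ.discount_from", "must be 'first' or 'second'")


@dataclass(frozen=True, order=True)
class ParameterRange:
    """Uncertainty interval (low, high) in the parameter's own units."""

    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise OutOfRangeError("range", f"low {self.low} > high {self.high}")

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class ModelParameters:
    """Complete input set for the cost-utility model."""

    saart_matrix: TransitionMatrix
    state_values: StateValues
    daart_annual_cost: float
    treatment_effect: TreatmentEffect
    mortality: MortalityTable
    econ: EconSettings = field(default_factory=EconSettings)
    ranges: dict[str, ParameterRange] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        self.saart_matrix.validate()
        self.state_values.validate()
        self.treatment_effect.validate()
        self.mortality.validate()
        self.econ.validate()
        if self.daart_annual_cost < 0:
            raise OutOfRangeError("daart.annual_cost", "must be >= 0")
        for name in self.ranges:
            if name not in PARAMETER_NAMES:
                raise SchemaError(f"ranges.{name}", "unknown parameter name")


# ---------------------------------------------------------------------------
# Dotted parameter vocabulary
# ---------------------------------------------------------------------------

_TRANSITION_NAMES = tuple(
    f"transition.{_STATE_KEYS[o]}.{_STATE_KEYS[d]}"
    for o in ALIVE_STATES
    for d in HealthState
    if d != o
)
_COST_NAMES = tuple(f"cost.state_{_STATE_KEYS[s]}" for s in ALIVE_STATES) + ("cost.daart",)
_UTILITY_NAMES = tuple(f"utility.state_{_STATE_KEYS[s]}" for s in ALIVE_STATES)

#: Every addressable scalar parameter (one-way SA, PSA and EVPPI share this).
PARAMETER_NAMES: tuple[str, ...] = (
    _TRANSITION_NAMES + _COST_NAMES + _UTILITY_NAMES + ("effect.rr", "econ.discount_rate")
)


def _parse_transition_name(name: str) -> tuple[HealthState, HealthState]:
    _, o, d = name.split(".")
    return _STATE_FROM_KEY[o], _STATE_FROM_KEY[d]


def get_value(params: ModelParameters, name: str) -> float:
    """Read a scalar parameter by its dotted name."""
    if name.startswith("transition."):
        o, d = _parse_transition_name(name)
        return float(params.saart_matrix.probabilities[o, d])
    if name == "cost.daart":
        return float(params.daart_annual_cost)
    if name.startswith("cost.state_"):
        s = _STATE_FROM_KEY[name.removeprefix("cost.state_")]
        return float(params.state_values.annual_cost[s])
    if name.startswith("utility.state_"):
        s = _STATE_FROM_KEY[name.removeprefix("utility.state_")]
        return float(params.state_values.utility[s])
    if name == "effect.rr":
        return float(params.treatment_effect.relative_risk)
    if name == "econ.discount_rate":
        return float(params.econ.discount_rate_costs)
    raise SchemaError(name, "unknown parameter name")


def with_value(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one dotted parameter replaced.

    Transition edits keep the row stochastic by letting the stay probability
    absorb the change; an edit the stay mass cannot absorb raises
    :class:`InfeasibleAdjustmentError`.
    """
    if name.startswith("transition."):
        o, d = _parse_transition_name(name)
        p = params.saart_matrix.probabilities.copy()
        p[o, d] = value
        off = [p[o, j] for j in HealthState if j != o]
        try:
            p[o, o] = residual_stay_probability(off)
        except NonStochasticRowError as exc:
            raise InfeasibleAdjustmentError(
                f"{name}={value} leaves no feasible stay probability"
            ) from exc
        return replace(params, saart_matrix=TransitionMatrix(p))
    if name == "cost.daart":
        return replace(params, daart_annual_cost=float(value))
    if name.startswith("cost.state_"):
        s = _STATE_FROM_KEY[name.removeprefix("cost.state_")]
        cost = params.state_values.annual_cost.copy()
        cost[s] = value
        return replace(
            params, state_values=StateValues(cost, params.state_values.utility)
        )
    if name.startswith("utility.state_"):
        s = _STATE_FROM_KEY[name.removeprefix("utility.state_")]
        util = params.state_values.utility.copy()
        util[s] = value
        return replace(
            params, state_values=StateValues(params.state_values.annual_cost, util)
        )
    if name == "effect.rr":
        eff = params.treatment_effect
        return replace(
            params,
            treatment_effect=TreatmentEffect(
                float(value),
                min(eff.ci_low, float(value)),
                max(eff.ci_high, float(value)),
            ),
        )
    if name == "econ.discount_rate":
        return replace(
            params,
            econ=replace(
                params.econ,
                discount_rate_costs=float(value),
                discount_rate_qalys=float(value),
            ),
        )
    raise SchemaError(name, "unknown parameter name")


# ---------------------------------------------------------------------------
# Loading / serialization
# ---------------------------------------------------------------------------

_SECTIONS = {"transitions", "costs", "utilities", "daart", "effect", "mortality", "econ"}


def _as_document(source) -> dict:
    if isinstance(source, Mapping):
        return copy.deepcopy(dict(source))
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    elif isinstance(source, io.IOBase):
        text = source.read()
    else:
        raise SchemaError("source", f"cannot read parameters from {type(source)!r}")
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise SchemaError("source", "document root must be a mapping")
    return dict(doc)


def load_parameters(source) -> ModelParameters:
    """Parse and validate a parameter document (path, YAML text, mapping or file).

    The document schema has sections ``transitions``, ``costs``, ``utilities``,
    ``daart``, ``effect``, ``mortality``, ``econ`` and ``ranges``; see the
    bundled ``paper_2014_fixture.yaml`` for the reference layout.
    """
    doc = _as_document(source)
    missing = _SECTIONS - doc.keys()
    if missing:
        raise SchemaError(",".join(sorted(missing)), "missing required section(s)")

    try:
        rows = {
            _STATE_FROM_KEY[o]: {_STATE_FROM_KEY[d]: float(p) for d, p in offs.items()}
            for o, offs in doc["transitions"].items()
        }
    except (KeyError, AttributeError, TypeError, ValueError) as exc:
        raise SchemaError("transitions", f"malformed transitions section: {exc}") from exc
    matrix = TransitionMatrix.from_off_diagonals(rows)

    try:
        cost = np.zeros(N_STATES)
        util = np.zeros(N_STATES)
        for key, s in _STATE_FROM_KEY.items():
            if s == HealthState.DEATH:
                continue
            cost[s] = float(doc["costs"][key])
            util[s] = float(doc["utilities"][key])
        values = StateValues(cost, util)
        daart_cost = float(doc["daart"]["annual_cost"])
        effect = TreatmentEffect(
            float(doc["effect"]["rr"]),
            float(doc["effect"]["ci_low"]),
            float(doc["effect"]["ci_high"]),
        )
        mort_rows = [(float(a), float(p)) for a, p in doc["mortality"]]
        mortality = MortalityTable(
            [a for a, _ in mort_rows], [p for _, p in mort_rows]
        )
        econ = EconSettings(**{k: v for k, v in doc["econ"].items()})
        ranges = {
            str(k): ParameterRange(float(v[0]), float(v[1]))
            for k, v in doc.get("ranges", {}).items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError("document", f"malformed section: {exc}") from exc

    return ModelParameters(
        saart_matrix=matrix,
        state_values=values,
        daart_annual_cost=daart_cost,
        treatment_effect=effect,
        mortality=mortality,
        econ=econ,
        ranges=ranges,
    )


def serialize_parameters(params: ModelParameters) -> str:
    """Serialize to the same YAML schema ``load_parameters`` reads."""
    doc = {
        "transitions": {
            _STATE_KEYS[o]: {
                _STATE_KEYS[d]: float(params.saart_matrix.probabilities[o, d])
                for d in HealthState
                if d != o and params.saart_matrix.probabilities[o, d] != 0
            }
            for o in ALIVE_STATES
        },
        "costs": {
            _STATE_KEYS[s]: float(params.state_values.annual_cost[s])
            for s in ALIVE_STATES
        },
        "utilities": {
            _STATE_KEYS[s]: float(params.state_values.utility[s]) for s in ALIVE_STATES
        },
        "daart": {"annual_cost": float(params.daart_annual_cost)},
        "effect": {
            "rr": float(params.treatment_effect.relative_risk),
            "ci_low": float(params.treatment_effect.ci_low),
            "ci_high": float(params.treatment_effect.ci_high),
        },
        "mortality": [
            [float(a), float(p)]
            for a, p in zip(params.mortality.ages, params.mortality.probabilities)
        ],
        "econ": {
            "discount_rate_costs": float(params.econ.discount_rate_costs),
            "discount_rate_qalys": float(params.econ.discount_rate_qalys),
            "start_age": int(params.econ.start_age),
            "max_age": int(params.econ.max_age),
            "cycle_length": float(params.econ.cycle_length),
            "half_cycle_correction": bool(params.econ.half_cycle_correction),
            "wtp_threshold": float(params.econ.wtp_threshold),
            "discount_from": params.econ.discount_from,
            "rr_adjusts_death": bool(params.econ.rr_adjusts_death),
        },
        "ranges": {
            name: [float(r.low), float(r.high)] for name, r in params.ranges.items()
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def paper_fixture() -> ModelParameters:
    """The published Table 1 / Table 2 input set, validated."""
    text = resources.files("hivcea.data").joinpath(FIXTURE_NAME).read_text()
    return load_parameters(text)
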