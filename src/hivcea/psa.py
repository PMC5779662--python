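"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: each alive-state
transition row is drawn from a Dirichlet (so sampled rows are exactly
stochastic), utilities from Beta, costs from Gamma (both by method of
moments against the published ranges read as 95% intervals, sd = width/3.92)
and the effectiveness relative risk from a lognormal centred on the log of
the base value.  Both strategies share each draw's progression matrix, state
costs and utilities; only the sampled RR and DAART price differentiate the
arms (common random numbers for the increment).

The per-draw cohort runs are vectorised across draws; consistency with the
scalar engine in :mod:`hivcea.markov` is covered by tests.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DistributionFitError
from .markov import background_mortality_at
from .parameters import ALIVE_STATES, N_STATES, HealthState, ModelParameters

__all__ = [
    "DistributionFamily",
    "DistributionSpec",
    "PsaResult",
    "CeacCurve",
    "build_distributions",
    "sample_draws",
    "net_monetary_benefit",
    "ceac",
    "plane_export",
    "psa_summary",
    "DEFAULT_SEED",
    "DEFAULT_DRAWS",
]

log = logging.getLogger(__name__)

#: Default seed (publication date of the source analysis) and draw count.
DEFAULT_SEED = 20140123
DEFAULT_DRAWS = 10_000

#: Published ranges are read as 95% intervals: sd = width / 3.92.
_Z95 = 3.92

_STATE_KEYS = ("I", "II", "III", "IV", "death")
_DEATH = int(HealthState.DEATH)


class DistributionFamily(str, enum.Enum):
    DIRICHLET = "dirichlet"
    BETA = "beta"
    GAMMA = "gamma"
    LOGNORMAL = "lognormal"


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution assigned to a parameter or transition row.

    ``target`` is a dotted parameter name, or ``transition_row.<state>`` for
    a whole-row Dirichlet.  ``parameters`` holds the family-specific shapes;
    a ``{"degenerate": value}`` entry marks a zero-width range whose draws
    all equal the base value.
    """

    family: DistributionFamily
    target: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        p = self.parameters
        if "degenerate" in p:
            return
        if self.family is DistributionFamily.DIRICHLET:
            conc = np.asarray(p["concentrations"], float)
            if np.any(conc[conc != 0] <= 0):
                raise DistributionFitError(self.target, "concentrations must be > 0")
        elif self.family is DistributionFamily.BETA:
            if p["alpha"] <= 0 or p["beta"] <= 0:
                raise DistributionFitError(self.target, "Beta shapes must be > 0")
        elif self.family is DistributionFamily.GAMMA:
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise DistributionFitError(self.target, "Gamma shape/scale must be > 0")
        elif self.family is DistributionFamily.LOGNORMAL:
            if p["sigma"] < 0:
                raise DistributionFitError(self.target, "lognormal sigma must be >= 0")


def _beta_moments(target: str, mean: float, sd: float) -> dict:
    if sd == 0:
        return {"degenerate": mean}
    var = sd * sd
    if var >= mean * (1 - mean):
        raise DistributionFitError(
            target, f"sd {sd} too large for a Beta with mean {mean}"
        )
    k = mean * (1 - mean) / var - 1
    return {"alpha": mean * k, "beta": (1 - mean) * k}


def _gamma_moments(target: str, mean: float, sd: float) -> dict:
    if sd == 0:
        return {"degenerate": mean}
    if mean <= 0:
        raise DistributionFitError(target, "Gamma mean must be > 0")
    return {"shape": mean**2 / sd**2, "scale": sd**2 / mean}


def build_distributions(params: ModelParameters) -> list[DistributionSpec]:
    """Assign a sampling distribution to every uncertain input.

    Transition rows with more than two reachable destinations get one
    Dirichlet each, with concentrations = base probabilities (stay mass
    included) x an effective sample size fitted so the implied sd of the
    row's most uncertain published entry matches its range width / 3.92; the
    remaining entries' spreads are then implied rather than matched.  A row
    with exactly two outcomes (one exit destination plus stay) degrades to a
    Beta on the exit probability.  Utilities -> Beta, costs -> Gamma (method
    of moments, re-centred on the base value where the published range is
    inconsistent with it), RR -> lognormal with log-mean ln(base).
    """
    specs: list[DistributionSpec] = []
    base = params.saart_matrix.probabilities
    for origin in ALIVE_STATES:
        o = int(origin)
        row = base[o]
        exits = [d for d in range(N_STATES) if d != o and row[d] > 0]
        targets_sd = {}
        for d in exits:
            name = f"transition.{_STATE_KEYS[o]}.{_STATE_KEYS[d]}"
            rng_ = params.ranges.get(name)
            if rng_ is not None:
                targets_sd[d] = rng_.width / _Z95
        if len(exits) == 1:
            d = exits[0]
            sd = targets_sd.get(d, 0.0)
            specs.append(
                DistributionSpec(
                    DistributionFamily.BETA,
                    f"transition.{_STATE_KEYS[o]}.{_STATE_KEYS[d]}",
                    _beta_moments(f"transition.{_STATE_KEYS[o]}", row[d], sd),
                )
            )
            continue
        target = f"transition_row.{_STATE_KEYS[o]}"
        if not targets_sd or all(v == 0 for v in targets_sd.values()):
            specs.append(
                DistributionSpec(
                    DistributionFamily.DIRICHLET, target, {"degenerate": row.copy()}
                )
            )
            continue
        d_star, sd_star = max(targets_sd.items(), key=lambda kv: kv[1])
        p_star = row[d_star]
        n_eff = p_star * (1 - p_star) / sd_star**2 - 1
        if n_eff <= 0:
            raise DistributionFitError(target, "range too wide for a Dirichlet fit")
        conc = row * n_eff
        specs.append(
            DistributionSpec(
                DistributionFamily.DIRICHLET, target, {"concentrations": conc}
            )
        )

    for s in ALIVE_STATES:
        name = f"utility.state_{_STATE_KEYS[s]}"
        rng_ = params.ranges.get(name)
        sd = (rng_.width / _Z95) if rng_ else 0.0
        specs.append(
            DistributionSpec(
                DistributionFamily.BETA,
                name,
                _beta_moments(name, float(params.state_values.utility[s]), sd),
            )
        )
    for s in ALIVE_STATES:
        name = f"cost.state_{_STATE_KEYS[s]}"
        rng_ = params.ranges.get(name)
        sd = (rng_.width / _Z95) if rng_ else 0.0
        specs.append(
            DistributionSpec(
                DistributionFamily.GAMMA,
                name,
                _gamma_moments(name, float(params.state_values.annual_cost[s]), sd),
            )
        )
    rng_ = params.ranges.get("cost.daart")
    sd = (rng_.width / _Z95) if rng_ else 0.0
    specs.append(
        DistributionSpec(
            DistributionFamily.GAMMA,
            "cost.daart",
            _gamma_moments("cost.daart", float(params.daart_annual_cost), sd),
        )
    )
    eff = params.treatment_effect
    sigma = (np.log(eff.ci_high) - np.log(eff.ci_low)) / _Z95
    specs.append(
        DistributionSpec(
            DistributionFamily.LOGNORMAL,
            "effect.rr",
            {"mu": float(np.log(eff.relative_risk)), "sigma": float(sigma)},
        )
    )
    return specs


@dataclass(frozen=True)
class CeacCurve:
    """Probability that DAART is cost-effective across willingness-to-pay values."""

    wtp_grid: np.ndarray
    probability_alt_cost_effective: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp_grid,
                "p_daart_cost_effective": self.probability_alt_cost_effective,
            }
        )


@dataclass(frozen=True)
class PsaResult:
    """Monte-Carlo draws: sampled parameters and per-strategy outcomes.

    ``samples`` has one column per dotted parameter name (26 columns on the
    published input set); ``cost_ref``/``qaly_ref`` are the SAART arm,
    ``cost_alt``/``qaly_alt`` the DAART arm, aligned by draw.
    """

    samples: pd.DataFrame
    cost_ref: np.ndarray
    qaly_ref: np.ndarray
    cost_alt: np.ndarray
    qaly_alt: np.ndarray
    seed: int
    n_rejected: int = 0

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def incremental_cost(self) -> np.ndarray:
        return self.cost_alt - self.cost_ref

    @property
    def incremental_qalys(self) -> np.ndarray:
        return self.qaly_alt - self.qaly_ref

    def nmb(self, wtp: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-draw net monetary benefit (reference, alternative)."""
        return (
            net_monetary_benefit(self.cost_ref, self.qaly_ref, wtp),
            net_monetary_benefit(self.cost_alt, self.qaly_alt, wtp),
        )

    def ceac(self, wtp_grid) -> CeacCurve:
        return ceac(self, wtp_grid)


def net_monetary_benefit(cost, qalys, wtp: float):
    """Monetary-scale net benefit: wtp x QALYs - cost."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * np.asarray(qalys) - np.asarray(cost)


def ceac(psa: PsaResult, wtp_grid) -> CeacCurve:
    """Fraction of draws where DAART's net benefit beats SAART's (ties split)."""
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, float))
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be nonempty")
    probs = np.empty_like(wtp_grid)
    for i, w in enumerate(wtp_grid):
        nmb_ref, nmb_alt = psa.nmb(float(w))
        probs[i] = np.mean((nmb_alt > nmb_ref) + 0.5 * (nmb_alt == nmb_ref))
    return CeacCurve(wtp_grid, probs)


def plane_export(psa: PsaResult) -> pd.DataFrame:
    """Cost-effectiveness plane: one row per draw with its quadrant label."""
    dc, dq = psa.incremental_cost, psa.incremental_qalys
    quadrant = np.where(
        dq >= 0, np.where(dc >= 0, "NE", "SE"), np.where(dc >= 0, "NW", "SW")
    )
    return pd.DataFrame(
        {
            "incremental_cost": dc,
            "incremental_qalys": dq,
            "quadrant": quadrant,
        }
    )


def psa_summary(psa: PsaResult) -> pd.DataFrame:
    """Means and 2.5/97.5 percentiles of costs, QALYs and increments."""
    data = {
        "cost_saart": psa.cost_ref,
        "cost_daart": psa.cost_alt,
        "qalys_saart": psa.qaly_ref,
        "qalys_daart": psa.qaly_alt,
        "incremental_cost": psa.incremental_cost,
        "incremental_qalys": psa.incremental_qalys,
    }
    rows = []
    for name, arr in data.items():
        rows.append(
            {
                "quantity": name,
                "mean": float(np.mean(arr)),
                "p2.5": float(np.percentile(arr, 2.5)),
                "p97.5": float(np.percentile(arr, 97.5)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sampling and vectorised evaluation
# ---------------------------------------------------------------------------


def _sample_spec(rng: np.random.Generator, spec: DistributionSpec, n: int):
    p = spec.parameters
    if "degenerate" in p:
        val = p["degenerate"]
        return np.tile(np.asarray(val, float), (n, 1)) if np.ndim(val) else np.full(
            n, float(val)
        )
    if spec.family is DistributionFamily.DIRICHLET:
        conc = np.asarray(p["concentrations"], float)
        out = np.zeros((n, conc.size))
        pos = conc > 0
        out[:, pos] = rng.dirichlet(conc[pos], size=n)
        return out
    if spec.family is DistributionFamily.BETA:
        return rng.beta(p["alpha"], p["beta"], size=n)
    if spec.family is DistributionFamily.GAMMA:
        return rng.gamma(p["shape"], p["scale"], size=n)
    if spec.family is DistributionFamily.LOGNORMAL:
        return rng.lognormal(p["mu"], p["sigma"], size=n)
    raise ValueError(f"unknown family {spec.family}")


def _sample_parameter_table(
    rng: np.random.Generator, params: ModelParameters, specs, n: int
) -> tuple[pd.DataFrame, dict]:
    """Draw all parameters; return the flat sample table and structured arrays."""
    matrix_rows = {int(s): None for s in ALIVE_STATES}
    columns: dict[str, np.ndarray] = {}
    util = np.tile(params.state_values.utility, (n, 1))
    cost = np.tile(params.state_values.annual_cost, (n, 1))
    daart_cost = np.full(n, float(params.daart_annual_cost))
    rr = np.full(n, float(params.treatment_effect.relative_risk))

    for spec in specs:
        draw = _sample_spec(rng, spec, n)
        t = spec.target
        if t.startswith("transition_row."):
            o = _STATE_KEYS.index(t.removeprefix("transition_row."))
            matrix_rows[o] = draw
            for d in range(N_STATES):
                if d != o and params.saart_matrix.probabilities[o, d] > 0:
                    columns[f"transition.{_STATE_KEYS[o]}.{_STATE_KEYS[d]}"] = draw[:, d]
        elif t.startswith("transition."):  # Beta on a two-outcome row
            _, o_key, d_key = t.split(".")
            o, d = _STATE_KEYS.index(o_key), _STATE_KEYS.index(d_key)
            row = np.tile(params.saart_matrix.probabilities[o], (n, 1))
            row[:, d] = draw
            row[:, o] = 0.0
            row[:, o] = 1.0 - row.sum(axis=1)
            matrix_rows[o] = row
            columns[t] = draw
        elif t.startswith("utility.state_"):
            s = _STATE_KEYS.index(t.removeprefix("utility.state_"))
            util[:, s] = draw
            columns[t] = draw
        elif t == "cost.daart":
            daart_cost = draw
            columns[t] = draw
        elif t.startswith("cost.state_"):
            s = _STATE_KEYS.index(t.removeprefix("cost.state_"))
            cost[:, s] = draw
            columns[t] = draw
        elif t == "effect.rr":
            rr = draw
            columns[t] = draw
        else:
            raise ValueError(f"unknown sampling target {t}")

    matrices = np.zeros((n, N_STATES, N_STATES))
    matrices[:, _DEATH, _DEATH] = 1.0
    for o in (int(s) for s in ALIVE_STATES):
        row = matrix_rows[o]
        if row is None:  # no spec for this row: keep base values
            row = np.tile(params.saart_matrix.probabilities[o], (n, 1))
        matrices[:, o, :] = row

    table = pd.DataFrame(columns)
    return table, {
        "matrices": matrices,
        "utilities": util,
        "costs": cost,
        "daart_cost": daart_cost,
        "rr": rr,
    }


def _valid_mask(arrays: dict) -> np.ndarray:
    m = arrays["matrices"]
    ok = np.all(np.isfinite(m), axis=(1, 2))
    ok &= np.all(m >= 0, axis=(1, 2)) & np.all(m <= 1 + 1e-12, axis=(1, 2))
    ok &= np.all(np.abs(m.sum(axis=2) - 1) < 1e-9, axis=1)
    u = arrays["utilities"]
    ok &= np.all((u >= 0) & (u <= 1), axis=1)
    ok &= np.all(arrays["costs"] >= 0, axis=1)
    ok &= arrays["daart_cost"] >= 0
    ok &= arrays["rr"] > 0
    return ok


def _batch_evaluate(
    params: ModelParameters,
    matrices: np.ndarray,
    utilities: np.ndarray,
    costs: np.ndarray,
    intervention_cost,
    rr,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cohort evaluation across draws; mirrors the scalar engine."""
    econ = params.econ
    n = matrices.shape[0]
    rr = np.broadcast_to(np.asarray(rr, float), (n,))
    icost = np.broadcast_to(np.asarray(intervention_cost, float), (n,))

    adj = matrices.copy()
    worse_end = N_STATES if econ.rr_adjusts_death else _DEATH
    for o in (int(s) for s in ALIVE_STATES):
        adj[:, o, :o] *= rr[:, None]
        adj[:, o, o + 1 : worse_end] /= rr[:, None]
        off = adj[:, o, :].sum(axis=1) - adj[:, o, o]
        adj[:, o, o] = 1.0 - off
    if np.any(adj < -1e-9):
        raise FloatingPointError("RR adjustment produced a negative probability")

    T = int(round(econ.max_age - econ.start_age))
    alive = slice(0, _DEATH)
    cost_per_state = costs.copy()
    cost_per_state[:, alive] += icost[:, None]

    k = np.arange(1, T + 1, dtype=float)
    expo = k - 1.0 if econ.discount_from == "first" else k
    dfc = (1.0 + econ.discount_rate_costs) ** -expo
    dfq = (1.0 + econ.discount_rate_qalys) ** -expo

    occ = np.zeros((n, N_STATES))
    occ[:, int(HealthState.STATE_I)] = 1.0
    total_cost = np.zeros(n)
    total_qaly = np.zeros(n)
    for t in range(T):
        p_bg = background_mortality_at(params.mortality, econ.start_age + t)
        m = adj.copy()
        m[:, alive, alive.start : alive.stop] *= 1.0 - p_bg
        m[:, alive, _DEATH] = 1.0 - (1.0 - p_bg) * (1.0 - adj[:, alive, _DEATH])
        occ_next = np.einsum("ns,nsd->nd", occ, m)
        mid = 0.5 * (occ + occ_next) if econ.half_cycle_correction else occ
        total_cost += dfc[t] * np.einsum("ns,ns->n", mid, cost_per_state)
        total_qaly += dfq[t] * np.einsum("ns,ns->n", mid, utilities)
        occ = occ_next
    return total_cost, total_qaly


def sample_draws(
    params: ModelParameters,
    n: int = DEFAULT_DRAWS,
    seed: int = DEFAULT_SEED,
    specs: list[DistributionSpec] | None = None,
) -> PsaResult:
    """Run the Monte-Carlo PSA: sample parameters and evaluate both arms.

    Reproducible given ``seed``.  Draws failing validation are rejected and
    redrawn (a rejection rate above 1% logs a warning).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if specs is None:
        specs = build_distributions(params)
    rng = np.random.default_rng(seed)

    table, arrays = _sample_parameter_table(rng, params, specs, n)
    n_rejected = 0
    for _ in range(100):
        bad = ~_valid_mask(arrays)
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        n_rejected += n_bad
        new_table, new_arrays = _sample_parameter_table(rng, params, specs, n_bad)
        idx = np.flatnonzero(bad)
        table.iloc[idx] = new_table.values
        for key in arrays:
            arrays[key][idx] = new_arrays[key]
    else:
        raise RuntimeError("PSA rejection resampling failed to converge")
    if n_rejected > 0.01 * n:
        log.warning("PSA rejected %d of %d draws (>1%%)", n_rejected, n)

    cost_ref, qaly_ref = _batch_evaluate(
        params, arrays["matrices"], arrays["utilities"], arrays["costs"], 0.0, 1.0
    )
    cost_alt, qaly_alt = _batch_evaluate(
        params,
        arrays["matrices"],
        arrays["utilities"],
        arrays["costs"],
        arrays["daart_cost"],
        arrays["rr"],
    )
    return PsaResult(
        samples=table,
        cost_ref=cost_ref,
        qaly_ref=qaly_ref,
        cost_alt=cost_alt,
        qaly_alt=qaly_alt,
        seed=seed,
        n_rejected=n_rejected,
    )
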