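"""Value-of-information analysis.

Per-patient EVPI is the expected opportunity loss of deciding under current
information: the mean over PSA draws of the best per-draw net monetary
benefit, minus the net monetary benefit of the strategy that is best on
average.  It is scaled to the population level with an effective-population
annuity (annual eligible cohort, discounted over the decision's lifetime).
Grouped EVPPI uses a single-loop linear metamodel: each strategy's net
benefit is regressed on the group's sampled parameters and the fitted values
stand in for the conditional expectations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psa import PsaResult

__all__ = [
    "EffectivePopulation",
    "VoiCurve",
    "EvppiResult",
    "EVPPI_GROUPS",
    "evpi_per_patient",
    "effective_population",
    "population_evpi",
    "evpi_curve",
    "evppi_linear",
]

log = logging.getLogger(__name__)

#: Parameter groups for partial EVPI.  State treatment costs form their own
#: optional group, kept apart from the intervention's own price.
EVPPI_GROUPS: dict[str, tuple[str, ...]] = {
    "effectiveness": ("effect.rr",),
    "cost": ("cost.daart",),
    "utility": tuple(f"utility.state_{k}" for k in ("I", "II", "III", "IV")),
    "probabilities": tuple(),  # filled lazily: every transition.* column
    "treatment_cost": tuple(f"cost.state_{k}" for k in ("I", "II", "III", "IV")),
}


@dataclass(frozen=True)
class EffectivePopulation:
    """Annual decision-relevant population and its discounted 50-year total.

    Default inputs: ~24.4 million people living with HIV in sub-Saharan
    Africa, of whom 37% are on ART and 17.4% are at high risk of
    non-adherence; the annual effective population (~1.6 million) is summed
    over the treatment lifetime at the QALY discount rate.
    """

    plhiv: float = 24.4e6
    on_art_fraction: float = 0.37
    high_risk_fraction: float = 0.174
    horizon_years: int = 50
    discount_rate: float = 0.03
    annual_effective: float = field(init=False)
    discounted_total: float = field(init=False)

    def __post_init__(self):
        for name in ("on_art_fraction", "high_risk_fraction"):
            f = getattr(self, name)
            if not 0 <= f <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        annual = self.plhiv * self.on_art_fraction * self.high_risk_fraction
        t = np.arange(self.horizon_years)
        total = float(np.sum(annual / (1 + self.discount_rate) ** t))
        object.__setattr__(self, "annual_effective", float(annual))
        object.__setattr__(self, "discounted_total", total)


def effective_population(**kwargs) -> EffectivePopulation:
    """Build an :class:`EffectivePopulation`; defaults are the published inputs."""
    return EffectivePopulation(**kwargs)


def evpi_per_patient(psa: PsaResult, wtp: float) -> float:
    """Per-patient expected value of perfect information at one threshold."""
    if psa.n == 0:
        raise ValueError("psa must contain at least one draw")
    nmb = np.vstack(psa.nmb(wtp))  # (2, n)
    value = float(nmb.max(axis=0).mean() - nmb.mean(axis=1).max())
    return max(value, 0.0)


def population_evpi(evpi_pp: float, pop: EffectivePopulation) -> float:
    """Scale per-patient EVPI by the discounted effective population."""
    if evpi_pp < 0:
        raise ValueError("evpi_pp must be >= 0")
    return evpi_pp * pop.discounted_total


@dataclass(frozen=True)
class VoiCurve:
    """EVPI across a willingness-to-pay grid, per patient and population."""

    wtp_grid: np.ndarray
    evpi_per_patient: np.ndarray
    evpi_population: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp_grid,
                "evpi_per_patient": self.evpi_per_patient,
                "evpi_population": self.evpi_population,
            }
        )


def evpi_curve(
    psa: PsaResult, wtp_grid, pop: EffectivePopulation | None = None
) -> VoiCurve:
    """Per-patient and population EVPI over a willingness-to-pay grid."""
    pop = pop or EffectivePopulation()
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, float))
    pp = np.array([evpi_per_patient(psa, float(w)) for w in wtp_grid])
    return VoiCurve(wtp_grid, pp, pp * pop.discounted_total)


@dataclass(frozen=True)
class EvppiResult:
    """Partial EVPI for one parameter group at one threshold.

    ``evppi_per_patient`` is clipped to [0, EVPI]; ``raw_value`` keeps the
    unclipped metamodel estimate for diagnostics.
    """

    group_name: str
    wtp: float
    evppi_per_patient: float
    evppi_population: float
    raw_value: float
    evpi_per_patient: float


def _group_columns(psa: PsaResult, group: str) -> list[str]:
    if group not in EVPPI_GROUPS:
        raise KeyError(f"unknown EVPPI group {group!r}; known: {list(EVPPI_GROUPS)}")
    if group == "probabilities":
        cols = [c for c in psa.samples.columns if c.startswith("transition.")]
    else:
        cols = [c for c in EVPPI_GROUPS[group] if c in psa.samples.columns]
    if not cols:
        raise KeyError(f"group {group!r} has no sampled columns in this PSA")
    return cols


def evppi_linear(
    psa: PsaResult,
    group: str,
    wtp: float,
    pop: EffectivePopulation | None = None,
) -> EvppiResult:
    """Single-loop linear-metamodel EVPPI for a named parameter group.

    Each strategy's per-draw net monetary benefit is regressed (OLS with
    intercept) on the group's sampled parameter columns; the fitted values
    approximate E[NMB | group], and the EVPI formula applied to them gives
    the partial value.  Collinear columns are dropped by the least-squares
    solve with a logged warning.  The estimate is clipped to [0, EVPI].
    """
    pop = pop or EffectivePopulation()
    cols = _group_columns(psa, group)
    X = np.column_stack(
        [np.ones(psa.n)] + [psa.samples[c].to_numpy(float) for c in cols]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        log.warning(
            "EVPPI design for group %s is rank-deficient (%d < %d); "
            "collinear columns resolved by least squares",
            group,
            rank,
            X.shape[1],
        )
    nmb = np.vstack(psa.nmb(wtp))  # (2, n)
    fitted = np.empty_like(nmb)
    for i in range(nmb.shape[0]):
        beta, *_ = np.linalg.lstsq(X, nmb[i], rcond=None)
        fitted[i] = X @ beta
    raw = float(fitted.max(axis=0).mean() - fitted.mean(axis=1).max())
    evpi = evpi_per_patient(psa, wtp)
    clipped = float(np.clip(raw, 0.0, evpi))
    if raw > evpi:
        log.info(
            "EVPPI(%s) metamodel estimate %.4f exceeds EVPI %.4f; clipped",
            group,
            raw,
            evpi,
        )
    return EvppiResult(
        group_name=group,
        wtp=float(wtp),
        evppi_per_patient=clipped,
        evppi_population=population_evpi(clipped, pop),
        raw_value=raw,
        evpi_per_patient=evpi,
    )
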