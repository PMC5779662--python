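"""Model / Results facade for the cost-utility analysis.

:class:`CostUtilityModel` is constructed from a :class:`ModelParameters`
input set (or a parameter file) and knows how to evaluate both treatment
strategies; :meth:`CostUtilityModel.fit` returns a
:class:`CostUtilityResults` carrying the base-case estimates, the ICER and a
text summary.  Sensitivity analyses, the probabilistic analysis and the
value-of-information calculations hang off these two objects as thin
wrappers over the functional modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import deterministic, psa as psa_mod, voi as voi_mod
from .deterministic import IcerResult, ThresholdResult, TornadoEntry
from .markov import EconResult, daart_strategy, evaluate_strategy, saart_strategy
from .parameters import (
    HealthState,
    ModelParameters,
    load_parameters,
    paper_fixture,
)
from .psa import PsaResult

__all__ = ["CostUtilityModel", "CostUtilityResults"]


class CostUtilityModel:
    """Lifetime five-state Markov cost-utility model of DAART vs SAART.

    Parameters
    ----------
    params : ModelParameters
        Validated input set (transition matrix, state costs/utilities, DAART
        price, effectiveness RR, background mortality, economic settings).

    Examples
    --------
    >>> model = CostUtilityModel.from_paper()
    >>> results = model.fit()
    >>> print(results.summary())            # doctest: +SKIP
    """

    def __init__(self, params: ModelParameters):
        self.params = params

    @classmethod
    def from_file(cls, source) -> "CostUtilityModel":
        """Build from a parameter document (path, YAML text or mapping)."""
        return cls(load_parameters(source))

    @classmethod
    def from_paper(cls) -> "CostUtilityModel":
        """Build from the bundled published input set."""
        return cls(paper_fixture())

    def fit(self) -> "CostUtilityResults":
        """Evaluate both strategies deterministically at the base case."""
        ref, alt, icer = deterministic.base_case(self.params)
        return CostUtilityResults(self, ref, alt, icer)

    # -- analyses ----------------------------------------------------------

    def structural_scenario(self) -> tuple[ModelParameters, IcerResult]:
        """ICER with all reverse (improvement) transitions removed."""
        return deterministic.structural_scenario(self.params)

    def one_way(
        self, relative_delta: float = 0.25, overrides=None
    ) -> list[TornadoEntry]:
        """One-way sensitivity analysis; see :func:`deterministic.one_way_sensitivity`."""
        return deterministic.one_way_sensitivity(self.params, relative_delta, overrides)

    def threshold(self, price_grid=None, wtp=None) -> ThresholdResult:
        """Threshold analysis over the annual DAART price."""
        return deterministic.threshold_analysis(self.params, price_grid, wtp)

    def convention_sensitivity(self) -> pd.DataFrame:
        """Base case under alternative discounting/half-cycle/horizon conventions."""
        return deterministic.convention_sensitivity(self.params)

    def psa(
        self,
        n: int = psa_mod.DEFAULT_DRAWS,
        seed: int = psa_mod.DEFAULT_SEED,
        specs=None,
    ) -> PsaResult:
        """Probabilistic sensitivity analysis with ``n`` Monte-Carlo draws."""
        return psa_mod.sample_draws(self.params, n=n, seed=seed, specs=specs)


@dataclass
class CostUtilityResults:
    """Deterministic base-case results with uncertainty analyses attached."""

    model: CostUtilityModel
    saart: EconResult
    daart: EconResult
    icer: IcerResult

    def trace_frame(self) -> pd.DataFrame:
        """Per-cycle occupancy and cumulative discounted outcomes, both arms."""
        params = self.model.params
        econ = params.econ
        frames = []
        for res, strategy in (
            (self.saart, saart_strategy()),
            (self.daart, daart_strategy(params)),
        ):
            occ = res.trace.occupancy
            n = res.trace.n_cycles
            df = pd.DataFrame(
                occ, columns=[s.name.lower() for s in HealthState]
            )
            df.insert(0, "cycle", np.arange(n + 1))
            df.insert(1, "age", econ.start_age + np.arange(n + 1))
            df.insert(2, "strategy", res.strategy)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Plain-text results table in the style of a regression summary."""
        i = self.icer
        lines = [
            "Cost-utility analysis: DAART vs self-administered ART",
            "=" * 61,
            f"{'Strategy':<10}{'Cost (US$)':>15}{'QALYs':>12}"
            f"{'Incr. cost':>14}{'Incr. QALYs':>10}",
            "-" * 61,
            f"{'SAART':<10}{i.cost_ref:>15,.0f}{i.qaly_ref:>12.2f}"
            f"{'-':>14}{'-':>10}",
            f"{'DAART':<10}{i.cost_alt:>15,.0f}{i.qaly_alt:>12.2f}"
            f"{i.incremental_cost:>14,.0f}{i.incremental_qalys:>10.2f}",
            "-" * 61,
        ]
        if i.dominance == "alternative_dominant":
            lines.append("DAART dominates (cheaper and more effective)")
        elif i.dominance == "alternative_dominated":
            lines.append("DAART is dominated (dearer and less effective)")
        elif i.dominance == "undefined":
            lines.append("ICER undefined (zero incremental QALYs)")
        else:
            lines.append(f"ICER: {i.icer:,.0f} US$/QALY")
        econ = self.model.params.econ
        lines += [
            f"WTP threshold: {econ.wtp_threshold:,.0f} US$/QALY -> DAART is "
            + (
                "cost-effective"
                if not np.isnan(i.icer) and i.icer <= econ.wtp_threshold
                else "not cost-effective"
            ),
            f"(start age {econ.start_age}, horizon to age {econ.max_age}, "
            f"discount {econ.discount_rate_costs:.0%}, half-cycle correction "
            f"{'on' if econ.half_cycle_correction else 'off'})",
        ]
        return "\n".join(lines)

    # -- uncertainty -------------------------------------------------------

    def evpi(self, psa: PsaResult, wtp_grid, pop=None) -> voi_mod.VoiCurve:
        """EVPI curve from a PSA run (per patient and population)."""
        return voi_mod.evpi_curve(psa, wtp_grid, pop)

    def evppi(self, psa: PsaResult, group: str, wtp: float, pop=None):
        """Grouped linear-metamodel EVPPI from a PSA run."""
        return voi_mod.evppi_linear(psa, group, wtp, pop)

    def plot_ceac(self, psa: PsaResult, wtp_grid, ax=None):
        """Convenience CEAC plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        curve = psa_mod.ceac(psa, wtp_grid)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.wtp_grid, curve.probability_alt_cost_effective)
        ax.set_xlabel("Willingness to pay (US$/QALY)")
        ax.set_ylabel("P(DAART cost-effective)")
        ax.set_ylim(0, 1)
        return ax
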