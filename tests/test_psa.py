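"""Distribution assignment, Monte-Carlo sampling and CEAC construction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hivcea.exceptions import DistributionFitError
from hivcea.markov import StrategySpec, evaluate_strategy
from hivcea.parameters import ParameterRange
from hivcea.psa import (
    DistributionFamily,
    PsaResult,
    build_distributions,
    ceac,
    net_monetary_benefit,
    plane_export,
    psa_summary,
    sample_draws,
)


def _spec_by_target(specs, target):
    return next(s for s in specs if s.target == target)


class TestBuildDistributions:
    def test_families_assigned_per_parameter_class(self, params):
        specs = build_distributions(params)
        families = {s.target: s.family for s in specs}
        for key in ("I", "II", "III", "IV"):
            assert families[f"transition_row.{key}"] is DistributionFamily.DIRICHLET
        for key in ("I", "II", "III", "IV"):
            assert families[f"utility.state_{key}"] is DistributionFamily.BETA
            assert families[f"cost.state_{key}"] is DistributionFamily.GAMMA
        assert families["cost.daart"] is DistributionFamily.GAMMA
        assert families["effect.rr"] is DistributionFamily.LOGNORMAL

    def test_rr_lognormal_parameters(self, params):
        spec = _spec_by_target(build_distributions(params), "effect.rr")
        assert spec.parameters["mu"] == pytest.approx(np.log(1.29))
        assert spec.parameters["sigma"] == pytest.approx(
            (np.log(1.48) - np.log(1.12)) / 3.92
        )

    def test_utility_iv_beta_moments(self, params):
        spec = _spec_by_target(build_distributions(params), "utility.state_IV")
        sd = (0.80 - 0.24) / 3.92
        assert sd == pytest.approx(0.1429, abs=5e-5)
        a, b = spec.parameters["alpha"], spec.parameters["beta"]
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert mean == pytest.approx(0.73)
        assert np.sqrt(var) == pytest.approx(sd)

    def test_dirichlet_matches_most_uncertain_entry(self, params):
        spec = _spec_by_target(build_distributions(params), "transition_row.I")
        conc = np.asarray(spec.parameters["concentrations"])
        n_eff = conc.sum()
        # most uncertain published entry of the State I row is I->II
        sd_target = (0.271 - 0.187) / 3.92
        p = 0.227
        implied_sd = np.sqrt(p * (1 - p) / (n_eff + 1))
        assert implied_sd == pytest.approx(sd_target, rel=1e-6)
        assert conc / n_eff == pytest.approx(
            params.saart_matrix.probabilities[0], rel=1e-12
        )

    def test_zero_width_range_degenerates(self, params):
        p2 = dataclasses.replace(
            params,
            ranges={**params.ranges, "cost.daart": ParameterRange(964.0, 964.0)},
        )
        spec = _spec_by_target(build_distributions(p2), "cost.daart")
        assert spec.parameters == {"degenerate": 964.0}

    def test_infeasible_beta_moments_raise(self, params):
        # a range so wide the implied sd exceeds a Beta's maximum
        p2 = dataclasses.replace(
            params,
            ranges={**params.ranges, "utility.state_I": ParameterRange(-3.0, 3.0)},
        )
        with pytest.raises(DistributionFitError):
            build_distributions(p2)

    def test_two_outcome_row_gets_beta(self, params):
        p = params.saart_matrix.probabilities.copy()
        p[0] = 0.0
        p[0, 4] = 0.022
        p[0, 0] = 1 - 0.022
        p2 = dataclasses.replace(
            params, saart_matrix=dataclasses.replace(params.saart_matrix, probabilities=p)
        )
        spec = _spec_by_target(build_distributions(p2), "transition.I.death")
        assert spec.family is DistributionFamily.BETA


class TestSampling:
    def test_seed_reproducibility(self, model):
        a = model.psa(n=200, seed=42)
        b = model.psa(n=200, seed=42)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert np.array_equal(a.cost_alt, b.cost_alt)

    def test_degenerate_specs_reproduce_base_case(self, params, fitted):
        # zero-width ranges mean sd = 0: every family degenerates to the base
        # value (the midpoint itself is never used, only the width); the RR
        # lognormal is parameterised by its confidence interval, so collapse
        # that too
        from hivcea.parameters import TreatmentEffect

        p2 = dataclasses.replace(
            params,
            ranges={k: ParameterRange(0.5, 0.5) for k in params.ranges},
            treatment_effect=TreatmentEffect(1.29, 1.29, 1.29),
        )
        res = sample_draws(p2, n=5, seed=0)
        assert np.allclose(res.cost_ref, fitted.saart.discounted_cost)
        assert np.allclose(res.qaly_alt, fitted.daart.discounted_qalys)

    def test_sampled_means_converge_to_base(self, psa_default, params):
        """Monte-Carlo means match each spec's analytic mean within 3 SE."""
        s = psa_default.samples
        n = psa_default.n
        checks = {
            "cost.daart": 964.0,
            "cost.state_IV": 1272.44,
            "utility.state_II": 0.89,
            "utility.state_IV": 0.73,
        }
        for name, mean in checks.items():
            draw = s[name]
            se = draw.std() / np.sqrt(n)
            assert abs(draw.mean() - mean) < 3 * se, name
        # lognormal mean is median * exp(sigma^2 / 2)
        sigma = (np.log(1.48) - np.log(1.12)) / 3.92
        rr_mean = 1.29 * np.exp(sigma**2 / 2)
        rr = s["effect.rr"]
        assert abs(rr.mean() - rr_mean) < 3 * rr.std() / np.sqrt(n)

    def test_dirichlet_rows_sum_to_one(self, psa_default, params):
        cols = [c for c in psa_default.samples.columns if c.startswith("transition.I.")]
        off = psa_default.samples[cols].to_numpy().sum(axis=1)
        assert np.all(off < 1.0)  # stay mass is the positive remainder

    def test_vectorised_evaluation_matches_scalar_engine(self, model, params):
        """Each PSA draw's outcomes equal a scalar-engine run on that draw."""
        import hivcea.parameters as hp

        res = model.psa(n=4, seed=123)
        for i in range(res.n):
            p_i = params
            for name, value in res.samples.iloc[i].items():
                p_i = hp.with_value(p_i, name, float(value))
            rr_i = float(res.samples.iloc[i]["effect.rr"])
            daart_cost_i = float(res.samples.iloc[i]["cost.daart"])
            ref = evaluate_strategy(p_i, StrategySpec("SAART", 0.0, 1.0))
            alt = evaluate_strategy(p_i, StrategySpec("DAART", daart_cost_i, rr_i))
            assert res.cost_ref[i] == pytest.approx(ref.discounted_cost, rel=1e-9)
            assert res.qaly_ref[i] == pytest.approx(ref.discounted_qalys, rel=1e-9)
            assert res.cost_alt[i] == pytest.approx(alt.discounted_cost, rel=1e-9)
            assert res.qaly_alt[i] == pytest.approx(alt.discounted_qalys, rel=1e-9)


class TestNmbAndCeac:
    def test_nmb_arithmetic(self):
        assert net_monetary_benefit(5200, 8.52, 5086) == pytest.approx(38132.72)
        assert net_monetary_benefit(123.0, 4.0, 0.0) == -123.0
        assert net_monetary_benefit(0.0, 0.0, 10_000.0) == 0.0

    def test_ceac_zero_wtp_with_costlier_alt(self, psa_default):
        curve = ceac(psa_default, [0.0])
        assert curve.probability_alt_cost_effective[0] == 0.0

    def test_ceac_monotone_when_alt_more_effective_everywhere(self, psa_default):
        # restrict to the draws with a strict QALY gain: on that subsample
        # higher willingness-to-pay can only favour DAART
        keep = psa_default.incremental_qalys > 0
        assert keep.mean() > 0.95  # nearly all draws show a gain
        sub = PsaResult(
            samples=psa_default.samples[keep].reset_index(drop=True),
            cost_ref=psa_default.cost_ref[keep],
            qaly_ref=psa_default.qaly_ref[keep],
            cost_alt=psa_default.cost_alt[keep],
            qaly_alt=psa_default.qaly_alt[keep],
            seed=psa_default.seed,
        )
        curve = ceac(sub, np.arange(0, 30_000, 500.0))
        assert np.all(np.diff(curve.probability_alt_cost_effective) >= 0)

    def test_tie_splitting(self):
        res = PsaResult(
            samples=pd.DataFrame({"effect.rr": [1.0, 1.0]}),
            cost_ref=np.array([0.0, 0.0]),
            qaly_ref=np.array([0.0, 0.0]),
            cost_alt=np.array([0.0, 0.0]),
            qaly_alt=np.array([0.0, 0.0]),
            seed=0,
        )
        curve = ceac(res, [1000.0])
        assert curve.probability_alt_cost_effective[0] == 0.5


class TestExports:
    def test_plane_quadrants(self):
        res = PsaResult(
            samples=pd.DataFrame({"effect.rr": [1, 1, 1]}),
            cost_ref=np.array([10.0, 10.0, 10.0]),
            qaly_ref=np.array([1.0, 1.0, 1.0]),
            cost_alt=np.array([20.0, 5.0, 20.0]),
            qaly_alt=np.array([2.0, 2.0, 0.5]),
            seed=0,
        )
        frame = plane_export(res)
        assert list(frame["quadrant"]) == ["NE", "SE", "NW"]

    def test_summary_covers_key_quantities(self, psa_default):
        frame = psa_summary(psa_default)
        assert set(frame["quantity"]) >= {
            "incremental_cost",
            "incremental_qalys",
            "cost_saart",
            "qalys_daart",
        }
        row = frame.set_index("quantity").loc["incremental_qalys"]
        assert row["p2.5"] < row["mean"] < row["p97.5"]
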