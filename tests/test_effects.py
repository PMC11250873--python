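"""Marginal effects, pseudo-R-squared and nested model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dwscrash.data import DesignMatrix
from dwscrash.effects import (
    likelihood_ratio_test,
    marginal_effect_indicator,
    marginal_effects,
    mcfadden_r2,
    null_loglik,
)
from dwscrash.ordinal import OrderedLogit, OrderedLogitResults, fit_fixed


def _indicator_design(rng, n=400):
    X = np.column_stack(
        [np.ones(n), rng.integers(0, 2, n), rng.integers(0, 2, n)]
    ).astype(float)
    beta = np.array([-0.2, 0.8, 0.0])
    latent = X @ beta + rng.logistic(size=n)
    y = np.where(latent <= 0, 0, np.where(latent <= 1.3, 1, 2))
    frame = pd.DataFrame(X, columns=["const", "treat", "noise"])
    return DesignMatrix(outcome=y, X=frame, roles={c: "fixed" for c in frame.columns})


class TestMarginalEffects:
    def test_fixed_model_matches_analytic_logistic_difference(self, rng):
        design = _indicator_design(rng)
        res = fit_fixed(design)
        et = marginal_effects(res, design, variables=["treat"], pvalues=False)
        beta, psi1 = res.params[:-1], res.psi1
        xbar = design.X.mean().to_numpy()
        j = design.X.columns.get_loc("treat")
        x1, x0 = xbar.copy(), xbar.copy()
        x1[j], x0[j] = 1.0, 0.0
        for k, (lo, hi) in enumerate([(-np.inf, 0.0), (0.0, psi1), (psi1, np.inf)]):
            analytic = (expit(hi - x1 @ beta) - expit(lo - x1 @ beta)) - (
                expit(hi - x0 @ beta) - expit(lo - x0 @ beta)
            )
            assert et.table[f"effect_y{k}"].iloc[0] == pytest.approx(analytic, abs=1e-10)

    def test_effects_sum_to_zero_across_categories(self, rng):
        design = _indicator_design(rng)
        res = fit_fixed(design)
        et = marginal_effects(res, design, pvalues=False)
        assert et.conservation_residual() < 1e-12

    def test_crp_effects_sum_to_zero(self, compact_scenario, crp_fit):
        _, design, _ = compact_scenario
        et = marginal_effects(crp_fit, design, variables=["female", "year_index"], pvalues=False)
        assert et.conservation_residual() < 1e-10

    def test_zero_coefficient_gives_zero_effect_and_p_near_one(self, rng):
        design = _indicator_design(rng)
        res = fit_fixed(design)
        params = res.params.copy()
        params[design.X.columns.get_loc("noise")] = 0.0
        res0 = OrderedLogitResults(
            model=res.model, params=params, llf=res.model.loglike(params),
            hessian=res.hessian, converged=True, grad_norm=0.0, n_iter=0,
        )
        et = marginal_effects(res0, design, variables=["noise"])
        assert np.allclose(
            et.table[["effect_y0", "effect_y1", "effect_y2"]].to_numpy(), 0.0, atol=1e-12
        )
        assert np.all(et.table[["p_y0", "p_y1", "p_y2"]].to_numpy() > 0.9)

    def test_strong_effect_detected_at_large_n(self):
        rng = np.random.default_rng(77)
        design = _indicator_design(rng, n=10_000)
        res = fit_fixed(design)
        et = marginal_effects(res, design, variables=["treat"])
        assert np.all(et.table[["p_y0", "p_y1", "p_y2"]].to_numpy() < 0.01)

    def test_year_uses_plus_one_increment(self, compact_scenario, fixed_fit):
        _, design, _ = compact_scenario
        eff = marginal_effect_indicator(fixed_fit, design, "year_index", 2)
        beta, psi1 = fixed_fit.params[:-1], fixed_fit.psi1
        xbar = design.X.mean().to_numpy()
        j = design.X.columns.get_loc("year_index")
        x1 = xbar.copy()
        x1[j] += 1.0
        analytic = (1 - expit(psi1 - x1 @ beta)) - (1 - expit(psi1 - xbar @ beta))
        assert eff == pytest.approx(analytic, abs=1e-10)

    def test_non_indicator_without_rule_is_error(self, rng):
        design = _indicator_design(rng)
        design.X["cont"] = rng.normal(size=design.n_rows)
        design.roles["cont"] = "fixed"
        res = fit_fixed(design)
        with pytest.raises(ValueError):
            marginal_effects(res, design, variables=["cont"], pvalues=False)

    def test_observation_averaged_variant(self, rng):
        design = _indicator_design(rng)
        res = fit_fixed(design)
        at_means = marginal_effects(res, design, variables=["treat"], pvalues=False)
        averaged = marginal_effects(
            res, design, variables=["treat"], at="observations", pvalues=False
        )
        assert averaged.conservation_residual() < 1e-12
        # the two conventions agree in sign and rough magnitude
        assert np.sign(averaged.table["effect_y0"].iloc[0]) == np.sign(
            at_means.table["effect_y0"].iloc[0]
        )


class TestMcFaddenR2:
    def test_closed_form_identities(self):
        assert mcfadden_r2(-100.0, -100.0) == 0.0
        assert mcfadden_r2(-50.0, -100.0) == 0.5

    def test_matches_hand_arithmetic_for_fit(self, compact_scenario, fixed_fit):
        _, design, _ = compact_scenario
        ll0 = null_loglik(design.outcome)
        assert mcfadden_r2(fixed_fit.llf, ll0) == pytest.approx(1.0 - fixed_fit.llf / ll0)
        assert 0.0 <= mcfadden_r2(fixed_fit.llf, ll0) < 1.0

    def test_misordering_is_error(self):
        with pytest.raises(ValueError):
            mcfadden_r2(-101.0, -100.0)
        with pytest.raises(ValueError):
            mcfadden_r2(-1.0, 1.0)

    def test_null_is_multinomial_share_loglik(self, rng):
        y = rng.choice([0, 1, 2], size=300, p=[0.5, 0.3, 0.2])
        shares = np.array([(y == k).mean() for k in (0, 1, 2)])
        expected = sum((y == k).sum() * np.log(shares[k]) for k in (0, 1, 2))
        assert null_loglik(y) == pytest.approx(expected, abs=1e-6)


class TestLikelihoodRatio:
    def test_comparison_statistics(self, compact_scenario, fixed_fit, crp_fit):
        _, design, _ = compact_scenario
        comp = likelihood_ratio_test(fixed_fit, crp_fit)
        assert comp.lr_statistic == pytest.approx(2.0 * (crp_fit.llf - fixed_fit.llf))
        assert comp.lr_df == 15
        assert 0.0 <= comp.lr_p <= 1.0
        assert comp.pseudo_r2_crp >= comp.pseudo_r2_fixed
        assert comp.loglik_crp >= comp.loglik_fixed >= comp.null_loglik

    def test_negative_statistic_is_error(self, fixed_fit, crp_fit):
        worse = OrderedLogitResults(
            model=fixed_fit.model,
            params=fixed_fit.params,
            llf=crp_fit.llf + 5.0,
            hessian=fixed_fit.hessian,
            converged=True,
            grad_norm=0.0,
            n_iter=0,
        )
        with pytest.raises(ValueError):
            likelihood_ratio_test(worse, crp_fit)

    def test_to_frame_layout(self, fixed_fit, crp_fit):
        comp = likelihood_ratio_test(fixed_fit, crp_fit)
        frame = comp.to_frame()
        assert list(frame.columns) == ["statistic", "value"]
        assert frame.shape[0] == 8
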