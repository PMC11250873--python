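"""Correlated random-parameters model: draws, simulated likelihood, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dwscrash.crp import (
    CorrelatedRandomParamsOrderedLogit,
    CRPSpec,
    draw_coefficients,
    fit_crp,
    random_param_covariance,
    simulated_loglik,
)
from dwscrash.data import DesignMatrix
from dwscrash.halton import DrawMatrix, halton_normal_draws
from dwscrash.ordinal import OrderedLogit
from dwscrash.simulate import generate_scenario, recovery_scenario, scenario_design


def _small_problem(rng, n=60, nr=2):
    Xf = np.column_stack([np.ones(n), rng.normal(size=n)])
    Xr = rng.integers(0, 2, size=(n, nr)).astype(float)
    y = rng.integers(0, 3, size=n)
    return y, Xf, Xr


class TestDrawCoefficients:
    def test_zero_factor_collapses_to_means(self):
        draws = halton_normal_draws(4, 3, 5)
        means = np.array([0.5, -1.0, 2.0])
        coefs = draw_coefficients(means, np.zeros((3, 3)), draws)
        assert np.allclose(coefs, means)

    def test_identity_factor_unit_propagation(self):
        values = np.zeros((1, 1, 2))
        values[0, 0] = [1.0, 0.0]
        draws = DrawMatrix(values=values, primes=(2, 3), discard=0)
        coefs = draw_coefficients(np.array([0.3, 0.7]), np.eye(2), draws)
        assert np.allclose(coefs[0, 0], [1.3, 0.7])

    def test_sample_covariance_matches_omega_omega_t(self, rng):
        omega = np.array([[0.8, 0.0], [0.5, 0.6]])
        phi = rng.standard_normal((1, 100_000, 2))
        draws = DrawMatrix(values=phi, primes=(2, 3), discard=0)
        coefs = draw_coefficients(np.zeros(2), omega, draws)[0]
        emp = np.cov(coefs.T)
        assert np.allclose(emp, omega @ omega.T, atol=0.02)

    def test_dimension_mismatch_is_error(self):
        draws = halton_normal_draws(2, 2, 3)
        with pytest.raises(ValueError):
            draw_coefficients(np.zeros(3), np.eye(3), draws)


class TestSimulatedLoglik:
    @pytest.mark.parametrize("D", [1, 10, 900])
    def test_nesting_identity_at_zero_omega(self, rng, D):
        y, Xf, Xr = _small_problem(rng)
        fixed = OrderedLogit(y, np.hstack([Xf, Xr]))
        beta = np.array([0.2, -0.4, 0.5, -0.1])
        psi1 = 1.3
        ll_fixed = fixed.loglike(np.append(beta, np.log(psi1)))
        m = CorrelatedRandomParamsOrderedLogit(y, Xf, Xr, D=D)
        ll_sim = m.loglike(m.pack(beta[:2], beta[2:], np.zeros((2, 2)), psi1))
        assert ll_sim == pytest.approx(ll_fixed, abs=1e-10)

    def test_permutation_invariance(self, rng):
        y, Xf, Xr = _small_problem(rng)
        m = CorrelatedRandomParamsOrderedLogit(y, Xf, Xr, D=25)
        params = m.pack([0.1, 0.2], [0.3, -0.2], [[0.5, 0], [0.2, 0.4]], 1.1)
        ll = m.loglike(params)
        perm = rng.permutation(len(y))
        draws_perm = DrawMatrix(
            values=m.draws.values[perm], primes=m.draws.primes, discard=m.draws.discard
        )
        m2 = CorrelatedRandomParamsOrderedLogit(y[perm], Xf[perm], Xr[perm], draws=draws_perm)
        assert m2.loglike(params) == pytest.approx(ll, rel=1e-14)

    def test_column_sign_flip_with_draws_is_exact(self, rng):
        y, Xf, Xr = _small_problem(rng)
        m = CorrelatedRandomParamsOrderedLogit(y, Xf, Xr, D=40)
        omega = np.array([[-0.5, 0.0], [0.3, 0.4]])
        params = m.pack([0.1, 0.2], [0.3, -0.2], omega, 1.1)
        ll = m.loglike(params)
        flipped = m._normalize_signs(params)
        _, _, omega_after, _ = m.unpack(flipped)
        assert omega_after[0, 0] > 0
        assert m.loglike(flipped) == ll  # bit-identical by construction

    def test_stabilizes_as_draws_double(self, rng):
        y, Xf, Xr = _small_problem(rng, n=40, nr=1)
        diffs = []
        prev = None
        for D in (50, 100, 200, 400, 800):
            m = CorrelatedRandomParamsOrderedLogit(y, Xf, Xr, D=D)
            ll = m.loglike(m.pack([0.2, -0.4], [0.5], [[0.8]], 1.3))
            if prev is not None:
                diffs.append(abs(ll - prev))
            prev = ll
        assert diffs[-1] < diffs[0]

    def test_gauss_hermite_quadrature_oracle(self, rng):
        from scipy.special import expit, roots_hermitenorm

        y, Xf, Xr = _small_problem(rng, n=50, nr=1)
        beta_f, b_r, omega, psi1 = np.array([0.2, -0.4]), np.array([0.5]), 0.8, 1.3
        m = CorrelatedRandomParamsOrderedLogit(y, Xf, Xr, D=5000)
        ll_obs = m.loglike_obs(m.pack(beta_f, b_r, [[omega]], psi1))
        nodes, w = roots_hermitenorm(50)
        w = w / w.sum()
        eta0 = Xf @ beta_f
        upper = np.where(y == 0, 0.0, np.where(y == 1, psi1, np.inf))
        lower = np.where(y == 0, -np.inf, np.where(y == 1, 0.0, psi1))
        probs = np.zeros(len(y))
        for t, wt in zip(nodes, w):
            eta = eta0 + Xr[:, 0] * (b_r[0] + omega * t)
            probs += wt * (expit(upper - eta) - expit(lower - eta))
        assert np.max(np.abs(ll_obs - np.log(probs))) < 1e-3

    def test_analytic_score_matches_finite_differences(self, rng):
        from dwscrash._numdiff import gradient_fd

        y, Xf, Xr = _small_problem(rng)
        m = CorrelatedRandomParamsOrderedLogit(y, Xf, Xr, D=20)
        params = m.pack([0.1, 0.2], [0.3, -0.2], [[0.5, 0], [0.2, 0.4]], 1.1)
        assert m.score(params) == pytest.approx(gradient_fd(m.loglike, params), abs=1e-5)

    def test_convenience_wrapper_matches_model(self, compact_scenario):
        config, design, _ = compact_scenario
        draws = halton_normal_draws(design.n_rows, 5, 30)
        ll = simulated_loglik(
            np.zeros(len(design.fixed_columns)), np.zeros(5), np.zeros((5, 5)), 1.5,
            design, draws,
        )
        fixed = OrderedLogit.from_design(design)
        beta = np.zeros(design.n_cols)
        assert ll == pytest.approx(fixed.loglike(np.append(beta, np.log(1.5))), abs=1e-10)


class TestFitCrp:
    def test_converged_and_dominates_fixed(self, compact_scenario, fixed_fit, crp_fit):
        assert crp_fit.converged
        assert crp_fit.llf >= fixed_fit.llf
        assert crp_fit.psi1 > 0
        assert np.all(np.diag(crp_fit.cholesky.to_numpy()) >= 0)

    def test_reported_llf_consistent_with_params(self, crp_fit):
        assert crp_fit.model.loglike(crp_fit.params) == pytest.approx(crp_fit.llf)

    def test_table_layout_blocks(self, crp_fit):
        table = crp_fit.to_frame()
        blocks = table["block"].tolist()
        assert blocks.count("mean of random parameter") == 5
        assert blocks.count("diagonal Cholesky") == 5
        assert blocks.count("below-diagonal Cholesky") == 10
        assert blocks[-1] == "threshold"

    def test_null_omega_data_rarely_significant(self):
        """With truth Omega = 0, fitted Cholesky elements should be noise."""
        n_insig = 0
        n_elem = 0
        lr_rejections = 0
        reps = 12
        for rep in range(reps):
            rng = np.random.default_rng(3000 + rep)
            n = 500
            Xf = np.column_stack([np.ones(n), rng.normal(size=n)])
            Xr = rng.integers(0, 2, size=(n, 2)).astype(float)
            beta = np.array([-0.2, 0.3])
            b_r = np.array([0.4, -0.3])
            latent = Xf @ beta + Xr @ b_r + rng.logistic(size=n)
            y = np.where(latent <= 0, 0, np.where(latent <= 1.2, 1, 2))
            m = CorrelatedRandomParamsOrderedLogit(y, Xf, Xr, D=40)
            res = m.fit(gtol=1e-3)
            fixed_res = m._fixed_model().fit()
            lr = max(2.0 * (res.llf - fixed_res.llf), 0.0)
            lr_rejections += stats.chi2.sf(lr, 3) < 0.05
            chol_p = res.pvalues[m.n_fixed + m.n_random : m.n_fixed + m.n_random + m.n_chol]
            chol_p = chol_p[np.isfinite(chol_p)]
            n_insig += int((chol_p > 0.05).sum())
            n_elem += chol_p.size
        assert n_insig / n_elem >= 0.75
        assert lr_rejections / reps <= 0.25


class TestRandomParamCovariance:
    def test_hand_computed_two_by_two(self, crp_fit):
        omega = np.array([[1.0, 0.0], [1.0, 1.0]])
        sigma = omega @ omega.T
        assert np.allclose(sigma, [[1.0, 1.0], [1.0, 2.0]])
        corr = sigma / np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
        assert corr[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_fit_covariance_consistent(self, crp_fit):
        out = random_param_covariance(crp_fit)
        omega = crp_fit.cholesky.to_numpy()
        assert np.allclose(out["covariance"].to_numpy(), omega @ omega.T)
        corr = out["correlation"].to_numpy()
        finite = np.isfinite(corr)
        assert np.all(corr[finite] <= 1.0 + 1e-12)
        assert np.all(corr[finite] >= -1.0 - 1e-12)
        assert out["cholesky_elements"].shape[0] == 15

    def test_diagonal_omega_gives_zero_correlations(self):
        omega = np.diag([0.5, 0.8, 0.3])
        sigma = omega @ omega.T
        corr = sigma / np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
        assert np.allclose(corr, np.eye(3))


def test_spec_validation():
    with pytest.raises(ValueError):
        CRPSpec(random_columns=())
    with pytest.raises(ValueError):
        CRPSpec(random_columns=("a",), D=0)


def test_fit_crp_unknown_random_column(compact_scenario):
    _, design, _ = compact_scenario
    with pytest.raises(ValueError):
        fit_crp(design, CRPSpec(random_columns=("nonexistent",), D=10))
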