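"""Correlated random-parameters ordered logit via simulated maximum likelihood.

Driver-behaviour covariates (drinking, gender, age bands) plausibly act
differently on different drivers.  The model lets their coefficients vary
across observations as beta_i = b + Omega * phi_i, where phi_i is a vector
of independent standard normals and Omega is an unrestricted lower-triangular
Cholesky factor, so beta_i ~ N(b, Omega Omega').  Off-diagonal elements of
Omega induce correlation between the random coefficients — the feature that
distinguishes this model from an uncorrelated random-parameters one.

The per-observation likelihood integrates the ordered-logit probability over
the mixing distribution; that integral is simulated as the average over D
Halton draws (deterministic quasi-random points; D = 900 by default, after
published practice).  The simulated log-likelihood

    LL = sum_i ln[ (1/D) sum_d P_i(y_i | beta_i^{(d)}) ]

is maximized by BFGS with the analytic score, then Newton-polished.  Omega
is optimized unconstrained; afterwards columns are sign-normalized so the
reported diagonal is nonnegative (Omega and Omega with a negated column
imply the same covariance).  The matching draw dimension is negated with it,
which leaves the simulated log-likelihood exactly unchanged at finite D.

At Omega = 0 the simulated likelihood collapses to the fixed-parameter
ordered logit for every D, which is the nesting identity used by the
likelihood-ratio comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from ._numdiff import hessian_from_score
from .data import DesignMatrix
from .halton import DrawMatrix, halton_normal_draws
from .ordinal import ConvergenceError, OrderedLogit, _cell_bounds

__all__ = [
    "CRPSpec",
    "CorrelatedRandomParamsOrderedLogit",
    "CRPResults",
    "draw_coefficients",
    "simulated_loglik",
    "fit_crp",
    "random_param_covariance",
]

_PFLOOR = 1e-300


@dataclass(frozen=True)
class CRPSpec:
    """Configuration of the random-coefficient block and its draws."""

    random_columns: tuple[str, ...]
    D: int = 900
    primes: tuple[int, ...] | None = None
    discard: int = 10

    def __post_init__(self):
        if not self.random_columns:
            raise ValueError("random_columns must be non-empty")
        if self.D < 1:
            raise ValueError("D must be >= 1")


def draw_coefficients(
    random_means: np.ndarray, cholesky: np.ndarray, draws: DrawMatrix
) -> np.ndarray:
    """Per-observation, per-draw coefficients beta_i^(d) = b + Omega phi_i^(d).

    Returns an (n_obs, D, n_r) array.
    """
    b = np.asarray(random_means, float)
    omega = np.asarray(cholesky, float)
    if omega.shape != (b.shape[0], b.shape[0]) or draws.n_dims != b.shape[0]:
        raise ValueError("random_means, cholesky and draws dimensions disagree")
    return b + draws.values @ omega.T


class CorrelatedRandomParamsOrderedLogit:
    """Simulated-ML ordered logit with correlated normal random coefficients.

    Parameters are packed as ``[beta_fixed, random_means, omega_tril, delta]``
    with ``psi1 = exp(delta)`` and ``omega_tril`` the row-major lower triangle
    of the Cholesky factor.
    """

    def __init__(
        self,
        endog,
        exog_fixed,
        exog_random,
        draws: DrawMatrix | None = None,
        D: int = 900,
        primes: tuple[int, ...] | None = None,
        discard: int = 10,
        fixed_names: list[str] | None = None,
        random_names: list[str] | None = None,
    ):
        self.endog = np.asarray(endog, int)
        if isinstance(exog_fixed, pd.DataFrame):
            fixed_names = list(exog_fixed.columns)
            exog_fixed = exog_fixed.to_numpy(float)
        if isinstance(exog_random, pd.DataFrame):
            random_names = list(exog_random.columns)
            exog_random = exog_random.to_numpy(float)
        self.exog_fixed = np.asarray(exog_fixed, float)
        self.exog_random = np.asarray(exog_random, float)
        n = self.endog.shape[0]
        if self.exog_fixed.shape[0] != n or self.exog_random.shape[0] != n:
            raise ValueError("endog and exog row counts differ")
        self.fixed_names = fixed_names or [f"xf{j}" for j in range(self.exog_fixed.shape[1])]
        self.random_names = random_names or [f"xr{j}" for j in range(self.exog_random.shape[1])]
        nr = self.exog_random.shape[1]
        if draws is None:
            draws = halton_normal_draws(n, nr, D, discard=discard, primes=primes)
        if draws.n_obs != n or draws.n_dims != nr:
            raise ValueError("draws shape does not match the design")
        self.draws = draws
        #: per-dimension sign applied to the draws (set by sign normalization)
        self.draw_signs = np.ones(nr)
        self._tril = np.tril_indices(nr)
        self._cache: tuple[bytes, tuple] | None = None
        self.n_floored_last = 0

    # -- parameter packing --------------------------------------------------

    @property
    def n_fixed(self) -> int:
        return self.exog_fixed.shape[1]

    @property
    def n_random(self) -> int:
        return self.exog_random.shape[1]

    @property
    def n_chol(self) -> int:
        nr = self.n_random
        return nr * (nr + 1) // 2

    @property
    def k_params(self) -> int:
        return self.n_fixed + self.n_random + self.n_chol + 1

    def unpack(self, params):
        params = np.asarray(params, float)
        pf, nr = self.n_fixed, self.n_random
        beta_f = params[:pf]
        b_r = params[pf : pf + nr]
        omega = np.zeros((nr, nr))
        omega[self._tril] = params[pf + nr : pf + nr + self.n_chol]
        psi1 = np.exp(params[-1])
        return beta_f, b_r, omega, psi1

    def pack(self, beta_f, b_r, omega, psi1) -> np.ndarray:
        omega = np.asarray(omega, float)
        return np.concatenate(
            [
                np.asarray(beta_f, float),
                np.asarray(b_r, float),
                omega[self._tril],
                [np.log(psi1)],
            ]
        )

    @property
    def param_names(self) -> list[str]:
        names = list(self.fixed_names) + [f"mean:{r}" for r in self.random_names]
        for j, l in zip(*self._tril):
            if j == l:
                names.append(f"chol:{self.random_names[j]}")
            else:
                names.append(f"chol:{self.random_names[j]} - {self.random_names[l]}")
        return names + ["log_psi1"]

    # -- simulated likelihood ----------------------------------------------

    def _phi(self) -> np.ndarray:
        return self.draws.values * self.draw_signs

    def _eval(self, params):
        """Simulated log-likelihood, per-observation terms and analytic score."""
        key = np.asarray(params, float).tobytes()
        if self._cache is not None and self._cache[0] == key:
            return self._cache[1]

        beta_f, b_r, omega, psi1 = self.unpack(params)
        phi = self._phi()
        n, D = self.endog.shape[0], self.draws.D

        base = self.exog_fixed @ beta_f
        coefs = b_r + phi @ omega.T  # (n, D, nr)
        eta = base[:, None] + np.einsum("nr,ndr->nd", self.exog_random, coefs)

        upper, lower = _cell_bounds(self.endog, psi1)
        eu = expit(upper[:, None] - eta)
        el = expit(lower[:, None] - eta)
        fu = eu * (1.0 - eu)
        fl = el * (1.0 - el)
        p_draw = eu - el  # (n, D)

        p_mean = p_draw.mean(axis=1)
        floored = p_mean < _PFLOOR
        self.n_floored_last = int(floored.sum())
        p_mean = np.maximum(p_mean, _PFLOOR)
        ll_obs = np.log(p_mean)
        ll = float(ll_obs.sum())

        w = 1.0 / (D * p_mean)  # (n,)
        a = fl - fu  # dP/deta per draw
        s_a = a.sum(axis=1)  # (n,)
        g_fixed = self.exog_fixed.T @ (w * s_a)
        g_means = (self.exog_random * (w * s_a)[:, None]).sum(axis=0)
        b_mat = np.einsum("nd,ndl->nl", a, phi)  # (n, nr)
        m = (self.exog_random * w[:, None]).T @ b_mat  # (nr, nr): [j, l]
        g_omega = m[self._tril]
        at_upper = (self.endog == 1).astype(float)
        at_lower = (self.endog == 2).astype(float)
        g_delta = psi1 * float(
            np.sum(w * (at_upper * fu.sum(axis=1) - at_lower * fl.sum(axis=1)))
        )
        grad = np.concatenate([g_fixed, g_means, g_omega, [g_delta]])

        out = (ll, grad, ll_obs)
        self._cache = (key, out)
        return out

    def loglike(self, params) -> float:
        return self._eval(params)[0]

    def score(self, params) -> np.ndarray:
        return self._eval(params)[1]

    def loglike_obs(self, params) -> np.ndarray:
        return self._eval(params)[2]

    # -- estimation ---------------------------------------------------------

    def _fixed_model(self) -> OrderedLogit:
        X = np.hstack([self.exog_fixed, self.exog_random])
        return OrderedLogit(self.endog, X, names=list(self.fixed_names) + list(self.random_names))

    def fit(
        self,
        start_params=None,
        start_omega_scale: float = 0.1,
        gtol: float = 1e-5,
        maxiter: int = 1000,
        compute_cov: bool = True,
        raise_on_fail: bool = False,
    ) -> "CRPResults":
        """Maximize the simulated log-likelihood.

        Initialization uses the nested fixed-parameter fit for the means and
        ``start_omega_scale`` times the identity for the Cholesky factor.
        """
        fixed_res = None
        if start_params is None:
            fixed_res = self._fixed_model().fit()
            beta_all = fixed_res.params[:-1]
            start_params = self.pack(
                beta_all[: self.n_fixed],
                beta_all[self.n_fixed :],
                start_omega_scale * np.eye(self.n_random),
                np.exp(fixed_res.params[-1]),
            )
        x0 = np.asarray(start_params, float)

        res = optimize.minimize(
            lambda p: -self.loglike(p),
            x0,
            jac=lambda p: -self.score(p),
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        params, n_iter = res.x, res.nit
        params, polish_iter = self._newton_polish(params, gtol)

        params = self._normalize_signs(params)
        grad = self.score(params)
        grad_norm = float(np.max(np.abs(grad)))
        converged = grad_norm < gtol
        if not converged and raise_on_fail:
            raise ConvergenceError(
                f"gradient inf-norm {grad_norm:.2e} above {gtol:.0e} after "
                f"{n_iter}+{polish_iter} iterations"
            )
        hess = (
            hessian_from_score(self.score, params)
            if compute_cov
            else np.full((self.k_params,) * 2, np.nan)
        )
        return CRPResults(
            model=self,
            params=params,
            llf=self.loglike(params),
            hessian=hess,
            converged=converged,
            grad_norm=grad_norm,
            n_iter=n_iter + polish_iter,
            draw_signs=self.draw_signs.copy(),
            llf_fixed_start=None if fixed_res is None else fixed_res.llf,
            n_floored=self.n_floored_last,
        )

    def _newton_polish(self, params, gtol, maxiter: int = 15):
        ll = self.loglike(params)
        for it in range(maxiter):
            g = self.score(params)
            if np.max(np.abs(g)) < gtol:
                return params, it
            H = hessian_from_score(self.score, params)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            scale = 1.0
            for _ in range(30):
                trial = params - scale * step
                if self.loglike(trial) >= ll - 1e-10:
                    params, ll = trial, self.loglike(trial)
                    break
                scale *= 0.5
            else:
                return params, it
        return params, maxiter

    def _normalize_signs(self, params) -> np.ndarray:
        """Flip Cholesky columns with negative diagonal, and their draws.

        (Omega S)(S phi) = Omega phi exactly, so the simulated likelihood is
        bit-identical after normalization.
        """
        beta_f, b_r, omega, psi1 = self.unpack(params)
        for l in range(self.n_random):
            if omega[l, l] < 0:
                omega[:, l] = -omega[:, l]
                self.draw_signs[l] = -self.draw_signs[l]
        self._cache = None
        return self.pack(beta_f, b_r, omega, psi1)

    # -- prediction ---------------------------------------------------------

    def predict(self, params, exog_fixed=None, exog_random=None, draws=None) -> np.ndarray:
        """Simulated three-category probabilities per row.

        With ``exog`` overrides, ``draws`` must cover the new rows (default:
        a fresh Halton matrix with this model's draw configuration).
        """
        beta_f, b_r, omega, psi1 = self.unpack(params)
        Xf = self.exog_fixed if exog_fixed is None else np.atleast_2d(np.asarray(exog_fixed, float))
        Xr = self.exog_random if exog_random is None else np.atleast_2d(np.asarray(exog_random, float))
        if draws is None:
            if exog_fixed is None:
                draws = self.draws
                phi = self._phi()
            else:
                draws = halton_normal_draws(
                    Xf.shape[0], self.n_random, self.draws.D,
                    discard=self.draws.discard, primes=self.draws.primes,
                )
                phi = draws.values
        else:
            phi = draws.values
        coefs = b_r + phi @ omega.T
        eta = (Xf @ beta_f)[:, None] + np.einsum("nr,ndr->nd", Xr, coefs)
        p_le0 = expit(-eta)
        p_le1 = expit(psi1 - eta)
        probs = np.stack([p_le0, p_le1 - p_le0, 1.0 - p_le1], axis=-1)
        return probs.mean(axis=1)


@dataclass
class CRPResults:
    """Estimates and diagnostics of a fitted correlated random-parameters model."""

    model: CorrelatedRandomParamsOrderedLogit
    params: np.ndarray
    llf: float
    hessian: np.ndarray
    converged: bool
    grad_norm: float
    n_iter: int
    draw_signs: np.ndarray
    llf_fixed_start: float | None = None
    n_floored: int = 0
    cov_params: np.ndarray = field(init=False)

    def __post_init__(self):
        try:
            self.cov_params = np.linalg.inv(-self.hessian)
        except np.linalg.LinAlgError:
            self.cov_params = np.full_like(self.hessian, np.nan)

    @property
    def fixed_params(self) -> pd.Series:
        return pd.Series(self.params[: self.model.n_fixed], index=self.model.fixed_names)

    @property
    def random_means(self) -> pd.Series:
        m = self.model
        return pd.Series(
            self.params[m.n_fixed : m.n_fixed + m.n_random], index=m.random_names
        )

    @property
    def cholesky(self) -> pd.DataFrame:
        _, _, omega, _ = self.model.unpack(self.params)
        return pd.DataFrame(omega, index=self.model.random_names, columns=self.model.random_names)

    @property
    def random_cov(self) -> pd.DataFrame:
        """Implied random-coefficient covariance Omega Omega'."""
        omega = self.cholesky.to_numpy()
        return pd.DataFrame(
            omega @ omega.T, index=self.model.random_names, columns=self.model.random_names
        )

    @property
    def random_corr(self) -> pd.DataFrame:
        sigma = self.random_cov.to_numpy()
        sd = np.sqrt(np.diag(sigma))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = sigma / np.outer(sd, sd)
        return pd.DataFrame(corr, index=self.model.random_names, columns=self.model.random_names)

    @property
    def psi1(self) -> float:
        return float(np.exp(self.params[-1]))

    @property
    def psi1_se(self) -> float:
        with np.errstate(invalid="ignore"):
            return float(self.psi1 * np.sqrt(self.cov_params[-1, -1]))

    @property
    def cov_ok(self) -> bool:
        """False when the Hessian was near-singular (flagged standard errors)."""
        return bool(np.all(np.diag(self.cov_params) > 0))

    @property
    def bse(self) -> np.ndarray:
        # NaN (flagged) where the inverse Hessian has a nonpositive diagonal
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def nobs(self) -> int:
        return self.model.endog.shape[0]

    @property
    def D(self) -> int:
        return self.model.draws.D

    def predict(self, exog_fixed=None, exog_random=None, draws=None) -> np.ndarray:
        return self.model.predict(self.params, exog_fixed, exog_random, draws)

    def diag_cov_se(self) -> pd.Series:
        """Delta-method standard errors of the Omega Omega' diagonal."""
        m = self.model
        omega = self.cholesky.to_numpy()
        ses = []
        off = m.n_fixed + m.n_random
        tril_j, tril_l = m._tril
        for r in range(m.n_random):
            grad = np.zeros(self.params.shape[0])
            for pos, (j, l) in enumerate(zip(tril_j, tril_l)):
                if j == r:
                    grad[off + pos] = 2.0 * omega[j, l]
            ses.append(float(np.sqrt(grad @ self.cov_params @ grad)))
        return pd.Series(ses, index=m.random_names)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table in the published layout.

        Blocks: fixed coefficients, means of random parameters, diagonal
        Cholesky elements, below-diagonal Cholesky elements, threshold.
        """
        m = self.model
        rows = []
        names = self.param_block_labels()
        coefs = np.append(self.params[:-1], self.psi1)
        ses = np.append(self.bse[:-1], self.psi1_se)
        z = coefs / ses
        p = 2.0 * stats.norm.sf(np.abs(z))
        blocks = (
            ["fixed"] * m.n_fixed
            + ["mean of random parameter"] * m.n_random
            + [
                "diagonal Cholesky" if j == l else "below-diagonal Cholesky"
                for j, l in zip(*m._tril)
            ]
            + ["threshold"]
        )
        for name, block, c, s, zz, pp in zip(names, blocks, coefs, ses, z, p):
            rows.append((name, block, c, s, zz, pp))
        return pd.DataFrame(
            rows,
            columns=["variable", "block", "coefficient", "std_error", "z_value", "p_value"],
        )

    def param_block_labels(self) -> list[str]:
        m = self.model
        labels = list(m.fixed_names) + list(m.random_names)
        for j, l in zip(*m._tril):
            if j == l:
                labels.append(m.random_names[j])
            else:
                labels.append(f"{m.random_names[j]} - {m.random_names[l]}")
        return labels + ["threshold_psi1"]

    def summary(self) -> str:
        lines = [
            "Correlated random parameters ordered logit (simulated ML)",
            f"  n = {self.nobs}, D = {self.D} Halton draws "
            f"(primes {self.model.draws.primes}, discard {self.model.draws.discard})",
            f"  simulated log-likelihood = {self.llf:.3f}",
            f"  converged = {self.converged} (grad inf-norm {self.grad_norm:.2e}, "
            f"{self.n_iter} iterations)",
        ]
        if self.n_floored:
            lines.append(f"  WARNING: {self.n_floored} observations hit the probability floor")
        lines += ["", self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}")]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# operation-style conveniences

def simulated_loglik(
    fixed_beta, random_means, cholesky, psi1: float, design: DesignMatrix, draws: DrawMatrix
) -> float:
    """Simulated log-likelihood at explicit parameter values."""
    model = CorrelatedRandomParamsOrderedLogit(
        design.outcome,
        design.X[design.fixed_columns],
        design.X[design.random_columns],
        draws=draws,
    )
    return model.loglike(model.pack(fixed_beta, random_means, cholesky, psi1))


def fit_crp(design: DesignMatrix, spec: CRPSpec | None = None, **fit_kwargs) -> CRPResults:
    """Fit the correlated random-parameters model to an encoded design."""
    if spec is None:
        spec = CRPSpec(random_columns=tuple(design.random_columns))
    missing = [c for c in spec.random_columns if c not in design.X.columns]
    if missing:
        raise ValueError(f"random columns absent from design: {missing}")
    fixed_cols = [c for c in design.X.columns if c not in spec.random_columns]
    model = CorrelatedRandomParamsOrderedLogit(
        design.outcome,
        design.X[fixed_cols],
        design.X[list(spec.random_columns)],
        D=spec.D,
        primes=spec.primes,
        discard=spec.discard,
    )
    return model.fit(**fit_kwargs)


def random_param_covariance(results: CRPResults) -> dict[str, pd.DataFrame]:
    """Implied covariance/correlation of the random coefficients.

    Also returns the Cholesky-element table with z and p values carried from
    the fit, for judging which correlations are statistically supported.
    """
    table = results.to_frame()
    chol_rows = table[table["block"].str.contains("Cholesky")].reset_index(drop=True)
    return {
        "covariance": results.random_cov,
        "correlation": results.random_corr,
        "cholesky_elements": chol_rows,
    }
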