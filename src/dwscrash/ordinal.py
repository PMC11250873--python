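"""Fixed-parameter ordered logit for the warning-system count.

The observed count Y_i in {0, 1, 2} is driven by a latent propensity
Y*_i = beta' X_i + eps_i with standard-logistic error, cut by thresholds
(-inf, 0, psi_1, +inf): Y = 0 if Y* <= 0, Y = 1 if 0 < Y* <= psi_1, else 2.
An intercept is estimated and the first threshold is fixed at zero for
identification; psi_1 is optimized on the log scale (psi_1 = exp(delta)) to
enforce positivity and reported on the natural scale with a delta-method
standard error.

Estimation is quasi-Newton (BFGS with the analytic score) followed by Newton
polishing with a finite-difference Hessian of the score until the gradient
infinity-norm falls below 1e-6.  This model is both the baseline reported
alongside the correlated random-parameters model and its nested null
(zero Cholesky factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from ._numdiff import hessian_from_score
from .data import DesignMatrix

__all__ = [
    "ConvergenceError",
    "OrderedLogit",
    "OrderedLogitResults",
    "fixed_loglik",
    "fit_fixed",
    "predict_probs",
]

_PFLOOR = 1e-300


class ConvergenceError(RuntimeError):
    """Raised when an optimizer fails to reach the gradient tolerance."""


def _cell_bounds(outcome: np.ndarray, psi1: float):
    """Upper/lower latent thresholds (psi_{k}, psi_{k-1}) per observation."""
    upper = np.where(outcome == 0, 0.0, np.where(outcome == 1, psi1, np.inf))
    lower = np.where(outcome == 0, -np.inf, np.where(outcome == 1, 0.0, psi1))
    return upper, lower


class OrderedLogit:
    """Ordered logit model with thresholds (-inf, 0, psi1, +inf).

    Parameters
    ----------
    endog : array of int in {0, 1, 2}
        Ordinal outcome per observation.
    exog : DataFrame or 2-D array
        Design matrix including the intercept column.

    The parameter vector is ``[beta, delta]`` with ``psi1 = exp(delta)``.
    """

    def __init__(self, endog, exog, names: list[str] | None = None):
        self.endog = np.asarray(endog, int)
        if isinstance(exog, pd.DataFrame):
            names = list(exog.columns)
            exog = exog.to_numpy(float)
        self.exog = np.asarray(exog, float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be 2-D with one row per outcome")
        self.names = names or [f"x{j}" for j in range(self.exog.shape[1])]
        if not set(np.unique(self.endog)) <= {0, 1, 2}:
            raise ValueError("endog values must lie in {0, 1, 2}")

    @classmethod
    def from_design(cls, design: DesignMatrix) -> "OrderedLogit":
        return cls(design.outcome, design.X)

    @property
    def k_params(self) -> int:
        return self.exog.shape[1] + 1

    # -- likelihood ---------------------------------------------------------

    def _unpack(self, params):
        params = np.asarray(params, float)
        return params[:-1], np.exp(params[-1])

    def loglike_obs(self, params) -> np.ndarray:
        beta, psi1 = self._unpack(params)
        eta = self.exog @ beta
        upper, lower = _cell_bounds(self.endog, psi1)
        prob = expit(upper - eta) - expit(lower - eta)
        return np.log(np.maximum(prob, _PFLOOR))

    def loglike(self, params) -> float:
        return float(self.loglike_obs(params).sum())

    def score(self, params) -> np.ndarray:
        beta, psi1 = self._unpack(params)
        eta = self.exog @ beta
        upper, lower = _cell_bounds(self.endog, psi1)
        eu, el = expit(upper - eta), expit(lower - eta)
        fu, fl = eu * (1.0 - eu), el * (1.0 - el)
        prob = np.maximum(eu - el, _PFLOOR)
        g_beta = self.exog.T @ ((fl - fu) / prob)
        at_upper = (self.endog == 1).astype(float)
        at_lower = (self.endog == 2).astype(float)
        g_delta = psi1 * np.sum((at_upper * fu - at_lower * fl) / prob)
        return np.append(g_beta, g_delta)

    # -- estimation ---------------------------------------------------------

    def _start_params(self) -> np.ndarray:
        shares = np.array([(self.endog == k).mean() for k in (0, 1, 2)])
        shares = np.clip(shares, 1e-3, None)
        shares /= shares.sum()
        beta = np.zeros(self.exog.shape[1])
        b0 = -float(np.log(shares[0] / (1 - shares[0])))
        psi1 = float(np.log((shares[0] + shares[1]) / shares[2])) + b0
        if "const" in self.names:
            beta[self.names.index("const")] = b0
        return np.append(beta, np.log(max(psi1, 0.1)))

    def fit(
        self,
        start_params=None,
        gtol: float = 1e-6,
        maxiter: int = 500,
        raise_on_fail: bool = False,
    ) -> "OrderedLogitResults":
        """Maximize the log-likelihood; see the module docstring for the scheme."""
        x0 = np.asarray(start_params, float) if start_params is not None else self._start_params()
        res = optimize.minimize(
            lambda p: -self.loglike(p),
            x0,
            jac=lambda p: -self.score(p),
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        params, n_iter = res.x, res.nit
        params, polish_iter = self._newton_polish(params, gtol)
        grad = self.score(params)
        grad_norm = float(np.max(np.abs(grad)))
        converged = grad_norm < gtol
        if not converged and raise_on_fail:
            raise ConvergenceError(
                f"gradient inf-norm {grad_norm:.2e} above {gtol:.0e} after "
                f"{n_iter}+{polish_iter} iterations"
            )
        hess = hessian_from_score(self.score, params)
        return OrderedLogitResults(
            model=self,
            params=params,
            llf=self.loglike(params),
            hessian=hess,
            converged=converged,
            grad_norm=grad_norm,
            n_iter=n_iter + polish_iter,
        )

    def _newton_polish(self, params, gtol, maxiter: int = 50):
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
            # H should be negative definite at a maximum; ascend along -H^{-1} g
            scale = 1.0
            for _ in range(30):
                trial = params - scale * step
                ll_trial = self.loglike(trial)
                if ll_trial >= ll - 1e-10:
                    params, ll = trial, ll_trial
                    break
                scale *= 0.5
            else:
                return params, it
        return params, maxiter

    # -- prediction ---------------------------------------------------------

    def predict(self, params, exog=None) -> np.ndarray:
        """Per-row probabilities of the three outcome categories."""
        beta, psi1 = self._unpack(params)
        X = self.exog if exog is None else np.asarray(exog, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != beta.shape[0]:
            raise ValueError(
                f"exog has {X.shape[1]} columns, model expects {beta.shape[0]}"
            )
        eta = X @ beta
        p_le0 = expit(-eta)
        p_le1 = expit(psi1 - eta)
        return np.column_stack([p_le0, p_le1 - p_le0, 1.0 - p_le1])


@dataclass
class OrderedLogitResults:
    """Estimates, uncertainty and diagnostics of a fitted ordered logit."""

    model: OrderedLogit
    params: np.ndarray
    llf: float
    hessian: np.ndarray
    converged: bool
    grad_norm: float
    n_iter: int
    cov_params: np.ndarray = field(init=False)

    def __post_init__(self):
        try:
            self.cov_params = np.linalg.inv(-self.hessian)
        except np.linalg.LinAlgError:
            self.cov_params = np.full_like(self.hessian, np.nan)

    # parameterization: params = [beta..., delta], psi1 = exp(delta)
    @property
    def beta(self) -> pd.Series:
        return pd.Series(self.params[:-1], index=self.model.names)

    @property
    def psi1(self) -> float:
        return float(np.exp(self.params[-1]))

    @property
    def psi1_se(self) -> float:
        # delta method through psi1 = exp(delta)
        with np.errstate(invalid="ignore"):
            return float(self.psi1 * np.sqrt(self.cov_params[-1, -1]))

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
    def condition_number(self) -> float:
        """Condition number of the design, a multicollinearity diagnostic."""
        return float(np.linalg.cond(self.model.exog))

    def predict(self, exog=None) -> np.ndarray:
        return self.model.predict(self.params, exog)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: variable, coefficient, std error, z, p."""
        names = list(self.model.names) + ["threshold_psi1"]
        coefs = np.append(self.params[:-1], self.psi1)
        ses = np.append(self.bse[:-1], self.psi1_se)
        z = coefs / ses
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"variable": names, "coefficient": coefs, "std_error": ses, "z_value": z, "p_value": p}
        )

    def summary(self) -> str:
        table = self.to_frame()
        lines = [
            "Ordered logit (fixed parameters)",
            f"  n = {self.nobs}, log-likelihood = {self.llf:.3f}",
            f"  converged = {self.converged} (grad inf-norm {self.grad_norm:.2e}, "
            f"{self.n_iter} iterations)",
            f"  design condition number = {self.condition_number:.1f}",
            "",
            table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# operation-style conveniences

def fixed_loglik(beta, psi1: float, design: DesignMatrix) -> float:
    """Ordered-logit log-likelihood at explicit (beta, psi1)."""
    if psi1 <= 0:
        raise ValueError("psi1 must be positive")
    model = OrderedLogit.from_design(design)
    return model.loglike(np.append(np.asarray(beta, float), np.log(psi1)))


def fit_fixed(design: DesignMatrix, **kwargs) -> OrderedLogitResults:
    """Fit the fixed-parameter ordered logit to an encoded design."""
    return OrderedLogit.from_design(design).fit(**kwargs)


def predict_probs(results: OrderedLogitResults, X) -> np.ndarray:
    """Three outcome-category probabilities per row of ``X``."""
    return results.predict(X)
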