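"""Marginal effects and fit comparison for the ordinal warning-system models.

Latent-scale coefficients of an ordered logit are not directly interpretable
as probability changes, so each indicator's effect is reported as

    AME_k(v) = P(Y = k | x-bar, v = 1) - P(Y = k | x-bar, v = 0)

with the other covariates held at their sample means (the numeric year index
uses a +1 increment from its mean instead of the 0 -> 1 switch).  For the
correlated random-parameters model the probabilities are draw-averages over
the fitted mixing distribution.  Because the three category probabilities
sum to one at any covariate vector, each variable's effects across the three
categories sum to zero — a conservation identity used as a diagnostic.
An observation-averaged variant (averaging the probability difference over
sample rows rather than evaluating at the mean row) is available via
``at="observations"`` for sensitivity analysis.

Effect p-values are delta-method: the numerical gradient of each effect with
respect to the full parameter vector is propagated through the parameter
covariance.  Model comparison reports McFadden pseudo-R-squared against an
intercept-plus-threshold null and the likelihood-ratio statistic of the
correlated model against its nested fixed-parameter version (chi-square
reference with one degree of freedom per free Cholesky element; since the
null pins variance parameters at the boundary, this reference is
conservative in the rejecting direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._numdiff import gradient_fd
from .crp import CRPResults
from .data import DesignMatrix
from .halton import halton_normal_draws
from .ordinal import OrderedLogit, OrderedLogitResults

__all__ = [
    "EffectsTable",
    "FitComparison",
    "marginal_effects",
    "marginal_effect_indicator",
    "effect_pvalues",
    "mcfadden_r2",
    "null_loglik",
    "likelihood_ratio_test",
]


# ---------------------------------------------------------------------------
# probability evaluation shared by both model families

def _prob_fn(results, design: DesignMatrix, D_effects: int | None = None):
    """Return f(params, X_rows) -> (rows, 3) probabilities for the fit type."""
    if isinstance(results, CRPResults):
        m = results.model
        fixed_cols = list(m.fixed_names)
        random_cols = list(m.random_names)
        D = D_effects or max(m.draws.D, 500)
        # one deterministic draw block reused for every evaluation point, so
        # finite-difference gradients over params stay smooth
        draws = halton_normal_draws(1, m.n_random, D, discard=m.draws.discard, primes=m.draws.primes)

        def fn(params, X_rows: pd.DataFrame) -> np.ndarray:
            out = np.empty((X_rows.shape[0], 3))
            xf = X_rows[fixed_cols].to_numpy(float)
            xr = X_rows[random_cols].to_numpy(float)
            for i in range(out.shape[0]):
                out[i] = m.predict(params, xf[i : i + 1], xr[i : i + 1], draws=draws)[0]
            return out

        return fn
    if isinstance(results, OrderedLogitResults):
        cols = list(results.model.names)

        def fn(params, X_rows: pd.DataFrame) -> np.ndarray:
            return results.model.predict(params, X_rows[cols].to_numpy(float))

        return fn
    raise TypeError(f"unsupported results type {type(results).__name__}")


def _switch_rows(design: DesignMatrix, variable: str, base: pd.DataFrame):
    """(on, off) covariate rows for the 0->1 switch or the year +1 increment."""
    on, off = base.copy(), base.copy()
    if variable == "year_index":
        on["year_index"] = off["year_index"] + 1.0
        return on, off
    values = design.X[variable].to_numpy(float)
    if not set(np.unique(values)) <= {0.0, 1.0}:
        raise ValueError(
            f"{variable!r} is not an indicator column and has no increment rule"
        )
    on[variable], off[variable] = 1.0, 0.0
    return on, off


@dataclass
class EffectsTable:
    """Per-variable, per-category marginal effects with delta-method p-values."""

    table: pd.DataFrame
    at_means: pd.Series
    at: str = "means"

    def conservation_residual(self) -> float:
        """Largest |sum over categories| of any variable's effects."""
        sums = sum(self.table[f"effect_y{k}"] for k in (0, 1, 2))
        return float(np.max(np.abs(sums.to_numpy())))

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def marginal_effects(
    results,
    design: DesignMatrix,
    variables: list[str] | None = None,
    at: str = "means",
    pvalues: bool = True,
    D_effects: int | None = None,
) -> EffectsTable:
    """Marginal effects of each indicator on the three category probabilities.

    Parameters
    ----------
    results : OrderedLogitResults or CRPResults
    at : {"means", "observations"}
        Evaluate with other covariates at sample means (default, the
        reported convention) or average the probability difference over the
        sample rows.
    pvalues : bool
        Compute delta-method p-values (numerical gradient over all model
        parameters).
    """
    if variables is None:
        variables = [c for c in design.X.columns if c != "const"]
    xbar = design.X.mean()
    if at == "means":
        base = pd.DataFrame([xbar])
    elif at == "observations":
        base = design.X.copy()
    else:
        raise ValueError("at must be 'means' or 'observations'")
    fn = _prob_fn(results, design, D_effects)
    params = results.params
    cov = results.cov_params

    def effect_vec(p, variable) -> np.ndarray:
        on, off = _switch_rows(design, variable, base)
        return (fn(p, on) - fn(p, off)).mean(axis=0)

    rows = []
    for v in variables:
        eff = effect_vec(params, v)
        if pvalues:
            grads = np.empty((params.shape[0], 3))
            h = 1e-5 * np.maximum(1.0, np.abs(params))
            for j in range(params.shape[0]):
                e = np.zeros_like(params)
                e[j] = h[j]
                grads[j] = (effect_vec(params + e, v) - effect_vec(params - e, v)) / (2 * h[j])
            var = np.einsum("jk,jl,lk->k", grads, cov, grads)
            se = np.sqrt(np.maximum(var, 0.0))
            with np.errstate(invalid="ignore", divide="ignore"):
                z = eff / se
            p = 2.0 * stats.norm.sf(np.abs(z))
        else:
            p = np.full(3, np.nan)
        rows.append((v, eff[0], p[0], eff[1], p[1], eff[2], p[2]))
    table = pd.DataFrame(
        rows,
        columns=["variable", "effect_y0", "p_y0", "effect_y1", "p_y1", "effect_y2", "p_y2"],
    )
    return EffectsTable(table=table, at_means=xbar, at=at)


def marginal_effect_indicator(results, design: DesignMatrix, variable: str, k: int) -> float:
    """Effect of switching one indicator on P(Y = k), other covariates at means."""
    if k not in (0, 1, 2):
        raise ValueError("k must be 0, 1 or 2")
    et = marginal_effects(results, design, variables=[variable], pvalues=False)
    return float(et.table[f"effect_y{k}"].iloc[0])


def effect_pvalues(results, design: DesignMatrix, variables: list[str] | None = None) -> pd.DataFrame:
    """Delta-method p-values for the at-means effects (variable x category)."""
    et = marginal_effects(results, design, variables=variables, pvalues=True)
    return et.table[["variable", "p_y0", "p_y1", "p_y2"]].copy()


# ---------------------------------------------------------------------------
# fit statistics

def mcfadden_r2(loglik: float, null_loglik: float) -> float:
    """McFadden pseudo-R-squared, 1 - LL / LL_null."""
    if null_loglik >= 0:
        raise ValueError("null log-likelihood must be negative")
    if loglik < null_loglik:
        raise ValueError("model log-likelihood is below the null (misfit ordering)")
    return 1.0 - loglik / null_loglik


def null_loglik(outcome: np.ndarray) -> float:
    """Log-likelihood of the intercept-plus-threshold-only ordered logit.

    The null fit is saturated in the category shares, so its likelihood is
    the multinomial log-likelihood of the empirical shares.
    """
    outcome = np.asarray(outcome, int)
    res = OrderedLogit(outcome, np.ones((outcome.shape[0], 1)), names=["const"]).fit()
    return res.llf


@dataclass
class FitComparison:
    """Nested comparison between the fixed and correlated models."""

    loglik_fixed: float
    loglik_crp: float
    null_loglik: float
    pseudo_r2_fixed: float
    pseudo_r2_crp: float
    lr_statistic: float
    lr_df: int
    lr_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "loglik_fixed",
                    "loglik_crp",
                    "null_loglik",
                    "pseudo_r2_fixed",
                    "pseudo_r2_crp",
                    "lr_statistic",
                    "lr_df",
                    "lr_p",
                ],
                "value": [
                    self.loglik_fixed,
                    self.loglik_crp,
                    self.null_loglik,
                    self.pseudo_r2_fixed,
                    self.pseudo_r2_crp,
                    self.lr_statistic,
                    self.lr_df,
                    self.lr_p,
                ],
            }
        )


def likelihood_ratio_test(fixed: OrderedLogitResults, crp: CRPResults) -> FitComparison:
    """Compare the correlated model against its nested fixed-parameter version.

    The statistic is 2 (LL_crp - LL_fixed) on as many degrees of freedom as
    there are free Cholesky elements.  A negative statistic means the richer
    model failed to reach its nested optimum and is reported as an error.
    """
    if fixed.nobs != crp.nobs:
        raise ValueError("fits use different samples")
    lr = 2.0 * (crp.llf - fixed.llf)
    if lr < 0:
        raise ValueError(
            f"negative LR statistic ({lr:.3f}): the correlated fit did not converge"
        )
    df = crp.model.n_chol
    ll0 = null_loglik(crp.model.endog)
    return FitComparison(
        loglik_fixed=fixed.llf,
        loglik_crp=crp.llf,
        null_loglik=ll0,
        pseudo_r2_fixed=mcfadden_r2(fixed.llf, ll0),
        pseudo_r2_crp=mcfadden_r2(crp.llf, ll0),
        lr_statistic=lr,
        lr_df=df,
        lr_p=float(stats.chi2.sf(lr, df)),
    )
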