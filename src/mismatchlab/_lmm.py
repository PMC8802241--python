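"""Random-intercept linear mixed model fitting with a graceful OLS fallback.

Inference on fixed effects uses Wald t statistics with between-within
(containment) denominator degrees of freedom: covariates that are constant
within every group are tested against (number of groups - number of
between-group coefficients); covariates that vary within groups against
(N - groups - number of within-group coefficients). For the balanced
between/within layouts this package fits, the rule is exact and coincides
with the classical split-plot ANOVA df.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class LMMResult:
    params: pd.Series
    bse: pd.Series
    df: pd.Series            # per-coefficient denominator df
    pvalues: pd.Series
    group_var: float         # random-intercept variance (0 for the OLS route)
    method: str              # "mixed" or "ols"
    converged: bool
    n_obs: int
    n_groups: int

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        crit = pd.Series(
            {k: stats.t.ppf(1 - alpha / 2, max(self.df[k], 1)) for k in self.params.index})
        return pd.DataFrame({"lower": self.params - crit * self.bse,
                             "upper": self.params + crit * self.bse})


def containment_df(X: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Between-within df per design column."""
    g = pd.Series(np.asarray(groups), index=X.index)
    n, G = len(X), g.nunique()
    within_var = {}
    for col in X.columns:
        nun = X[col].groupby(g, observed=True).nunique()
        within_var[col] = bool((nun > 1).any())
    q_b = sum(1 for c in X.columns if not within_var[c])
    q_w = sum(1 for c in X.columns if within_var[c])
    out = {}
    for col in X.columns:
        out[col] = float(max(n - G - q_w, 1)) if within_var[col] \
            else float(max(G - q_b, 1))
    return pd.Series(out)


def _finish(params, bse, df, group_var, method, converged, n, G) -> LMMResult:
    tvals = params / bse
    pvals = pd.Series(
        {k: 2 * stats.t.sf(abs(tvals[k]), max(df[k], 1)) for k in params.index})
    return LMMResult(params=params, bse=bse, df=df, pvalues=pvals,
                     group_var=group_var, method=method, converged=converged,
                     n_obs=n, n_groups=G)


def fit_random_intercept(endog: pd.Series, X: pd.DataFrame,
                         groups: pd.Series) -> LMMResult:
    """REML random-intercept fit; falls back to OLS (with a warning) when the
    mixed fit is singular or does not converge."""
    y = pd.Series(np.asarray(endog, dtype=float), index=X.index)
    g = pd.Series(np.asarray(groups), index=X.index)
    n, G = len(y), g.nunique()
    df = containment_df(X, g)

    if G >= 2:
        se_cap = 100.0 * (float(y.std()) + 1e-12)  # reject degenerate optima
        for method in ("bfgs", "cg", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.MixedLM(y, X, groups=g).fit(
                        reml=True, method=method, maxiter=200)
                params = res.params[X.columns].astype(float)
                bse = res.bse[X.columns].astype(float)
                if (res.converged and np.isfinite(bse).all()
                        and (bse > 0).all() and bse.max() < se_cap):
                    gvar = float(np.asarray(res.cov_re).ravel()[0])
                    return _finish(params, bse, df, gvar, "mixed", True, n, G)
            except (np.linalg.LinAlgError, ValueError):
                continue
        warnings.warn("mixed model did not converge; falling back to OLS",
                      stacklevel=2)

    ols = sm.OLS(y, X).fit()
    df_ols = pd.Series(float(max(ols.df_resid, 1)), index=X.columns)
    return _finish(ols.params.astype(float), ols.bse.astype(float), df_ols,
                   0.0, "ols", True, n, G)
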