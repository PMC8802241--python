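"""Divergence-mismatch regressions, mechanism regressions, the snowball
count analysis, and the F2 trait-correlation summary.

The central model, fitted to one mean value per cross x hybrid generation,
is

    response ~ divergence * generation + (1 | freshwater population)

where the response is mean mismatch, the dominance effect, or the variance
effect. Each freshwater population appears in exactly one cross, so the
random intercept is grouped by cross. Wald t tests use between-within
denominator df (10 for the default 12-cross layout, both for the
between-cross divergence slope and the within-cross interaction).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import fit_random_intercept
from .geometry import cross_registry, cross_rows, mismatch, population_mean
from .preprocess import StandardizedMatrix


@dataclass
class RegressionResult:
    """One divergence regression: pooled slope plus per-generation slopes."""

    response: str
    slope: float                 # pooled (additive-model) slope per unit divergence
    se: float
    ci: tuple[float, float]
    p: float
    interaction_t: float
    interaction_p: float
    per_generation: dict[str, dict] = field(default_factory=dict)
    method: str = "mixed"
    n_obs: int = 0

    def to_row(self) -> dict:
        row = {"response": self.response, "slope": self.slope, "se": self.se,
               "ci_lower": self.ci[0], "ci_upper": self.ci[1], "p": self.p,
               "interaction_t": self.interaction_t,
               "interaction_p": self.interaction_p, "method": self.method,
               "n_obs": self.n_obs}
        for gen, d in self.per_generation.items():
            for k, v in d.items():
                row[f"{gen}_{k}"] = v
        return row


def _divergence_regression(table: pd.DataFrame, response: str,
                           alpha: float = 0.05,
                           full: bool = True) -> RegressionResult:
    """Fit the mixed model in three parametrizations: interaction coding for
    the divergence x generation test, per-generation slope coding for the
    generation-specific slopes/CIs, additive coding for the pooled slope.
    ``full=False`` fits only the additive model (pooled slope)."""
    tab = table.dropna(subset=[response])
    if tab["cross_id"].nunique() < 3:
        raise ValueError("need at least 3 crosses for the divergence regression")
    y = tab[response].astype(float)
    groups = tab["cross_id"]
    d = tab["divergence"].astype(float)
    is_f2 = (tab["generation"] == "F2").astype(float)

    X_add = pd.DataFrame({"const": 1.0, "divergence": d, "gen_F2": is_f2})
    res_add = fit_random_intercept(y, X_add, groups)
    ci_add = res_add.conf_int(alpha)

    interaction_t = interaction_p = float("nan")
    per_gen: dict[str, dict] = {}
    if full:
        X_int = pd.DataFrame({"const": 1.0, "divergence": d, "gen_F2": is_f2,
                              "div_x_gen": d * is_f2})
        res_int = fit_random_intercept(y, X_int, groups)
        interaction_t = float(res_int.params["div_x_gen"] / res_int.bse["div_x_gen"])
        interaction_p = float(res_int.pvalues["div_x_gen"])

        X_per = pd.DataFrame({"const": 1.0, "gen_F2": is_f2,
                              "div_F1": d * (1 - is_f2), "div_F2": d * is_f2})
        res_per = fit_random_intercept(y, X_per, groups)
        ci_per = res_per.conf_int(alpha)
        for gen, col in (("F1", "div_F1"), ("F2", "div_F2")):
            if (tab["generation"] == gen).any():
                per_gen[gen] = {
                    "slope": float(res_per.params[col]),
                    "se": float(res_per.bse[col]),
                    "ci_lower": float(ci_per.loc[col, "lower"]),
                    "ci_upper": float(ci_per.loc[col, "upper"]),
                    "p": float(res_per.pvalues[col]),
                }

    return RegressionResult(
        response=response,
        slope=float(res_add.params["divergence"]),
        se=float(res_add.bse["divergence"]),
        ci=(float(ci_add.loc["divergence", "lower"]),
            float(ci_add.loc["divergence", "upper"])),
        p=float(res_add.pvalues["divergence"]),
        interaction_t=interaction_t,
        interaction_p=interaction_p,
        per_generation=per_gen, method=res_add.method, n_obs=len(tab))


def fit_divergence_mismatch(decompositions: pd.DataFrame,
                            alpha: float = 0.05,
                            full: bool = True) -> RegressionResult:
    """Mean mismatch per (cross, generation) against parental divergence.

    ``decompositions`` is the output of
    :func:`mismatchlab.geometry.decomposition_table` (columns cross_id,
    generation, divergence, mean_mismatch, ...).
    """
    return _divergence_regression(decompositions, "mean_mismatch", alpha, full=full)


def fit_effect_regressions(decompositions: pd.DataFrame,
                           alpha: float = 0.05
                           ) -> tuple[RegressionResult, RegressionResult]:
    """Same model with the dominance effect and the variance effect as
    responses (the two mechanism regressions)."""
    return (_divergence_regression(decompositions, "dominance_effect", alpha),
            _divergence_regression(decompositions, "variance_effect", alpha))


# -------------------------------------------------------------- snowball

def significant_pair_counts(matrix: StandardizedMatrix, alpha: float = 0.05,
                            tol: float = 1e-10) -> pd.DataFrame:
    """Per cross x hybrid generation: the number of trait pairs whose mean
    hybrid pairwise mismatch significantly exceeds the parental baseline.

    For every pair of traits, hybrid individuals' 2-D perpendicular mismatch
    is compared against the pooled parental individuals' 2-D deviation about
    the same parent line by a one-sided Welch t-test at ``alpha``.
    """
    traits = matrix.traits
    pairs = list(combinations(range(len(traits)), 2))
    rows = []
    for cross in cross_registry(matrix.data):
        parts = {gen: cross_rows(matrix, cross, gen)
                 for gen in ("PM", "PF", "F1", "F2")}
        fam_means = {gen: parts[gen].groupby("family_id", observed=True)[traits]
                     .mean().to_numpy(dtype=float)
                     for gen in ("PM", "PF")}
        X = {gen: parts[gen][traits].to_numpy(dtype=float) for gen in parts}
        for gen in ("F1", "F2"):
            if parts[gen].empty:
                continue
            count = 0
            for i, j in pairs:
                idx = [i, j]
                pm = fam_means["PM"][:, idx].mean(axis=0)
                pf = fam_means["PF"][:, idx].mean(axis=0)
                if np.linalg.norm(pf - pm) < tol:
                    continue
                d_hyb = mismatch(X[gen][:, idx], pm, pf, tol)
                d_par = mismatch(np.vstack([X["PM"][:, idx], X["PF"][:, idx]]),
                                 pm, pf, tol)
                _, p = stats.ttest_ind(d_hyb, d_par, equal_var=False,
                                       alternative="greater")
                if p < alpha:
                    count += 1
            rows.append({"cross_id": cross, "generation": gen,
                         "n_significant_pairs": count, "n_pairs": len(pairs)})
    return pd.DataFrame(rows)


@dataclass
class SnowballResult:
    generation: str
    linear_slope: float
    linear_p: float
    quadratic_coef: float
    quadratic_p: float     # added-term t-test of D^2 over the linear model
    counts: pd.DataFrame


def snowball(counts: pd.DataFrame, divergences: pd.DataFrame,
             alpha: float = 0.05) -> dict[str, SnowballResult]:
    """Fit count ~ D and count ~ D + D^2 per hybrid generation and report
    whether the quadratic term improves the fit (its t-test p-value).

    ``divergences`` maps cross_id -> divergence (columns cross_id,
    divergence); counts come from :func:`significant_pair_counts`.
    """
    merged = counts.merge(divergences[["cross_id", "divergence"]].drop_duplicates(),
                          on="cross_id")
    out = {}
    for gen, sub in merged.groupby("generation", observed=True):
        D = sub["divergence"].astype(float).to_numpy()
        c = sub["n_significant_pairs"].astype(float).to_numpy()
        X1 = np.column_stack([np.ones_like(D), D])
        X2 = np.column_stack([np.ones_like(D), D, D ** 2])
        import statsmodels.api as sm
        lin = sm.OLS(c, X1).fit()
        quad = sm.OLS(c, X2).fit()
        out[gen] = SnowballResult(
            generation=gen,
            linear_slope=float(lin.params[1]), linear_p=float(lin.pvalues[1]),
            quadratic_coef=float(quad.params[2]),
            quadratic_p=float(quad.pvalues[2]),
            counts=sub.reset_index(drop=True))
    return out


# ------------------------------------------------- F2 trait correlations

def f2_correlation_summary(matrix: StandardizedMatrix,
                           scope: str = "per_cross") -> dict:
    """Pearson correlations between all trait pairs among F2 hybrids.

    ``scope="per_cross"`` (default) computes correlations within each cross
    (avoiding inflation by between-cross mean differences) and aggregates
    over crosses x pairs; ``scope="pooled"`` pools all F2 fish.
    Returns median |r| and the percentage of pairs significant at P < 0.05.
    """
    traits = matrix.traits
    f2 = matrix.data[matrix.data["generation"] == "F2"]
    groups = ([("all", f2)] if scope == "pooled"
              else list(f2.groupby("cross_id", observed=True)))
    rs, ps = [], []
    for _, sub in groups:
        X = sub[traits].to_numpy(dtype=float)
        n = len(X)
        if n < 4:
            continue
        R = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices(len(traits), k=1)
        r = np.clip(R[iu], -0.999999999, 0.999999999)
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        rs.append(r)
        ps.append(p)
    r_all = np.concatenate(rs)
    p_all = np.concatenate(ps)
    return {"median_abs_r": float(np.median(np.abs(r_all))),
            "pct_significant": float(100.0 * np.mean(p_all < 0.05)),
            "n_pairs": int(r_all.size)}
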