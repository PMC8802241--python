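"""Per-trait line-cross quantitative genetics.

For each cross and trait the additive-dominance model regresses standardized
trait values on (i) an additive index — the expected fraction of the genome
that is freshwater-derived (PM 0, F1 and F2 0.5, PF 1) — and (ii) a dominance
deviation — the expected fraction of the genome heterozygous for
marine/freshwater alleles (parents 0, F1 1, F2 0.5) — with a random
intercept per family.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import fit_random_intercept
from .geometry import cross_rows, population_mean
from .preprocess import StandardizedMatrix

ADDITIVE_INDEX = {"PM": 0.0, "F1": 0.5, "F2": 0.5, "PF": 1.0}
HETEROZYGOSITY_INDEX = {"PM": 0.0, "PF": 0.0, "F1": 1.0, "F2": 0.5}


def parents_differ(matrix: StandardizedMatrix, cross_id: str, trait: str,
                   alpha: float = 0.05,
                   on: str = "individuals") -> tuple[bool | None, float]:
    """Welch two-sample t-test of marine vs freshwater parents on one trait.

    ``on="individuals"`` (default) tests individual fish; ``on="families"``
    tests family means. Returns (differ, p); (None, nan) when a side has
    fewer than two units.
    """
    sides = []
    for gen in ("PM", "PF"):
        sub = cross_rows(matrix, cross_id, gen)
        if on == "families":
            vals = sub.groupby("family_id", observed=True)[trait].mean().to_numpy()
        else:
            vals = sub[trait].to_numpy(dtype=float)
        sides.append(vals)
    if min(len(s) for s in sides) < 2:
        warnings.warn(
            f"cross {cross_id!r}, trait {trait!r}: fewer than 2 observations in a "
            "parent population; parent-difference test skipped", stacklevel=2)
        return None, float("nan")
    t, p = stats.ttest_ind(sides[0], sides[1], equal_var=False)
    return bool(p < alpha), float(p)


@dataclass
class DominanceFit:
    """Additive/dominance decomposition of one trait in one cross."""

    cross_id: str
    trait: str
    beta_additive: float
    beta_dominance: float
    se_dominance: float
    p_dominance: float
    parents_differ: bool | None
    p_parents: float
    method: str  # "mixed" or "ols"


def fit_additive_dominance(matrix: StandardizedMatrix, cross_id: str, trait: str,
                           alpha: float = 0.05) -> DominanceFit:
    """Random-intercept (family) regression of a standardized trait on the
    additive and heterozygosity indices for one cross."""
    frames = [cross_rows(matrix, cross_id, gen) for gen in ("PM", "PF", "F1", "F2")]
    if any(f.empty for f in frames):
        raise ValueError(
            f"cross {cross_id!r}: all four generation categories are required")
    df = pd.concat(frames, ignore_index=True)
    X = pd.DataFrame({
        "const": 1.0,
        "additive": df["generation"].map(ADDITIVE_INDEX).astype(float),
        "dominance": df["generation"].map(HETEROZYGOSITY_INDEX).astype(float),
    })
    res = fit_random_intercept(df[trait].astype(float), X, df["family_id"])
    differ, p_par = parents_differ(matrix, cross_id, trait, alpha=alpha)
    return DominanceFit(
        cross_id=cross_id, trait=trait,
        beta_additive=float(res.params["additive"]),
        beta_dominance=float(res.params["dominance"]),
        se_dominance=float(res.bse["dominance"]),
        p_dominance=float(res.pvalues["dominance"]),
        parents_differ=differ, p_parents=p_par, method=res.method)


def dominance_fit_table(matrix: StandardizedMatrix, cross_id: str,
                        alpha: float = 0.05) -> pd.DataFrame:
    rows = [fit_additive_dominance(matrix, cross_id, t, alpha).__dict__
            for t in matrix.traits]
    return pd.DataFrame(rows)


def dominance_coefficient(matrix: StandardizedMatrix, cross_id: str,
                          generation: str, trait: str,
                          alpha: float = 0.05) -> float | None:
    """Position of the hybrid mean on a trait axis rescaled so the marine
    parent is 0 and the freshwater parent is 1; transgressive values (<0, >1)
    are possible. Only computed when the parents are statistically
    distinguishable on that trait; returns None otherwise."""
    differ, _ = parents_differ(matrix, cross_id, trait, alpha=alpha)
    if not differ:
        return None
    i = matrix.traits.index(trait)
    pm = population_mean(cross_rows(matrix, cross_id, "PM"), matrix.traits)[i]
    pf = population_mean(cross_rows(matrix, cross_id, "PF"), matrix.traits)[i]
    hyb = population_mean(cross_rows(matrix, cross_id, generation), matrix.traits)[i]
    return float((hyb - pm) / (pf - pm))


def family_trait_variance(matrix: StandardizedMatrix, cross_id: str,
                          generation: str) -> pd.DataFrame:
    """Within-family sample variance per trait, averaged (unweighted) across
    families; singleton families contribute nothing (warned)."""
    sub = cross_rows(matrix, cross_id, generation)
    sizes = sub.groupby("family_id", observed=True).size()
    small = sizes[sizes < 2]
    if len(small):
        warnings.warn(
            f"cross {cross_id!r} {generation}: families of size 1 skipped: "
            f"{list(small.index)}", stacklevel=2)
    keep = sub[sub["family_id"].isin(sizes[sizes >= 2].index)]
    if keep.empty:
        raise ValueError(
            f"cross {cross_id!r} {generation}: no family with >= 2 individuals")
    fam_var = keep.groupby("family_id", observed=True)[matrix.traits].var(ddof=1)
    mean_var = fam_var.mean(axis=0)
    return pd.DataFrame({
        "cross_id": cross_id, "generation": generation,
        "trait": matrix.traits,
        "mean_within_family_variance": mean_var[matrix.traits].to_numpy(dtype=float),
    })
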