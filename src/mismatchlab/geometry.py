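"""Divergence, perpendicular mismatch, and its dominance/variance decomposition.

All geometry happens in standardized trait space. The central statistic is
the mismatch d_mm of an individual hybrid: the shortest (perpendicular)
Euclidean distance between its trait vector F and the infinite line through
the two parental mean phenotypes P_M and P_F,

    d_mm(F) = || (F - P_M) - ((F - P_M) . u) u ||,   u = (P_F - P_M)/||P_F - P_M||.

The line is infinite (not the segment) because transgressive hybrids project
beyond the parental means. Population mean vectors are unweighted means of
family means throughout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import cross_registry
from .preprocess import StandardizedMatrix

DEFAULT_COINCIDENT_TOL = 1e-10


# ---------------------------------------------------------------- primitives

def divergence(pm_mean: np.ndarray, pf_mean: np.ndarray) -> float:
    """Multivariate Euclidean distance between the parental mean phenotypes."""
    pm_mean = np.asarray(pm_mean, dtype=float)
    pf_mean = np.asarray(pf_mean, dtype=float)
    if pm_mean.shape != pf_mean.shape:
        raise ValueError(f"vector length mismatch: {pm_mean.shape} vs {pf_mean.shape}")
    return float(np.linalg.norm(pf_mean - pm_mean))


def mismatch(f: np.ndarray, pm_mean: np.ndarray, pf_mean: np.ndarray,
             tol: float = DEFAULT_COINCIDENT_TOL) -> np.ndarray | float:
    """Perpendicular distance of hybrid vector(s) ``f`` to the parent line.

    ``f`` may be a single vector or an (n, p) stack; returns a scalar or an
    array accordingly. If the parental means coincide (within ``tol``) the
    line is undefined and the distance to the (single) parental point is
    returned with a warning.
    """
    f = np.asarray(f, dtype=float)
    pm_mean = np.asarray(pm_mean, dtype=float)
    pf_mean = np.asarray(pf_mean, dtype=float)
    single = f.ndim == 1
    F = np.atleast_2d(f)
    if F.shape[1] != pm_mean.shape[0] or pm_mean.shape != pf_mean.shape:
        raise ValueError("trait dimension mismatch between hybrid and parent vectors")
    axis = pf_mean - pm_mean
    norm = np.linalg.norm(axis)
    if norm < tol:
        warnings.warn(
            "parental mean phenotypes coincide; mismatch falls back to the "
            "distance to the parental point", stacklevel=2)
        d = np.linalg.norm(F - pm_mean, axis=1)
    else:
        u = axis / norm
        centered = F - pm_mean
        along = centered @ u
        perp = centered - np.outer(along, u)
        d = np.linalg.norm(perp, axis=1)
    return float(d[0]) if single else d


def population_mean(df: pd.DataFrame, traits: list[str]) -> np.ndarray:
    """Unweighted mean of family means (each family counts once, regardless
    of how many fish it contributed)."""
    if df.empty:
        raise ValueError("empty population: cannot compute a mean phenotype")
    fam_means = df.groupby("family_id", observed=True)[traits].mean()
    return fam_means.mean(axis=0).to_numpy(dtype=float)


# ----------------------------------------------------------- row resolution

def cross_rows(matrix: StandardizedMatrix, cross_id: str,
               generation: str) -> pd.DataFrame:
    """Rows of one generation of one cross. PM rows of the shared marine
    population (empty cross_id) are resolved through the cross registry."""
    df = matrix.data
    cid = df["cross_id"].fillna("").astype(str)
    if generation in ("F1", "F2", "PF"):
        sub = df[(cid == str(cross_id)) & (df["generation"] == generation)]
        if generation == "PF" and sub.empty:
            raise ValueError(f"cross {cross_id!r}: no PF rows")
        return sub
    if generation == "PM":
        sub = df[(cid == str(cross_id)) & (df["generation"] == "PM")]
        if sub.empty:
            reg = cross_registry(df)
            if cross_id not in reg:
                raise ValueError(f"unknown cross {cross_id!r}")
            pm_pop = reg[cross_id][0]
            sub = df[(df["generation"] == "PM") & (df["population"] == pm_pop)]
        return sub
    raise ValueError(f"unknown generation {generation!r}")


def parental_means(matrix: StandardizedMatrix,
                   cross_id: str) -> tuple[np.ndarray, np.ndarray]:
    pm = population_mean(cross_rows(matrix, cross_id, "PM"), matrix.traits)
    pf = population_mean(cross_rows(matrix, cross_id, "PF"), matrix.traits)
    return pm, pf


# ----------------------------------------------------------------- summaries

@dataclass
class CrossSummary:
    """Per-cross geometry: parental means, divergence, hybrid means, and
    per-individual mismatch values."""

    cross_id: str
    pm_mean: np.ndarray
    pf_mean: np.ndarray
    divergence: float
    hybrid_means: dict[str, np.ndarray] = field(default_factory=dict)
    individual_mismatch: pd.DataFrame | None = None  # columns: meta + d_mm


def cross_summary(matrix: StandardizedMatrix, cross_id: str,
                  tol: float = DEFAULT_COINCIDENT_TOL) -> CrossSummary:
    pm, pf = parental_means(matrix, cross_id)
    rows = []
    hybrid_means: dict[str, np.ndarray] = {}
    for gen in ("F1", "F2"):
        sub = cross_rows(matrix, cross_id, gen)
        if sub.empty:
            continue
        hybrid_means[gen] = population_mean(sub, matrix.traits)
        d = mismatch(sub[matrix.traits].to_numpy(dtype=float), pm, pf, tol)
        block = sub[["individual_id", "cross_id", "generation", "family_id"]].copy()
        block["d_mm"] = d
        rows.append(block)
    indiv = pd.concat(rows, ignore_index=True) if rows else None
    return CrossSummary(cross_id=cross_id, pm_mean=pm, pf_mean=pf,
                        divergence=divergence(pm, pf),
                        hybrid_means=hybrid_means, individual_mismatch=indiv)


@dataclass
class MismatchDecomposition:
    """Mean mismatch of one hybrid generation split into the part caused by
    net dominance (the mean phenotype sitting off the parent line) and the
    part caused by phenotypic variation around that mean."""

    cross_id: str
    generation: str
    dominance_effect: float
    variance_effect: float
    mean_mismatch: float
    n_individuals: int
    n_families: int


def decompose(matrix: StandardizedMatrix, cross_id: str, generation: str,
              averaging: str = "family",
              tol: float = DEFAULT_COINCIDENT_TOL) -> MismatchDecomposition:
    """Dominance effect = d_mm of the generation's mean phenotype; variance
    effect = average of (individual d_mm - dominance effect).

    ``averaging="family"`` (default) averages the differences within family
    first, then unweighted across families; ``averaging="individual"``
    averages straight across fish, which makes
    dominance_effect + variance_effect == mean_mismatch exactly.
    """
    if averaging not in ("family", "individual"):
        raise ValueError("averaging must be 'family' or 'individual'")
    pm, pf = parental_means(matrix, cross_id)
    sub = cross_rows(matrix, cross_id, generation)
    if sub.empty:
        raise ValueError(f"cross {cross_id!r}: no {generation} rows")
    hyb_mean = population_mean(sub, matrix.traits)
    dom = float(mismatch(hyb_mean, pm, pf, tol))
    d = pd.Series(mismatch(sub[matrix.traits].to_numpy(dtype=float), pm, pf, tol),
                  index=sub.index)
    if averaging == "individual":
        mean_mm = float(d.mean())
    else:
        mean_mm = float(d.groupby(sub["family_id"], observed=True).mean().mean())
    return MismatchDecomposition(
        cross_id=cross_id, generation=generation,
        dominance_effect=dom, variance_effect=mean_mm - dom,
        mean_mismatch=mean_mm, n_individuals=len(sub),
        n_families=sub["family_id"].nunique())


def decomposition_table(matrix: StandardizedMatrix,
                        averaging: str = "family",
                        tol: float = DEFAULT_COINCIDENT_TOL) -> pd.DataFrame:
    """All crosses x hybrid generations, one MismatchDecomposition per row,
    plus the parental divergence (the regression predictor).

    Single-pass implementation: family means for every (cross, generation)
    are computed in one grouped aggregation, so the cost stays linear in the
    number of fish rather than crosses x fish.
    """
    if averaging not in ("family", "individual"):
        raise ValueError("averaging must be 'family' or 'individual'")
    df = matrix.data
    traits = matrix.traits
    reg = cross_registry(df)
    cid = df["cross_id"].fillna("").astype(str)
    work = df.assign(_cid=cid)
    fam_means = work.groupby(["_cid", "generation", "family_id"],
                             observed=True)[traits].mean()
    pop_means = fam_means.groupby(level=["_cid", "generation"],
                                  observed=True).mean()
    groups = work.groupby(["_cid", "generation"], observed=True)

    def _pop_mean(cross: str, gen: str) -> np.ndarray:
        if (cross, gen) in pop_means.index:
            return pop_means.loc[(cross, gen)].to_numpy(dtype=float)
        return pop_means.loc[("", gen)].to_numpy(dtype=float)  # shared marine

    rows = []
    for cross, (pm_pop, pf_pop) in reg.items():
        pm = _pop_mean(cross, "PM")
        pf = _pop_mean(cross, "PF")
        div = divergence(pm, pf)
        for gen in ("F1", "F2"):
            if (cross, gen) not in groups.indices:
                continue
            sub = work.iloc[groups.indices[(cross, gen)]]
            hyb_mean = fam_means.loc[(cross, gen)].mean(axis=0).to_numpy(dtype=float)
            dom = float(mismatch(hyb_mean, pm, pf, tol))
            d = pd.Series(mismatch(sub[traits].to_numpy(dtype=float), pm, pf, tol),
                          index=sub.index)
            if averaging == "individual":
                mean_mm = float(d.mean())
            else:
                mean_mm = float(d.groupby(sub["family_id"], observed=True)
                                .mean().mean())
            rows.append({"cross_id": cross, "generation": gen, "divergence": div,
                         "dominance_effect": dom,
                         "variance_effect": mean_mm - dom,
                         "mean_mismatch": mean_mm,
                         "n_individuals": len(sub),
                         "n_families": sub["family_id"].nunique()})
    return pd.DataFrame(rows)


def parent_deviation(matrix: StandardizedMatrix, cross_id: str,
                     tol: float = DEFAULT_COINCIDENT_TOL) -> dict[str, float]:
    """Mean 'mismatch' of parental individuals about their own line — the
    baseline deviation caused purely by within-population variation.
    Family-then-population averaged, keyed by generation (PM, PF)."""
    pm, pf = parental_means(matrix, cross_id)
    out = {}
    for gen in ("PM", "PF"):
        sub = cross_rows(matrix, cross_id, gen)
        d = pd.Series(mismatch(sub[matrix.traits].to_numpy(dtype=float), pm, pf, tol),
                      index=sub.index)
        out[gen] = float(d.groupby(sub["family_id"], observed=True).mean().mean())
    return out


def pairwise_mismatch(matrix: StandardizedMatrix, cross_id: str,
                      trait_i: str, trait_j: str,
                      generation: str | None = None,
                      tol: float = DEFAULT_COINCIDENT_TOL) -> pd.DataFrame:
    """d_mm restricted to the 2-D subspace of two named traits.

    Returns per-individual values for the requested generation (default:
    both hybrid generations). Falls back to distance-to-point (warned) when
    the parents do not differ in this trait pair.
    """
    for t in (trait_i, trait_j):
        if t not in matrix.traits:
            raise KeyError(f"unknown trait {t!r}")
    sub2 = [trait_i, trait_j]
    pm_rows = cross_rows(matrix, cross_id, "PM")
    pf_rows = cross_rows(matrix, cross_id, "PF")
    pm = population_mean(pm_rows, sub2)
    pf = population_mean(pf_rows, sub2)
    gens = [generation] if generation else ["F1", "F2"]
    blocks = []
    for gen in gens:
        sub = cross_rows(matrix, cross_id, gen)
        if sub.empty:
            continue
        block = sub[["individual_id", "cross_id", "generation", "family_id"]].copy()
        block["trait_i"], block["trait_j"] = trait_i, trait_j
        block["d_mm"] = mismatch(sub[sub2].to_numpy(dtype=float), pm, pf, tol)
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def parent_distances(matrix: StandardizedMatrix, cross_id: str,
                     generation: str) -> pd.DataFrame:
    """Euclidean distance of each hybrid to each parental mean phenotype."""
    pm, pf = parental_means(matrix, cross_id)
    sub = cross_rows(matrix, cross_id, generation)
    X = sub[matrix.traits].to_numpy(dtype=float)
    out = sub[["individual_id", "cross_id", "generation", "family_id"]].copy()
    out["dist_to_marine"] = np.linalg.norm(X - pm, axis=1)
    out["dist_to_freshwater"] = np.linalg.norm(X - pf, axis=1)
    return out


def mismatch_table(matrix: StandardizedMatrix,
                   tol: float = DEFAULT_COINCIDENT_TOL) -> pd.DataFrame:
    """Per-individual multivariate mismatch for every cross and hybrid
    generation (the long output table)."""
    blocks = []
    for cross in cross_registry(matrix.data):
        cs = cross_summary(matrix, cross, tol)
        if cs.individual_mismatch is not None:
            block = cs.individual_mismatch.copy()
            block["divergence"] = cs.divergence
            blocks.append(block)
    return pd.concat(blocks, ignore_index=True)
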