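"""Raw measurements -> standardized trait space.

Order of operations (each sequential, each recorded in the transform record):

1. absence substitution: structures recorded as absent (0 mm) get 0.1 mm so
   the log is defined;
2. size correction: each linear trait becomes the residual of
   ln(trait) ~ ln(standard length), fitted once pooled over the whole dataset
   (counts pass through);
3. fixation correction: gape width, snout length and head length are further
   residualized on the 3-level mouth-openness category;
4. standardization: every trait is z-scored over the entire dataset (parents
   and hybrids pooled), so one unit means one grand SD everywhere downstream.

The transform record holds the fitted intercepts/slopes, category effects and
grand mean/SD per trait, enough to project a held-out fish into the same space.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import META_COLUMNS, TraitConfig
from .data_io import TraitTable


class FitError(RuntimeError):
    pass


@dataclass
class TransformRecord:
    """Per-trait fitted parameters of the preprocessing chain."""

    allometry: dict[str, dict] = field(default_factory=dict)   # trait -> {intercept, slope, degenerate}
    fixation: dict[str, dict] = field(default_factory=dict)    # trait -> {category(str): effect}
    standardization: dict[str, dict] = field(default_factory=dict)  # trait -> {mean, sd}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "allometry": self.allometry,
            "fixation": self.fixation,
            "standardization": self.standardization,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransformRecord":
        d = json.loads(Path(path).read_text())
        return cls(allometry=d["allometry"], fixation=d["fixation"],
                   standardization=d["standardization"])


@dataclass
class StandardizedMatrix:
    """Individuals x traits matrix in standardized units, with row metadata.

    ``data`` holds the metadata columns plus one column per trait; every trait
    column has mean 0 and SD 1 across the full dataset.
    """

    data: pd.DataFrame
    traits: list[str]
    transforms: TransformRecord = field(default_factory=TransformRecord)
    config: TraitConfig | None = None

    @property
    def values(self) -> np.ndarray:
        return self.data[self.traits].to_numpy(dtype=float)

    @property
    def meta(self) -> pd.DataFrame:
        return self.data[META_COLUMNS]

    def select(self, *, population: str | None = None, cross_id: str | None = None,
               generation: str | None = None) -> pd.DataFrame:
        """Row subset; for parental generations of a cross, resolution through
        the cross registry (shared marine rows carry no cross_id) is handled
        by :func:`mismatchlab.geometry.cross_rows`."""
        m = pd.Series(True, index=self.data.index)
        if population is not None:
            m &= self.data["population"] == population
        if cross_id is not None:
            m &= self.data["cross_id"].fillna("").astype(str) == cross_id
        if generation is not None:
            m &= self.data["generation"] == generation
        return self.data[m]

    def to_csv(self, path: str | Path) -> None:
        self.data[META_COLUMNS + self.traits].to_csv(path, index=False)


def substitute_absences(table: TraitTable) -> TraitTable:
    """Replace recorded-absent (0) values with 0.1 mm for traits whose absence
    is a normal polymorphism (first dorsal spine, pelvic spine, pelvic girdle),
    so the subsequent log-transform is defined."""
    df = table.data.copy()
    for t, spec in table.config.traits.items():
        vals = pd.to_numeric(df[t], errors="coerce")
        if (vals < 0).any():
            raise ValueError(f"negative raw measurement in trait {t!r}")
        if spec.absence_substitution_mm is not None:
            df[t] = vals.where(vals > 0, spec.absence_substitution_mm)
        elif spec.kind == "linear" and (vals == 0).any():
            raise ValueError(
                f"trait {t!r} has zero values but no absence substitution registered"
            )
    return TraitTable(df, table.config)


def size_correct(table: TraitTable, record: TransformRecord | None = None,
                 pooled: bool = True) -> tuple[pd.DataFrame, TransformRecord]:
    """ln-ln allometric residuals against standard length.

    Each size-corrected trait column is replaced by the residual of
    ln(trait) on ln(SL), fitted across the entire dataset (``pooled=True``,
    the default) or within population (off-default option). Count traits are
    returned untouched. If all fish share one SL the slope is indeterminate
    and the trait is mean-centered on the log scale instead (warned).
    """
    df = table.data.copy()
    if record is None:
        record = TransformRecord()
    if len(df) < 3:
        raise FitError("need at least 3 individuals for the allometric fit")
    sl = pd.to_numeric(df["standard_length"], errors="coerce").to_numpy(dtype=float)
    if not np.all(sl > 0):
        raise ValueError("standard_length must be strictly positive")
    ln_sl = np.log(sl)

    groups = (np.zeros(len(df), dtype=int) if pooled
              else pd.factorize(df["population"])[0])

    for t, spec in table.config.traits.items():
        if not spec.size_correct or spec.kind != "linear":
            continue
        raw = pd.to_numeric(df[t], errors="coerce").to_numpy(dtype=float)
        if np.any(raw <= 0):
            raise ValueError(f"trait {t!r} must be strictly positive before ln-transform")
        ln_t = np.log(raw)
        resid = np.empty_like(ln_t)
        params = []
        for g in np.unique(groups):
            m = groups == g
            x, y = ln_sl[m], ln_t[m]
            if np.ptp(x) < 1e-12:
                warnings.warn(
                    f"standard length constant; mean-centering ln({t}) instead of "
                    "fitting allometry", stacklevel=2)
                resid[m] = y - y.mean()
                params.append({"intercept": float(y.mean()), "slope": 0.0,
                               "degenerate": True})
                continue
            slope, intercept = np.polyfit(x, y, 1)
            resid[m] = y - (intercept + slope * x)
            params.append({"intercept": float(intercept), "slope": float(slope),
                           "degenerate": False})
        df[t] = resid
        record.allometry[t] = params[0] if pooled else {"per_population": params}
    return df, record


def fixation_correct(df: pd.DataFrame, config: TraitConfig,
                     record: TransformRecord) -> tuple[pd.DataFrame, TransformRecord]:
    """Remove the mouth-openness (fixation posture) effect from the affected
    traits: residuals on fixation_score as a 3-level factor, applied after
    size correction (sequential residualization)."""
    df = df.copy()
    score = df.get("fixation_score", pd.Series(0, index=df.index)).fillna(0).astype(int)
    for t in config.fixation_traits:
        vals = df[t].astype(float)
        effects: dict[str, float] = {}
        adjusted = vals.copy()
        for cat in (0, 1, 2):
            m = score == cat
            if not m.any():
                warnings.warn(f"fixation category {cat} empty for {t!r}; no adjustment",
                              stacklevel=2)
                continue
            eff = float(vals[m].mean())
            effects[str(cat)] = eff
            adjusted[m] = vals[m] - eff
        df[t] = adjusted
        record.fixation[t] = effects
    return df, record


def standardize(df: pd.DataFrame, config: TraitConfig,
                record: TransformRecord | None = None) -> StandardizedMatrix:
    """z-score every trait over the full dataset (sample SD, n-1)."""
    if record is None:
        record = TransformRecord()
    out = df.copy()
    for t in config.trait_names:
        vals = out[t].astype(float)
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"trait {t!r} has zero variance; cannot standardize")
        out[t] = (vals - mu) / sd
        record.standardization[t] = {"mean": mu, "sd": sd}
    return StandardizedMatrix(out.reset_index(drop=True), config.trait_names,
                              record, config)


def preprocess(table: TraitTable, pooled_allometry: bool = True) -> StandardizedMatrix:
    """Full chain: substitute absences -> size-correct -> fixation-correct ->
    standardize."""
    table = substitute_absences(table)
    df, record = size_correct(table, pooled=pooled_allometry)
    df, record = fixation_correct(df, table.config, record)
    return standardize(df, table.config, record)
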