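"""Reading, validating and writing per-individual trait tables.

Canonical format is wide: one row per fish, metadata columns
(individual_id, population, cross_id, generation, family_id), standard_length,
the registered trait columns, and the quality/condition flags
(fixation_score, swim_bladder_ok, second_dorsal_spine_present).

The marine ancestor is shared across crosses: PM rows carry an empty
cross_id and are linked to every cross through the cross registry.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import GENERATIONS, META_COLUMNS, TraitConfig

FLAG_COLUMNS = ["fixation_score", "swim_bladder_ok", "second_dorsal_spine_present"]


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class IntegrityError(ValueError):
    """Cross-referencing between rows is inconsistent."""


@dataclass
class TraitTable:
    """Validated per-individual phenotype table.

    ``data`` is wide (one row per fish); ``config`` carries the trait
    registry the columns were validated against.
    """

    data: pd.DataFrame
    config: TraitConfig

    def __post_init__(self) -> None:
        validate_trait_table(self.data, self.config)

    @property
    def traits(self) -> list[str]:
        return self.config.trait_names

    @property
    def n(self) -> int:
        return len(self.data)

    def crosses(self) -> dict[str, tuple[str, str]]:
        """Map cross_id -> (marine population, freshwater population)."""
        return cross_registry(self.data)


def validate_trait_table(df: pd.DataFrame, config: TraitConfig) -> None:
    missing = [c for c in META_COLUMNS + ["standard_length"] + config.trait_names
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    bad_gen = set(df["generation"].unique()) - set(GENERATIONS)
    if bad_gen:
        raise ValueError(
            f"generation labels outside {GENERATIONS}: {sorted(map(str, bad_gen))}"
        )

    dup = df["individual_id"][df["individual_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate individual_id: {sorted(dup.unique())[:5]}")

    bad_rows: list[str] = []
    sl = pd.to_numeric(df["standard_length"], errors="coerce")
    for idx in df.index[~(sl > 0)]:
        bad_rows.append(f"row {idx}: standard_length must be > 0")
    for t in config.trait_names:
        vals = pd.to_numeric(df[t], errors="coerce")
        for idx in df.index[vals.isna() & df[t].notna()]:
            bad_rows.append(f"row {idx}: unparseable value in {t!r}")
        if config.traits[t].kind == "count":
            ok = vals.isna() | ((vals >= 0) & (np.mod(vals.fillna(0), 1) == 0))
            for idx in df.index[~ok]:
                bad_rows.append(f"row {idx}: count trait {t!r} must be a nonnegative integer")
    if bad_rows:
        raise ValueError("invalid rows:\n" + "\n".join(bad_rows))

    _check_cross_links(df)


def _check_cross_links(df: pd.DataFrame) -> None:
    cid = df["cross_id"].fillna("").astype(str)
    pm_pops = df.loc[df["generation"] == "PM", "population"].unique()
    for cross in sorted(set(cid[df["generation"].isin(["F1", "F2"])]) - {""}):
        sub = df[cid == cross]
        pf = sub.loc[sub["generation"] == "PF", "population"].unique()
        pm_local = sub.loc[sub["generation"] == "PM", "population"].unique()
        if len(pf) != 1:
            raise IntegrityError(
                f"cross {cross!r}: expected exactly one PF population, found {len(pf)}"
            )
        n_pm = len(pm_local) if len(pm_local) else len(pm_pops)
        if n_pm != 1:
            raise IntegrityError(
                f"cross {cross!r}: expected exactly one PM population, found {n_pm}"
            )


def cross_registry(df: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """Resolve each cross to its (PM population, PF population) pair.

    PM rows without a cross_id belong to the single shared marine population.
    """
    cid = df["cross_id"].fillna("").astype(str)
    shared_pm = df.loc[(df["generation"] == "PM") & (cid == ""), "population"].unique()
    out: dict[str, tuple[str, str]] = {}
    for cross in sorted(set(cid[df["generation"] == "PF"]) - {""}):
        sub = df[cid == cross]
        pf = sub.loc[sub["generation"] == "PF", "population"].unique()[0]
        pm_local = sub.loc[sub["generation"] == "PM", "population"].unique()
        if len(pm_local):
            pm = pm_local[0]
        elif len(shared_pm) == 1:
            pm = shared_pm[0]
        else:
            raise IntegrityError(f"cross {cross!r}: no PM population resolvable")
        out[cross] = (pm, pf)
    return out


def read_trait_table(path: str | Path, config: TraitConfig,
                     sep: Optional[str] = None) -> TraitTable:
    """Read a wide CSV/TSV trait table and validate it against the registry.

    ``sep=None`` infers from the extension (.tsv -> tab, otherwise comma).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"individual_id": str, "population": str,
                                           "cross_id": str, "family_id": str})
    df["cross_id"] = df["cross_id"].fillna("")
    for col, default in (("fixation_score", 0),
                         ("swim_bladder_ok", True),
                         ("second_dorsal_spine_present", True)):
        if col not in df.columns:
            df[col] = default
    return TraitTable(df.reset_index(drop=True), config)


def read_long_trait_table(path: str | Path, config: TraitConfig,
                          value_col: str = "value",
                          trait_col: str = "trait") -> TraitTable:
    """Convenience reader for long format (one row per fish x trait)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    long = pd.read_csv(path, sep=sep, dtype={"cross_id": str})
    if "cross_id" in long.columns:
        long["cross_id"] = long["cross_id"].fillna("")
    keep = [c for c in long.columns if c not in (trait_col, value_col)]
    wide = long.pivot_table(index=keep, columns=trait_col, values=value_col,
                            aggfunc="first").reset_index()
    wide.columns.name = None
    for col, default in (("fixation_score", 0),
                         ("swim_bladder_ok", True),
                         ("second_dorsal_spine_present", True)):
        if col not in wide.columns:
            wide[col] = default
    wide["cross_id"] = wide["cross_id"].fillna("")
    return TraitTable(wide.reset_index(drop=True), config)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write in the canonical column order so outputs are diff-stable."""
    cols = (META_COLUMNS + ["standard_length"] + table.traits
            + [c for c in FLAG_COLUMNS if c in table.data.columns])
    extra = [c for c in table.data.columns if c not in cols]
    table.data[cols + extra].to_csv(path, index=False)


@dataclass
class ExclusionLog:
    entries: list[dict] = field(default_factory=list)

    def record(self, individual_id: str, reason: str) -> None:
        self.entries.append({"individual_id": individual_id, "reason": reason})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["individual_id", "reason"])


def apply_exclusions(table: TraitTable) -> tuple[TraitTable, ExclusionLog]:
    """Drop fish with a missing second dorsal spine (extreme outliers) or an
    uninflated swim bladder. Idempotent; returns the filtered table plus a
    per-individual log.
    """
    df = table.data
    log = ExclusionLog()
    spine_ok = df.get("second_dorsal_spine_present",
                      pd.Series(True, index=df.index)).astype(bool)
    bladder_ok = df.get("swim_bladder_ok", pd.Series(True, index=df.index)).astype(bool)
    for _, row in df[~spine_ok].iterrows():
        log.record(row["individual_id"], "missing second dorsal spine")
    for _, row in df[spine_ok & ~bladder_ok].iterrows():
        log.record(row["individual_id"], "swim bladder not inflated")
    kept = df[spine_ok & bladder_ok].reset_index(drop=True)
    if kept.empty:
        warnings.warn("all individuals excluded", stacklevel=2)
    return TraitTable(kept, table.config), log


def drop_incomplete_cases(table: TraitTable) -> tuple[TraitTable, ExclusionLog]:
    """Require complete trait vectors (mismatch needs every trait measured)."""
    df = table.data
    log = ExclusionLog()
    complete = df[table.traits].notna().all(axis=1)
    for _, row in df[~complete].iterrows():
        missing = [t for t in table.traits if pd.isna(row[t])]
        log.record(row["individual_id"], f"missing trait value(s): {', '.join(missing)}")
    return TraitTable(df[complete].reset_index(drop=True), table.config), log
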