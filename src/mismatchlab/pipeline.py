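"""End-to-end orchestration: preprocess -> geometry -> quantgen -> inference,
with all stage outputs written as flat CSV plus a single JSON run report.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import TraitConfig
from .data_io import (TraitTable, apply_exclusions, cross_registry,
                      drop_incomplete_cases, read_trait_table)
from .geometry import (decomposition_table, mismatch_table, parent_deviation)
from .inference import (f2_correlation_summary, fit_divergence_mismatch,
                        fit_effect_regressions, significant_pair_counts, snowball)
from .preprocess import StandardizedMatrix, preprocess
from .quantgen import dominance_fit_table, family_trait_variance
from .simulate import SimulationConfig, simulate_study, write_truth

log = logging.getLogger("mismatchlab")


@dataclass
class RunReport:
    seed: int | None
    version: str
    divergences: dict[str, float]
    regressions: dict[str, dict]
    snowball: dict[str, dict]
    f2_correlations: dict
    n_individuals: int
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _stage(name: str, timings: dict):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc_type is not None:
                log.error("stage %s failed: %s", name, exc)
            else:
                log.info("stage %s done in %.2fs", name, timings[name])
            return False
    return _T()


def analyze_matrix(matrix: StandardizedMatrix, out_dir: str | Path,
                   alpha: float = 0.05, seed: int | None = None,
                   fit_dominance: bool = True) -> RunReport:
    """Run every analysis stage on an already-standardized matrix and write
    the stage CSVs plus report.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    with _stage("mismatch", timings):
        mm = mismatch_table(matrix)
        mm.to_csv(out / "individual_mismatch.csv", index=False)
        divergences = (mm[["cross_id", "divergence"]].drop_duplicates()
                       .set_index("cross_id")["divergence"].to_dict())

    with _stage("decompose", timings):
        dec = decomposition_table(matrix)
        dec.to_csv(out / "decomposition.csv", index=False)
        baseline = pd.DataFrame([
            {"cross_id": c, **parent_deviation(matrix, c)}
            for c in cross_registry(matrix.data)])
        baseline.to_csv(out / "parent_deviation.csv", index=False)

    with _stage("regress", timings):
        mm_reg = fit_divergence_mismatch(dec, alpha)
        dom_reg, var_reg = fit_effect_regressions(dec, alpha)
        regs = {"mean_mismatch": mm_reg.to_row(),
                "dominance_effect": dom_reg.to_row(),
                "variance_effect": var_reg.to_row()}
        pd.DataFrame(regs.values()).to_csv(out / "regressions.csv", index=False)

    if fit_dominance:
        with _stage("dominance", timings):
            fits = pd.concat([dominance_fit_table(matrix, c, alpha)
                              for c in cross_registry(matrix.data)],
                             ignore_index=True)
            fits.to_csv(out / "dominance_fits.csv", index=False)
        with _stage("trait_variance", timings):
            tv = pd.concat(
                [family_trait_variance(matrix, c, g)
                 for c in cross_registry(matrix.data) for g in ("F1", "F2")],
                ignore_index=True)
            tv.to_csv(out / "trait_variance.csv", index=False)

    with _stage("snowball", timings):
        counts = significant_pair_counts(matrix, alpha)
        counts.to_csv(out / "snowball_counts.csv", index=False)
        snow = snowball(counts, dec, alpha)
        snow_dict = {g: {"linear_slope": r.linear_slope, "linear_p": r.linear_p,
                         "quadratic_coef": r.quadratic_coef,
                         "quadratic_p": r.quadratic_p}
                     for g, r in snow.items()}

    with _stage("correlations", timings):
        corr = f2_correlation_summary(matrix)

    report = RunReport(seed=seed, version=__version__,
                       divergences={k: float(v) for k, v in divergences.items()},
                       regressions=regs, snowball=snow_dict,
                       f2_correlations=corr, n_individuals=len(matrix.data),
                       stage_seconds=timings)
    report.to_json(out / "report.json")
    return report


def run_pipeline(input_path: str | Path, config: TraitConfig,
                 out_dir: str | Path, alpha: float = 0.05) -> RunReport:
    """Raw CSV -> exclusions -> complete cases -> preprocessing -> analysis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_trait_table(input_path, config)
    table, excl = apply_exclusions(table)
    table, incomplete = drop_incomplete_cases(table)
    pd.concat([excl.to_frame(), incomplete.to_frame()], ignore_index=True) \
        .to_csv(out / "exclusions.csv", index=False)
    matrix = preprocess(table)
    matrix.to_csv(out / "standardized.csv")
    matrix.transforms.to_json(out / "transforms.json")
    return analyze_matrix(matrix, out, alpha=alpha)


def run_simulated(sim_config: SimulationConfig | None, out_dir: str | Path,
                  seed: int = 0, alpha: float = 0.05) -> RunReport:
    """Simulate a study in analysis space and run every downstream stage."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_study(sim_config, seed=seed)
    matrix.to_csv(out / "simulated_standardized.csv")
    write_truth(truth, out / "truth.json")
    return analyze_matrix(matrix, out, alpha=alpha, seed=seed)
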