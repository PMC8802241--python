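from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mismatchlab import SimulationConfig, StandardizedMatrix, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One default-condition simulated study (12 crosses, 15 traits)."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def small_study():
    """Cheap study for structural tests: 4 crosses, 6 traits."""
    cfg = SimulationConfig(n_crosses=4, n_traits=6, seed=5)
    return simulate_study(cfg)


def make_matrix(rows: list[dict], traits: list[str]) -> StandardizedMatrix:
    """Hand-built standardized matrix from row dicts."""
    return StandardizedMatrix(pd.DataFrame(rows), traits)


def toy_cross_matrix(pm: np.ndarray, pf: np.ndarray, hybrids: np.ndarray,
                     generation: str = "F1",
                     hybrid_families: list[str] | None = None) -> StandardizedMatrix:
    """A single cross with zero-variance parents placed exactly at the given
    mean vectors and explicit hybrid coordinates."""
    traits = [f"t{i}" for i in range(len(pm))]
    rows = []
    for k in range(3):
        rows.append({"individual_id": f"pm{k}", "population": "marine",
                     "cross_id": "", "generation": "PM", "family_id": f"pmf{k % 2}",
                     **dict(zip(traits, pm))})
        rows.append({"individual_id": f"pf{k}", "population": "fw", "cross_id": "c1",
                     "generation": "PF", "family_id": f"pff{k % 2}",
                     **dict(zip(traits, pf))})
    hybrids = np.atleast_2d(hybrids)
    fams = hybrid_families or ["hf0"] * len(hybrids)
    for k, h in enumerate(hybrids):
        rows.append({"individual_id": f"h{k}", "population": "fw", "cross_id": "c1",
                     "generation": generation, "family_id": fams[k],
                     **dict(zip(traits, h))})
    return make_matrix(rows, traits)
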