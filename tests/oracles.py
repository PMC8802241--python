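"""Independent oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: distances to
the parent line are found by brute-force grid search over the line parameter,
and distribution means come from closed forms evaluated through scipy.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def grid_line_distance(f: np.ndarray, pm: np.ndarray, pf: np.ndarray) -> float:
    """Minimum distance from point f to the line pm + t*(pf-pm), by a coarse
    grid over t followed by a fine grid around the coarse minimum. The
    objective is quadratic in t, so the two-stage search brackets the true
    minimum; the grid range is chosen so the foot of the perpendicular is
    always inside it (|t*| <= |f - pm| / |pf - pm|)."""
    f = np.asarray(f, dtype=float)
    pm = np.asarray(pm, dtype=float)
    axis = np.asarray(pf, dtype=float) - pm
    reach = np.linalg.norm(f - pm) / np.linalg.norm(axis) + 1.0
    coarse = np.linspace(-reach, reach, 2001)
    step = coarse[1] - coarse[0]
    d = np.linalg.norm(pm + coarse[:, None] * axis - f, axis=1)
    t0 = coarse[np.argmin(d)]
    fine = np.linspace(t0 - 2 * step, t0 + 2 * step, 4001)
    return float(np.linalg.norm(pm + fine[:, None] * axis - f, axis=1).min())


def chi_mean(k: int) -> float:
    """E[chi_k] = sqrt(2) * Gamma((k+1)/2) / Gamma(k/2)."""
    return float(np.sqrt(2.0) * np.exp(gammaln((k + 1) / 2) - gammaln(k / 2)))


def half_normal_mean(s: float) -> float:
    """E|N(0, s^2)| = s * sqrt(2/pi)."""
    return float(s * np.sqrt(2.0 / np.pi))
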