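"""Restricted cubic spline basis for age-specific baseline log-odds.

Harrell-style natural cubic spline: with knots t_1 < ... < t_K the basis has
K-1 columns — the linear term plus K-2 cubic terms that are constrained to be
linear beyond the boundary knots.  The cubic terms are normalised by
(t_K - t_1)^2 so all columns are on roughly the scale of the variable itself.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rcs_basis", "default_knots", "rcs_names"]

#: percentiles used when knots are derived from observed event ages
DEFAULT_KNOT_PERCENTILES = (5.0, 27.5, 50.0, 72.5, 95.0)


def default_knots(event_ages: np.ndarray, n_knots: int = 5) -> np.ndarray:
    """Knot locations at conventional percentiles of observed event ages."""
    event_ages = np.asarray(event_ages, dtype=float)
    if event_ages.size < n_knots:
        raise ValueError("too few events to place spline knots")
    if n_knots == 5:
        pct = DEFAULT_KNOT_PERCENTILES
    else:
        pct = np.linspace(5.0, 95.0, n_knots)
    knots = np.percentile(event_ages, pct)
    if np.unique(knots).size != len(knots):
        raise ValueError("degenerate event-age distribution: duplicate knots")
    return knots


def rcs_names(n_knots: int, prefix: str = "age_rcs") -> list:
    return [f"{prefix}_{j}" for j in range(1, n_knots)]


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``x``.

    Returns an (n, K-1) array whose first column is ``x`` itself (no
    intercept); a linear function of ``x`` is reproduced exactly by loading
    only that column.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 3:
        raise ValueError("need at least 3 increasing knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    K = knots.size
    t = knots
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    plus3 = lambda u: np.clip(u, 0.0, None) ** 3
    for j in range(K - 2):
        term = (
            plus3(x - t[j])
            - plus3(x - t[K - 2]) * (t[K - 1] - t[j]) / (t[K - 1] - t[K - 2])
            + plus3(x - t[K - 1]) * (t[K - 2] - t[j]) / (t[K - 1] - t[K - 2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)
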