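"""Quantitative airborne-exposure metric and lagged exposure windows.

Exposure while at work is recorded as a category (light / medium / heavy) and
converted to a cumulative concentration-time metric in mg/m^3-years:

    d = c_light * years_light + c_medium * years_medium + gamma * c_heavy * years_heavy

where the concentrations are time-weighted work-area means and ``gamma``
down-weights heavy-area time for the use of filtration masks.  Hazard models
use the metric split into lagged windows of time-since-exposure, with no
contribution inside the lag or beyond a truncation horizon.

Window convention (fixed here, documented once): time is discretised to whole
years, a person-period is the half-open age interval [a, a+1), and an
increment accrued in period [a-k-1, a-k) lies at distance ``k`` years before
age ``a``.  A window (lo, hi] collects distances k with lo < k <= hi.  The
"recent" window used by the employment models collects distances 0..4, i.e.
exposure accrued during the five periods immediately preceding the current
one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ExposureCoefficients",
    "LagSpec",
    "CATEGORY_LEVELS",
    "exposure_metric",
    "annual_increment",
    "lagged_window_sums",
    "window_matrix",
]

#: ordered category labels; "none" is the unemployed / unexposed state.
CATEGORY_LEVELS = ("none", "light", "medium", "heavy")


@dataclass(frozen=True)
class ExposureCoefficients:
    """Work-area concentrations (mg/m^3) and the heavy-area discount weight."""

    conc_light: float = 0.29
    conc_medium: float = 0.58
    conc_heavy: float = 11.4
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if not (self.conc_light > 0 and self.conc_medium > 0 and self.conc_heavy > 0):
            raise ValueError("work-area concentrations must be positive")
        if not (self.conc_light < self.conc_medium < self.conc_heavy):
            raise ValueError("concentrations must be strictly increasing light < medium < heavy")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")

    def increments(self) -> np.ndarray:
        """Per-year metric increment for each category (none, light, medium, heavy)."""
        return np.array(
            [0.0, self.conc_light, self.conc_medium, self.gamma * self.conc_heavy]
        )


@dataclass(frozen=True)
class LagSpec:
    """Lag and time-since-exposure windows (years) for the hazard models.

    ``windows`` are (lo, hi] distances-before-now; the first window starts at
    the lag and windows must be contiguous, ordered and non-overlapping.
    Exposure beyond ``windows[-1][1]`` years before now contributes nothing.
    """

    lag: int = 2
    windows: tuple = ((2, 5), (5, 10), (10, 20))
    #: distances (inclusive) pooled into the employment models' recent window
    recent: tuple = (0, 4)

    def __post_init__(self) -> None:
        if self.windows[0][0] != self.lag:
            raise ValueError("first window must start at the lag")
        for (a0, a1), (b0, b1) in zip(self.windows, self.windows[1:]):
            if a1 != b0:
                raise ValueError("windows must be contiguous and ordered")
        for lo, hi in self.windows:
            if hi <= lo:
                raise ValueError(f"empty window ({lo}, {hi}]")

    @property
    def names(self) -> list:
        return [f"w_{lo}_{hi}" for lo, hi in self.windows]


def exposure_metric(
    years_light: float,
    years_medium: float,
    years_heavy: float,
    coeffs: ExposureCoefficients = ExposureCoefficients(),
) -> float:
    """Cumulative exposure d (mg/m^3-years) from category-specific durations."""
    if years_light < 0 or years_medium < 0 or years_heavy < 0:
        raise ValueError("durations must be non-negative")
    return (
        coeffs.conc_light * years_light
        + coeffs.conc_medium * years_medium
        + coeffs.gamma * coeffs.conc_heavy * years_heavy
    )


def annual_increment(
    category: str, coeffs: ExposureCoefficients = ExposureCoefficients()
) -> float:
    """Metric accrued in one year spent in ``category``."""
    try:
        idx = CATEGORY_LEVELS.index(category)
    except ValueError:
        raise ValueError(
            f"unknown exposure category {category!r}; expected one of {CATEGORY_LEVELS}"
        ) from None
    return float(coeffs.increments()[idx])


def lagged_window_sums(
    history: Sequence[float],
    current_age: int,
    spec: LagSpec = LagSpec(),
    start_age: int = 0,
) -> tuple:
    """Window sums at ``current_age`` for a single contiguous increment history.

    ``history[i]`` is the increment accrued in period
    [start_age + i, start_age + i + 1); the history must cover every period
    from ``start_age`` up to ``current_age - 1`` (unemployed years carry 0).
    """
    history = np.asarray(history, dtype=float)
    if history.ndim != 1:
        raise ValueError("history must be one-dimensional")
    n = history.shape[0]
    if np.any(np.isnan(history)):
        raise ValueError("history has gaps (NaN); unemployed years must carry increment 0")
    if start_age + n < current_age:
        raise ValueError(
            f"history covers ages [{start_age}, {start_age + n}) but must reach {current_age}"
        )
    out = []
    for lo, hi in spec.windows:
        # distance k in (lo, hi] -> source period start s in [age-hi-1, age-lo-2]
        s0 = max(current_age - hi - 1 - start_age, 0)
        s1 = min(current_age - lo - 1 - start_age, n)  # exclusive
        out.append(float(history[s0:s1].sum()) if s1 > s0 else 0.0)
    return tuple(out)


def window_matrix(
    inc: np.ndarray, spec: LagSpec = LagSpec(), include_recent: bool = True
) -> dict:
    """Window sums for every (row, age) cell of an increment matrix.

    ``inc[i, a]`` is the increment of individual ``i`` in the period starting
    at age-axis index ``a``.  Returns a dict mapping window name to a matrix of
    the same shape holding the window value evaluated *at* each age index.
    Used by the person-period expansion; the simulation engine computes the
    same quantities incrementally.
    """
    n, m = inc.shape
    cum = np.zeros((n, m + 1))
    np.cumsum(inc, axis=1, out=cum[:, 1:])

    def span_sum(lo: int, hi: int) -> np.ndarray:
        # distances k = a - s - 1 in [lo, hi]  <=>  source periods s in [a-hi-1, a-lo-1]
        ages = np.arange(m)
        s_first = np.clip(ages - hi - 1, 0, m)
        s_last = np.clip(ages - lo, 0, m)  # exclusive upper bound
        return cum[:, s_last] - cum[:, s_first]

    result = {}
    for (lo, hi), name in zip(spec.windows, spec.names):
        # distances strictly greater than lo: k in [lo+1, hi]
        result[name] = span_sum(lo + 1, hi)
    if include_recent:
        lo, hi = spec.recent
        result["w_recent"] = span_sum(lo, hi)
    return result
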