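"""Person-period expansion and design-matrix construction.

The analysis substrate is one row per worker per year at risk, from entry age
to the earliest of death, the age cap, or the administrative end of follow-up.
Each row carries the engineered covariates the hazard models use: lagged
exposure-window sums (post-entry exposure only; pre-entry exposure enters as a
single linear baseline term), cumulative time at work, calendar year, baseline
covariates, and outcome indicators.

Employment-transition outcomes are defined to match how the simulation draws
them: the row at age ``a`` carries ``leave_work`` = 1 if the worker was
employed at ``a`` and not employed at ``a+1`` (NaN when ``a+1`` is not
observed, i.e. on each worker's final row), and symmetrically for
``return_work`` on unemployed rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import CATEGORY_LEVELS, ExposureCoefficients, LagSpec, window_matrix
from .splines import rcs_basis, rcs_names

__all__ = ["DesignInfo", "expand_to_person_periods", "worker_outcomes"]

AGE_CENTER = 60.0
AGE_SCALE = 10.0
YEAR_CENTER = 1960.0
YEAR_SCALE = 10.0

CAUSE_LEVELS = ("none", "resp_cancer", "heart", "other")
DEATH_COLUMNS = {"resp_cancer": "d_resp", "heart": "d_heart", "other": "d_other"}


@dataclass(frozen=True)
class DesignInfo:
    """Covariate vocabulary shared by fitting, generation and simulation.

    Age enters through a restricted cubic spline on the centred/scaled age
    ``(age - 60) / 10`` with knots stored on the same scale; calendar year is
    centred/scaled the same way, so all design columns are O(1).
    """

    knots: tuple  # RCS knots on the raw age scale

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(k) <= 0):
            raise ValueError("spline knots must be strictly increasing")
        object.__setattr__(self, "knots", tuple(float(v) for v in k))

    @property
    def knots_scaled(self) -> np.ndarray:
        return (np.asarray(self.knots) - AGE_CENTER) / AGE_SCALE

    def column_names(self, covariates: Sequence[str], intercept: bool = True) -> list:
        names = ["intercept"] if intercept else []
        for c in covariates:
            if c == "age_rcs":
                names.extend(rcs_names(len(self.knots)))
            else:
                names.append(c)
        return names

    def build(
        self,
        data: Mapping[str, np.ndarray],
        covariates: Sequence[str],
        intercept: bool = True,
    ) -> tuple:
        """Assemble (X, column_names) from a mapping of 1-D arrays.

        Accepts a DataFrame or a plain dict of numpy arrays.  Supported terms:
        ``age_rcs`` (spline block), ``age``, ``year``, ``age_x_year``,
        ``cum_work``, ``pre_entry_years``, any raw column present in ``data``,
        and products written ``a:b`` of two already-resolvable terms.
        """

        def get(name: str) -> np.ndarray:
            if isinstance(data, pd.DataFrame):
                if name in data.columns:
                    return data[name].to_numpy(dtype=float)
            elif name in data:
                return np.asarray(data[name], dtype=float)
            raise KeyError(name)

        def term(name: str) -> np.ndarray:
            if name == "age":
                return (get("age") - AGE_CENTER) / AGE_SCALE
            if name == "year":
                return (get("calendar_year") - YEAR_CENTER) / YEAR_SCALE
            if name == "age_x_year":
                return term("age") * term("year")
            if name == "cum_work":
                return get("cum_years_worked") / 10.0
            if name == "pre_entry_years":
                return get("pre_entry_years_worked") / 10.0
            try:
                return get(name)
            except KeyError:
                raise ValueError(f"unknown covariate {name!r} in model specification") from None

        cols, names = [], []
        if intercept:
            names.append("intercept")
        for c in covariates:
            if c == "age_rcs":
                z = (np.atleast_1d(get("age")).astype(float) - AGE_CENTER) / AGE_SCALE
                block = rcs_basis(z, self.knots_scaled)
                cols.append(block)
                names.extend(rcs_names(len(self.knots)))
            elif ":" in c:
                a, b = c.split(":", 1)
                cols.append((term(a) * term(b))[:, None])
                names.append(c)
            else:
                cols.append(np.atleast_1d(term(c)).astype(float)[:, None])
                names.append(c)
        if cols:
            n = max(col.shape[0] for col in cols)
            cols = [np.broadcast_to(col, (n, col.shape[1])) for col in cols]
        elif isinstance(data, pd.DataFrame):
            n = len(data)
        else:
            n = next(
                (len(v) for v in data.values() if isinstance(v, (np.ndarray, list))), 1
            )
        if intercept:
            cols.insert(0, np.ones((n, 1)))
        X = np.concatenate(cols, axis=1) if cols else np.empty((n, 0))
        return X, names


def expand_to_person_periods(
    baseline: pd.DataFrame,
    history: pd.DataFrame,
    coeffs: ExposureCoefficients = ExposureCoefficients(),
    lag_spec: LagSpec = LagSpec(),
) -> pd.DataFrame:
    """Build the person-period table from baseline + annual history tables.

    One row per worker-year at risk with engineered covariates and outcome
    indicators; see module docstring for the transition-outcome convention.
    """
    required_b = {"worker_id", "entry_age", "us_born", "pre_entry_years_worked"}
    missing = required_b - set(baseline.columns)
    if missing:
        raise ValueError(f"baseline table missing columns: {sorted(missing)}")
    required_h = {"worker_id", "age", "calendar_year", "employed", "exposure_category", "death_cause"}
    missing = required_h - set(history.columns)
    if missing:
        raise ValueError(f"history table missing columns: {sorted(missing)}")

    h = history.sort_values(["worker_id", "age"], kind="mergesort").reset_index(drop=True)
    if h.duplicated(["worker_id", "age"]).any():
        raise ValueError("overlapping person-periods: duplicate (worker_id, age) rows")

    wid, workers = pd.factorize(h["worker_id"], sort=False)
    ages = h["age"].to_numpy(dtype=int)
    same_next = np.empty(len(h), dtype=bool)
    same_next[:-1] = wid[1:] == wid[:-1]
    same_next[-1] = False
    gap = same_next & (np.roll(ages, -1) != ages + 1)
    if gap.any():
        bad = h.loc[gap, "worker_id"].iloc[0]
        raise ValueError(f"history for worker {bad!r} has a gap; histories must be contiguous")

    cause = h["death_cause"].to_numpy()
    unknown = ~np.isin(cause, CAUSE_LEVELS)
    if unknown.any():
        raise ValueError(f"unknown cause label {cause[unknown][0]!r}")
    died = cause != "none"
    if (died & same_next).any():
        raise ValueError("death recorded before a worker's final person-period")
    per_worker_deaths = pd.Series(died).groupby(wid).sum()
    if (per_worker_deaths > 1).any():
        raise ValueError("more than one death recorded for a worker")

    cat = h["exposure_category"].to_numpy()
    bad_cat = ~np.isin(cat, CATEGORY_LEVELS)
    if bad_cat.any():
        raise ValueError(f"unknown exposure category {cat[bad_cat][0]!r}")
    employed = h["employed"].to_numpy(dtype=int)
    if ((cat != "none") & (employed == 0)).any():
        raise ValueError("exposure category present in an unemployed person-period")

    level_order = {c: i for i, c in enumerate(CATEGORY_LEVELS)}
    cat_idx = np.vectorize(level_order.get)(cat)
    inc = coeffs.increments()[cat_idx]

    # pivot to (worker, age) matrices for window sums and cumulative work time
    age_min = int(ages.min())
    age_span = int(ages.max()) - age_min + 1
    n_workers = len(workers)
    inc_mat = np.zeros((n_workers, age_span))
    emp_mat = np.zeros((n_workers, age_span))
    aidx = ages - age_min
    inc_mat[wid, aidx] = inc
    emp_mat[wid, aidx] = employed
    wins = window_matrix(inc_mat, lag_spec, include_recent=True)
    cumwork = np.cumsum(emp_mat, axis=1)

    out = pd.DataFrame(
        {
            "worker_id": h["worker_id"].to_numpy(),
            "age": ages,
            "calendar_year": h["calendar_year"].to_numpy(dtype=int),
            "employed": employed,
            "exposure_category": cat,
            "increment": inc,
            "cum_years_worked": cumwork[wid, aidx],
        }
    )
    for name, mat in wins.items():
        out[name] = mat[wid, aidx]

    b = baseline.set_index("worker_id")
    expo_col = (
        "pre_entry_exposure"
        if "pre_entry_exposure" in b.columns
        else "pre_entry_exposure_mgm3yr"
    )
    for col, src in [
        ("us_born", "us_born"),
        ("pre_entry_years_worked", "pre_entry_years_worked"),
        ("pre_entry_exposure", expo_col),
        ("entry_age", "entry_age"),
    ]:
        out[col] = b[src].reindex(out["worker_id"]).to_numpy()

    for label, col in DEATH_COLUMNS.items():
        out[col] = (cause == label).astype(int)
    out["at_risk"] = 1

    emp_next = np.where(same_next, np.roll(employed, -1), np.nan)
    out["leave_work"] = np.where(
        (employed == 1) & ~np.isnan(emp_next), 1.0 - emp_next, np.nan
    )
    out["return_work"] = np.where(
        (employed == 0) & ~np.isnan(emp_next), emp_next, np.nan
    )
    return out


def worker_outcomes(history: pd.DataFrame) -> pd.DataFrame:
    """Per-worker (entry_age, exit_age, cause) summary for risk estimation."""
    h = history.sort_values(["worker_id", "age"], kind="mergesort")
    g = h.groupby("worker_id", sort=False)
    out = pd.DataFrame(
        {
            "entry_age": g["age"].first(),
            "exit_age": g["age"].last(),
            "cause": g["death_cause"].last(),
        }
    )
    if (out["exit_age"] < out["entry_age"]).any():
        raise ValueError("worker with exit before entry")
    return out.reset_index()
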