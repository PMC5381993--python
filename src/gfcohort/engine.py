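"""Parametric g-formula Monte Carlo engine.

Baseline records are resampled with replacement and each pseudo-worker's
annual history is simulated forward from the fitted discrete-time models
under an intervention on exposure.  The per-period update order is fixed:

1. employment transition, drawn from the leave-work / return-to-work models
   using the *previous* period's covariates (1-period lag, avoiding
   simultaneity between exposure and leaving work within a period);
2. exposure category — drawn from the proportional-odds model under the
   natural course when employed, forced by the intervention otherwise — and
   the annual metric increment;
3. lagged exposure windows rebuilt;
4. death resolved among the competing causes by a single categorical draw
   with sequentially conditioned probabilities
   (h_resp, h_heart(1-h_resp), h_other(1-h_resp)(1-h_heart), survive);
5. age and calendar year advance; administrative censoring at the age cap or
   the administrative end year.

Randomness: one master seed spawns a substream for baseline sampling and a
(worker x period x draw-slot)-indexed uniform array for the simulation, so
results are invariant to execution order.  Interventions simulated from the
same seed share those uniforms (common random numbers), which sharpens
contrasts between interventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .exposure import CATEGORY_LEVELS, ExposureCoefficients, LagSpec
from .models import FittedModel, predict_category_probs, predict_hazard
from .personperiod import CAUSE_LEVELS, DesignInfo

__all__ = [
    "InterventionSpec",
    "INTERVENTIONS",
    "ModelSuite",
    "EngineState",
    "SimulatedHistories",
    "sample_baselines",
    "step_person_year",
    "simulate_pseudo_cohort",
    "histories_from_tables",
]

MODEL_NAMES = ("d_resp", "d_heart", "d_other", "leave_work", "return_work", "exposure_category")
CAUSE_CODES = {1: "resp_cancer", 2: "heart", 3: "other"}


@dataclass(frozen=True)
class InterventionSpec:
    """One of the five exposure interventions.

    ``natural_course`` draws exposure from the fitted ordinal model;
    ``never_exposed`` forces a zero increment in every period; the three
    ``always_X`` kinds force category X whenever employed (and ``none`` when
    not at work).
    """

    kind: str

    KINDS = ("natural_course", "never_exposed", "always_light", "always_medium", "always_heavy")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown intervention {self.kind!r}; expected one of {self.KINDS}")

    @property
    def forced_category(self) -> Optional[int]:
        """Category code forced while employed, or None for the natural course."""
        if self.kind == "natural_course":
            return None
        if self.kind == "never_exposed":
            return 0
        return {"always_light": 1, "always_medium": 2, "always_heavy": 3}[self.kind]


INTERVENTIONS = {k: InterventionSpec(k) for k in InterventionSpec.KINDS}


@dataclass
class ModelSuite:
    """The six fitted discrete-time models plus the shared covariate context."""

    models: Dict[str, FittedModel]
    design: DesignInfo
    coeffs: ExposureCoefficients = field(default_factory=ExposureCoefficients)
    lag_spec: LagSpec = field(default_factory=LagSpec)
    max_age: int = 90
    admin_end_year: int = 1990

    def __post_init__(self) -> None:
        missing = set(MODEL_NAMES) - set(self.models)
        if missing:
            raise ValueError(f"model suite missing models: {sorted(missing)}")

    def __getitem__(self, name: str) -> FittedModel:
        return self.models[name]

    def _plan(self) -> tuple:
        """Cached union covariate list and per-model column indices.

        The engine assembles one design matrix per period covering every
        model's columns, then slices per-model views; this keeps the
        per-period Python overhead flat in the number of models.
        """
        if getattr(self, "_plan_cache", None) is None:
            union: list = []
            for name in MODEL_NAMES:
                for c in self.models[name].spec.covariates:
                    if c not in union:
                        union.append(c)
            union_names = self.design.column_names(union, intercept=True)
            idx = {}
            for name in MODEL_NAMES:
                m = self.models[name]
                cols = self.design.column_names(
                    m.spec.covariates, intercept=(m.kind == "binary_logit")
                )
                idx[name] = np.array([union_names.index(c) for c in cols], dtype=int)
            self._plan_cache = (union, idx)
        return self._plan_cache

    @property
    def all_converged(self) -> bool:
        return all(m.converged for m in self.models.values())


@dataclass
class EngineState:
    """Vectorised simulation state for a block of pseudo-workers."""

    entry_age: np.ndarray
    birth_year: np.ndarray
    us_born: np.ndarray
    pre_entry_years_worked: np.ndarray
    pre_entry_exposure: np.ndarray
    age_min: int
    n_steps: int
    age: Optional[int] = None  # age currently being processed (None before start)

    def __post_init__(self) -> None:
        n = len(self.entry_age)
        self.n = n
        self.employed = np.zeros(n, dtype=np.int8)
        self.cum_work = np.zeros(n, dtype=float)
        self.alive = np.ones(n, dtype=bool)
        self.entered = np.zeros(n, dtype=bool)
        self.done = np.zeros(n, dtype=bool)  # dead or administratively censored
        self.cause = np.zeros(n, dtype=np.int8)  # 0 none, 1 resp, 2 heart, 3 other
        self.exit_age = np.full(n, -1, dtype=int)
        self.inc = np.zeros((n, self.n_steps), dtype=float)
        self.cat = np.zeros((n, self.n_steps), dtype=np.int8)
        self.emp = np.zeros((n, self.n_steps), dtype=np.int8)
        self.prev_X: Optional[np.ndarray] = None  # previous period's union design
        self.prev_employed: Optional[np.ndarray] = None

    def windows_at(self, a: int, lag_spec: LagSpec) -> dict:
        """Lagged window sums evaluated at age ``a`` (current period excluded)."""
        ai = a - self.age_min
        out = {}
        spans = [(lo + 1, hi) for lo, hi in lag_spec.windows]
        names = list(lag_spec.names) + ["w_recent"]
        spans.append(lag_spec.recent)
        for name, (lo, hi) in zip(names, spans):
            s0 = max(ai - hi - 1, 0)
            s1 = max(ai - lo, 0)
            out[name] = self.inc[:, s0:s1].sum(axis=1) if s1 > s0 else np.zeros(self.n)
        return out


def sample_baselines(
    baseline: pd.DataFrame,
    mc_size: int,
    rng: np.random.Generator,
    identity: bool = False,
) -> pd.DataFrame:
    """With-replacement sample of baseline rows (joint distribution preserved).

    ``identity=True`` is a test hook returning the table unchanged (requires
    ``mc_size`` equal to the table length).
    """
    if len(baseline) == 0:
        raise ValueError("empty baseline table")
    if mc_size <= 0:
        raise ValueError("mc_size must be positive")
    if identity:
        if mc_size != len(baseline):
            raise ValueError("identity sampling requires mc_size == len(baseline)")
        return baseline.reset_index(drop=True)
    idx = rng.integers(0, len(baseline), size=mc_size)
    return baseline.iloc[idx].reset_index(drop=True)


def _init_state(baseline: pd.DataFrame, max_age: int) -> EngineState:
    entry_age = baseline["entry_age"].to_numpy(dtype=int)
    if "birth_year" in baseline.columns:
        birth = baseline["birth_year"].to_numpy(dtype=int)
    else:
        birth = baseline["entry_year"].to_numpy(dtype=int) - entry_age
    expo_col = (
        "pre_entry_exposure"
        if "pre_entry_exposure" in baseline.columns
        else "pre_entry_exposure_mgm3yr"
    )
    age_min = int(entry_age.min())
    return EngineState(
        entry_age=entry_age,
        birth_year=birth,
        us_born=baseline["us_born"].to_numpy(dtype=float),
        pre_entry_years_worked=baseline["pre_entry_years_worked"].to_numpy(dtype=float),
        pre_entry_exposure=baseline[expo_col].to_numpy(dtype=float),
        age_min=age_min,
        n_steps=max_age - age_min,
    )


def _predict_rows(model: FittedModel, X_union: np.ndarray, cols: np.ndarray, sel) -> np.ndarray:
    X = X_union[np.ix_(sel, cols)]
    if model.kind == "binary_logit":
        return predict_hazard(model, X)
    return predict_category_probs(model, X)


def _advance(
    state: EngineState,
    a: int,
    suite: ModelSuite,
    intervention: InterventionSpec,
    u_emp: np.ndarray,
    u_cat: np.ndarray,
    u_die: np.ndarray,
) -> None:
    """Execute the fixed per-period update for age ``a`` in place.

    The uniform arrays are indexed by pseudo-worker; only entries for active
    workers are consumed.
    """
    design = suite.design
    union_covs, col_idx = suite._plan()
    ai = a - state.age_min
    new = state.alive & ~state.done & ~state.entered & (state.entry_age == a)
    state.entered |= new
    active = state.entered & state.alive & ~state.done
    if not active.any():
        state.age = a
        state.prev_X = None
        return

    # (1) employment transition (entrants start employed: cohort entry requires
    # a completed year of work, so the entry period is an employed one),
    # drawn from the *previous* period's covariates
    cont = active & ~new
    if cont.any() and state.prev_X is not None:
        prev_emp = state.prev_employed
        for model_name, at_work, becomes in (("leave_work", 1, 0), ("return_work", 0, 1)):
            sel = np.flatnonzero(cont & (prev_emp == at_work))
            if sel.size:
                p = _predict_rows(suite[model_name], state.prev_X, col_idx[model_name], sel)
                moved = u_emp[sel] < p
                state.employed[sel] = np.where(moved, becomes, at_work)
    state.employed[new] = 1
    state.employed[~active] = 0

    # (2,3) cumulative work time, lagged windows; current exposure is drawn
    # below but cannot enter any model's covariates for this period (lag >= 1)
    state.cum_work[active] += state.employed[active]
    wins = state.windows_at(a, suite.lag_spec)
    cov = {
        "age": float(a),  # scalar: the spline basis row is shared by all workers
        "calendar_year": (state.birth_year + a).astype(float),
        "employed": state.employed.astype(float),
        "cum_years_worked": state.cum_work,
        "us_born": state.us_born,
        "pre_entry_years_worked": state.pre_entry_years_worked,
        "pre_entry_exposure": state.pre_entry_exposure,
        **wins,
    }
    X_union, _ = design.build(cov, union_covs, intercept=True)

    cat_codes = np.zeros(state.n, dtype=np.int8)
    emp_active = active & (state.employed == 1)
    forced = intervention.forced_category
    if forced is None:
        sel = np.flatnonzero(emp_active)
        if sel.size:
            probs = _predict_rows(
                suite["exposure_category"], X_union, col_idx["exposure_category"], sel
            )
            cum = np.cumsum(probs, axis=1)
            draw = (u_cat[sel, None] > cum).sum(axis=1)  # 0..J-1 among employed cats
            cat_codes[sel] = draw + 1  # shift past "none"
    elif forced > 0:
        cat_codes[emp_active] = forced
    state.cat[active, ai] = cat_codes[active]
    state.inc[active, ai] = suite.coeffs.increments()[cat_codes[active]]
    state.emp[active, ai] = state.employed[active]

    # (4) death, sequentially conditioned single categorical draw; the three
    # cause models usually share one design, so predict with a single matmul
    sel = np.flatnonzero(active)
    death_names = ("d_resp", "d_heart", "d_other")
    if np.array_equal(col_idx["d_resp"], col_idx["d_heart"]) and np.array_equal(
        col_idx["d_resp"], col_idx["d_other"]
    ):
        Xd = X_union[np.ix_(sel, col_idx["d_resp"])]
        B = np.column_stack([suite[n].params for n in death_names])
        h = expit(Xd @ B)
    else:
        h = np.column_stack(
            [_predict_rows(suite[name], X_union, col_idx[name], sel) for name in death_names]
        )
    p1 = h[:, 0]
    p2 = h[:, 1] * (1 - h[:, 0])
    p3 = h[:, 2] * (1 - h[:, 0]) * (1 - h[:, 1])
    u = u_die[sel]
    cause = np.zeros(sel.size, dtype=np.int8)
    cause[u < p1] = 1
    cause[(u >= p1) & (u < p1 + p2)] = 2
    cause[(u >= p1 + p2) & (u < p1 + p2 + p3)] = 3
    died = cause > 0
    didx = sel[died]
    state.cause[didx] = cause[died]
    state.alive[didx] = False
    state.done[didx] = True
    state.exit_age[didx] = a

    # (5) administrative censoring: last period at the age cap or admin end year
    surv = active.copy()
    surv[didx] = False
    censor = surv & ((a + 1 >= suite.max_age) | (state.birth_year + a >= suite.admin_end_year))
    state.exit_age[censor] = a
    state.done[censor] = True

    state.age = a
    state.prev_X = X_union
    state.prev_employed = state.employed.copy()


def step_person_year(
    state: EngineState,
    suite: ModelSuite,
    intervention: InterventionSpec,
    rng: np.random.Generator,
) -> EngineState:
    """Advance the simulation state one person-year (spec'd single-step entry).

    Raises if every worker in the state is already dead or censored.
    """
    if not (state.alive & ~state.done).any():
        raise ValueError("inconsistent state: stepping a dead/censored state")
    a = state.age_min if state.age is None else state.age + 1
    if a >= suite.max_age:
        raise ValueError(f"cannot step past the age cap {suite.max_age}")
    u = rng.random((3, state.n))
    _advance(state, a, suite, intervention, u[0], u[1], u[2])
    return state


@dataclass
class SimulatedHistories:
    """Per-pseudo-worker simulated histories under one intervention."""

    intervention: str
    entry_age: np.ndarray
    exit_age: np.ndarray
    cause_code: np.ndarray  # 0 none (administrative censoring), 1 resp, 2 heart, 3 other
    birth_year: np.ndarray
    inc: np.ndarray  # (n, n_steps) annual exposure increments
    cat: np.ndarray  # (n, n_steps) category codes
    emp: np.ndarray  # (n, n_steps) employment indicators
    age_min: int

    @property
    def n(self) -> int:
        return len(self.entry_age)

    @property
    def cause(self) -> np.ndarray:
        labels = np.array(CAUSE_LEVELS)
        return labels[self.cause_code]

    def cumulative_exposure(self) -> np.ndarray:
        """Total simulated post-entry exposure per pseudo-worker (mg/m^3-years)."""
        return self.inc.sum(axis=1)

    def person_years(self, max_age: Optional[int] = None) -> float:
        exit_age = self.exit_age
        if max_age is not None:
            exit_age = np.minimum(exit_age, max_age - 1)
        return float(np.sum(exit_age - self.entry_age + 1))

    def to_history_frame(self) -> pd.DataFrame:
        """Dump to the same annual history-table schema as the cohort generator."""
        rows_per = self.exit_age - self.entry_age + 1
        wid = np.repeat(np.arange(self.n), rows_per)
        age = np.concatenate([np.arange(e, x + 1) for e, x in zip(self.entry_age, self.exit_age)])
        ai = age - self.age_min
        cat_lab = np.array(CATEGORY_LEVELS)[self.cat[wid, ai]]
        cause_lab = np.where(
            age == self.exit_age[wid], np.array(CAUSE_LEVELS)[self.cause_code[wid]], "none"
        )
        return pd.DataFrame(
            {
                "worker_id": wid,
                "age": age,
                "calendar_year": self.birth_year[wid] + age,
                "employed": self.emp[wid, ai].astype(int),
                "exposure_category": cat_lab,
                "death_cause": cause_lab,
            }
        )


def histories_from_tables(
    history: pd.DataFrame,
    coeffs: ExposureCoefficients = ExposureCoefficients(),
    label: str = "observed",
) -> SimulatedHistories:
    """Pack an observed annual-history table into a SimulatedHistories object.

    Lets observed data flow through the same estimator code paths (cumulative
    incidence, person-years, calibration) as simulated pseudo-cohorts.
    """
    h = history.sort_values(["worker_id", "age"], kind="mergesort")
    wid, _ = pd.factorize(h["worker_id"], sort=False)
    ages = h["age"].to_numpy(dtype=int)
    n = wid.max() + 1
    age_min = int(ages.min())
    n_steps = int(ages.max()) - age_min + 1
    ai = ages - age_min

    level_order = {c: i for i, c in enumerate(CATEGORY_LEVELS)}
    cat_codes = h["exposure_category"].map(level_order).to_numpy(dtype=np.int8)
    cause_order = {c: i for i, c in enumerate(CAUSE_LEVELS)}
    cause_codes = h["death_cause"].map(cause_order).to_numpy(dtype=np.int8)

    inc = np.zeros((n, n_steps))
    cat = np.zeros((n, n_steps), dtype=np.int8)
    emp = np.zeros((n, n_steps), dtype=np.int8)
    inc[wid, ai] = coeffs.increments()[cat_codes]
    cat[wid, ai] = cat_codes
    emp[wid, ai] = h["employed"].to_numpy(dtype=np.int8)

    g_first = np.zeros(len(h), dtype=bool)
    g_first[0] = True
    g_first[1:] = wid[1:] != wid[:-1]
    g_last = np.roll(g_first, -1)
    g_last[-1] = True
    entry = ages[g_first]
    exit_age = ages[g_last]
    cause = cause_codes[g_last]
    birth = h["calendar_year"].to_numpy(dtype=int)[g_first] - entry
    return SimulatedHistories(
        intervention=label,
        entry_age=entry,
        exit_age=exit_age,
        cause_code=cause,
        birth_year=birth,
        inc=inc,
        cat=cat,
        emp=emp,
        age_min=age_min,
    )


def simulate_pseudo_cohort(
    suite: ModelSuite,
    baseline: pd.DataFrame,
    intervention: InterventionSpec | str,
    mc_size: int,
    seed: int | np.random.SeedSequence,
    identity_baselines: bool = False,
    allow_unconverged: bool = False,
) -> SimulatedHistories:
    """Simulate ``mc_size`` pseudo-worker histories under an intervention."""
    if isinstance(intervention, str):
        intervention = INTERVENTIONS[intervention]
    if not suite.all_converged and not allow_unconverged:
        bad = [n for n, m in suite.models.items() if not m.converged]
        raise ValueError(f"refusing to simulate from unconverged models: {bad}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_base, ss_sim = ss.spawn(2)
    rng_base = np.random.default_rng(ss_base)
    sample = sample_baselines(baseline, mc_size, rng_base, identity=identity_baselines)
    state = _init_state(sample, suite.max_age)
    if (state.entry_age >= suite.max_age).any():
        raise ValueError("baseline entry age at or beyond the age cap")
    if ((state.birth_year + state.entry_age) > suite.admin_end_year).any():
        raise ValueError("baseline entry year beyond the administrative end of follow-up")

    rng_sim = np.random.default_rng(ss_sim)
    # pre-drawn uniforms indexed (worker, period, slot): execution-order invariant
    U = rng_sim.random((state.n, state.n_steps, 3))
    for a in range(state.age_min, suite.max_age):
        ai = a - state.age_min
        _advance(state, a, suite, intervention, U[:, ai, 0], U[:, ai, 1], U[:, ai, 2])
        if state.done.all():
            break
    return SimulatedHistories(
        intervention=intervention.kind,
        entry_age=state.entry_age,
        exit_age=state.exit_age,
        cause_code=state.cause,
        birth_year=state.birth_year,
        inc=state.inc,
        cat=state.cat,
        emp=state.emp,
        age_min=state.age_min,
    )
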