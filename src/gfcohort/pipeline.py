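"""End-to-end analysis: fit -> simulate -> estimate -> bootstrap -> calibrate.

The public surface follows the Model/Results convention: build a
:class:`GFormulaModel` from the baseline and annual-history tables, call
``fit()`` to obtain a :class:`GFormulaResults`, and from the results object
simulate interventions, estimate cumulative-incidence contrasts, compute
worker-level bootstrap percentile confidence intervals, and run the
natural-course calibration diagnostic.

Bootstrap resampling is at the worker level (person-periods within a worker
are dependent): each replicate draws workers with replacement, refits all six
models (as frequency-weighted fits over the cached design matrices), reruns
the requested interventions and recomputes every contrast.  The point
estimate comes from the original sample; intervals are percentile-based.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace as dc_replace
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .config import exposure_from_config, lag_from_config, load_config, model_specs_from_config
from .engine import (
    MODEL_NAMES,
    ModelSuite,
    SimulatedHistories,
    simulate_pseudo_cohort,
)
from .models import FittedModel, ModelFitError, ModelSpec, fit_pooled_logistic, fit_proportional_odds
from .personperiod import DesignInfo, expand_to_person_periods, worker_outcomes
from .risks import CAUSES, CIFCurveSet, contrast_table, cumulative_incidence, per_1000, risk_difference
from .splines import default_knots

__all__ = [
    "GFormulaModel",
    "GFormulaResults",
    "BootstrapResult",
    "CalibrationReport",
    "bootstrap_cis",
    "calibration_report",
    "run_analysis",
]

logger = logging.getLogger("gfcohort")

CATEGORY_CODE = {"light": 0, "medium": 1, "heavy": 2}


@dataclass
class _ModelData:
    """Cached fitting substrate for one model: rows, design, outcome, workers."""

    spec: ModelSpec
    X: np.ndarray
    y: np.ndarray
    names: list
    worker_idx: np.ndarray


class GFormulaModel:
    """Parametric g-formula model for an occupational cohort.

    Parameters
    ----------
    baseline, history : DataFrame
        One row per worker (entry age/year, birthplace, pre-entry work and
        exposure) and one row per worker-year (employment, exposure category,
        vital status).
    config : dict or path, optional
        Overrides merged over the packaged defaults (model specs, exposure
        constants, lag windows, pipeline settings).
    """

    def __init__(self, baseline: pd.DataFrame, history: pd.DataFrame, config=None):
        self.config = load_config(config)
        self.baseline = baseline.reset_index(drop=True)
        self.history = history
        self.coeffs = exposure_from_config(self.config)
        self.lag_spec = lag_from_config(self.config)
        self.model_specs = model_specs_from_config(self.config)
        self.max_age = int(self.config["generator"]["max_age"])
        self.admin_end_year = int(self.config["generator"]["admin_end_year"])
        self.pp = expand_to_person_periods(baseline, history, self.coeffs, self.lag_spec)

        knots = self.config["pipeline"].get("knots")
        if knots is None:
            dead = self.pp[["d_resp", "d_heart", "d_other"]].sum(axis=1) > 0
            knots = default_knots(self.pp.loc[dead, "age"].to_numpy())
        self.design = DesignInfo(knots=tuple(float(k) for k in knots))

        wid_codes, workers = pd.factorize(self.pp["worker_id"], sort=False)
        self._wid_codes = wid_codes
        self._workers = workers
        self.n_workers = len(workers)
        # one union design over all person-periods; per-model row/column slices
        union: list = []
        for name in MODEL_NAMES:
            for c in self.model_specs[name].covariates:
                if c not in union:
                    union.append(c)
        self._X_union, self._union_names = self.design.build(self.pp, union, intercept=True)
        self._data = {name: self._prepare(self.model_specs[name]) for name in MODEL_NAMES}

    # -- fitting -----------------------------------------------------------

    def _risk_set(self, spec: ModelSpec) -> np.ndarray:
        pp = self.pp
        if spec.risk_set == "at_risk":
            return np.ones(len(pp), dtype=bool)
        if spec.risk_set == "employed":
            return (pp["employed"].to_numpy() == 1) & pp["leave_work"].notna().to_numpy()
        if spec.risk_set == "unemployed":
            return (pp["employed"].to_numpy() == 0) & pp["return_work"].notna().to_numpy()
        if spec.risk_set == "employed_now":
            return pp["employed"].to_numpy() == 1
        raise ValueError(f"unknown risk set {spec.risk_set!r}")

    def _prepare(self, spec: ModelSpec) -> _ModelData:
        mask = self._risk_set(spec)
        if not mask.any():
            raise ValueError(f"empty risk set for model {spec.outcome!r}")
        idx = np.flatnonzero(mask)
        names = self.design.column_names(
            spec.covariates, intercept=(spec.family == "binary_logit")
        )
        cols = np.array([self._union_names.index(c) for c in names])
        X = self._X_union[np.ix_(idx, cols)]
        if spec.family == "binary_logit":
            y = self.pp[spec.outcome].to_numpy(dtype=float)[idx]
        else:
            y = self.pp["exposure_category"].map(CATEGORY_CODE).to_numpy(dtype=float)[idx]
        return _ModelData(spec=spec, X=X, y=y, names=names, worker_idx=self._wid_codes[idx])

    def _fit_suite(self, worker_weights: Optional[np.ndarray] = None) -> ModelSuite:
        models = {}
        warm = getattr(self, "_warm", {})
        for name in MODEL_NAMES:
            d = self._data[name]
            w = None if worker_weights is None else worker_weights[d.worker_idx]
            start = warm.get(name) if worker_weights is not None else None
            if d.spec.family == "binary_logit":
                models[name] = fit_pooled_logistic(
                    d.X, d.y, d.names, weights=w, outcome=name, spec=d.spec, start=start
                )
            else:
                models[name] = fit_proportional_odds(
                    d.X, d.y.astype(int), d.names, weights=w, outcome=name, spec=d.spec,
                    start=start,
                )
        return ModelSuite(
            models=models,
            design=self.design,
            coeffs=self.coeffs,
            lag_spec=self.lag_spec,
            max_age=self.max_age,
            admin_end_year=self.admin_end_year,
        )

    def fit(self) -> "GFormulaResults":
        """Fit the six discrete-time models by maximum likelihood."""
        suite = self._fit_suite()
        # warm starts for bootstrap refits
        self._warm = {name: suite[name].params for name in MODEL_NAMES}
        return GFormulaResults(model=self, suite=suite)


@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals for every estimand."""

    table: pd.DataFrame  # columns: estimand, point, ci_lower, ci_upper
    B: int
    n_failed: int
    draws: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        bad = (self.table["ci_lower"] > self.table["point"] + 1e-12) | (
            self.table["ci_upper"] < self.table["point"] - 1e-12
        )
        if bad.any():
            logger.warning(
                "percentile CI does not contain the point estimate for %d estimand(s) "
                "(possible with percentile intervals; reported as computed)",
                int(bad.sum()),
            )


@dataclass
class CalibrationReport:
    """Observed-vs-simulated natural-course diagnostics."""

    cif_observed: CIFCurveSet
    cif_simulated: CIFCurveSet
    exposure_summary: pd.DataFrame      # median / IQR of cumulative exposure over person-time
    employment_by_age: pd.DataFrame     # observed vs simulated employment prevalence
    max_cif_discrepancy_by70: float
    max_cif_discrepancy: float

    def to_frame(self) -> pd.DataFrame:
        obs = self.cif_observed.to_frame().set_index("age")
        sim = self.cif_simulated.to_frame().set_index("age")
        out = obs.join(sim, lsuffix="_observed", rsuffix="_simulated")
        return out.reset_index()

    def to_text(self) -> str:
        lines = [
            "Natural-course calibration",
            f"  max |observed - simulated| CIF through age 70: {self.max_cif_discrepancy_by70:.4f}",
            f"  max |observed - simulated| CIF over full grid:  {self.max_cif_discrepancy:.4f}",
            "",
            "Cumulative exposure across person-time (mg/m^3-years):",
            self.exposure_summary.to_string(index=False),
        ]
        return "\n".join(lines) + "\n"

    def plot(self, path=None):
        """Observed (dashed) vs natural-course (solid) CIF curves per cause."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 5))
        colors = {"resp_cancer": "C0", "heart": "C1", "other": "C2"}
        for cause, color in colors.items():
            if cause not in self.cif_observed.cif.columns:
                continue
            ax.plot(self.cif_observed.ages + 1, self.cif_observed.cif[cause],
                    "--", color=color, label=f"{cause} (observed)")
            ax.plot(self.cif_simulated.ages + 1, self.cif_simulated.cif[cause],
                    "-", color=color, label=f"{cause} (natural course)")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("cumulative incidence")
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig


def _grouped_cumsum(x: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting at each group boundary (groups contiguous)."""
    cum = np.cumsum(x)
    first = np.zeros(len(x), dtype=bool)
    if len(x):
        first[0] = True
        first[1:] = groups[1:] != groups[:-1]
    start_offset = np.where(first, cum - x, 0.0)
    return cum - np.maximum.accumulate(start_offset)


def _person_time_cumexp_simulated(h: SimulatedHistories) -> np.ndarray:
    cum = np.cumsum(h.inc, axis=1)
    ai_entry = h.entry_age - h.age_min
    ai_exit = h.exit_age - h.age_min
    m = cum.shape[1]
    mask = (np.arange(m)[None, :] >= ai_entry[:, None]) & (np.arange(m)[None, :] <= ai_exit[:, None])
    return cum[mask]


def _employment_by_age(entry, exit_age, emp, age_min, label) -> pd.DataFrame:
    m = emp.shape[1]
    ages = np.arange(age_min, age_min + m)
    at_risk = (ages[None, :] >= entry[:, None]) & (ages[None, :] <= exit_age[:, None])
    n = at_risk.sum(axis=0)
    worked = (emp * at_risk).sum(axis=0)
    with np.errstate(invalid="ignore"):
        prev = np.where(n > 0, worked / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"age": ages, f"employment_{label}": prev, f"n_{label}": n})


class GFormulaResults:
    """Fitted model suite plus the simulation / estimation machinery."""

    def __init__(self, model: GFormulaModel, suite: ModelSuite):
        self.model = model
        self.suite = suite
        cfg = model.config["pipeline"]
        self.eval_ages = list(cfg["eval_ages"])
        self.reference = cfg["reference"]
        self.interventions = list(cfg["interventions"])
        self.mc_size = int(cfg["mc_size"])
        self.age_start = int(cfg["age_start"])
        self.seed = int(cfg["seed"])

    # -- presentation ------------------------------------------------------

    @property
    def params(self) -> pd.DataFrame:
        rows = []
        for name in MODEL_NAMES:
            m = self.suite[name]
            bse = m.bse
            for i, term in enumerate(m.param_names):
                rows.append(
                    {
                        "model": name,
                        "term": term,
                        "estimate": m.params[i],
                        "std_error": np.nan if bse is None else bse[i],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Parametric g-formula model suite", "=" * 64]
        for name in MODEL_NAMES:
            m = self.suite[name]
            lines.append(
                f"\n{name} ({m.kind}; n={m.nobs:.0f}, loglik={m.llf:.2f}, "
                f"AIC={m.aic:.2f}, converged={m.converged})"
            )
            lines.append(f"{'term':<22}{'estimate':>12}{'std err':>12}")
            bse = m.bse
            for i, term in enumerate(m.param_names):
                se = float(bse[i]) if bse is not None else float("nan")
                lines.append(f"{term:<22}{m.params[i]:>12.4f}{se:>12.4f}")
        return "\n".join(lines)

    # -- simulation & estimation -------------------------------------------

    def simulate(
        self,
        intervention: str,
        mc_size: Optional[int] = None,
        seed: Optional[object] = None,
    ) -> SimulatedHistories:
        return simulate_pseudo_cohort(
            self.suite,
            self.model.baseline,
            intervention,
            mc_size=mc_size or self.mc_size,
            seed=self.seed if seed is None else seed,
        )

    def cumulative_incidence(self, histories: SimulatedHistories, label="") -> CIFCurveSet:
        return cumulative_incidence(
            histories, causes=CAUSES, age_start=self.age_start, age_max=self.model.max_age,
            label=label,
        )

    def estimate(
        self,
        interventions: Optional[Sequence[str]] = None,
        mc_size: Optional[int] = None,
        seed: Optional[object] = None,
    ) -> tuple:
        """Simulate the interventions and build the risk-contrast table.

        Returns (curves, contrasts): intervention -> CIFCurveSet, and the
        deaths/excess-deaths-per-1,000 table (empty contrast columns when the
        reference intervention is not among those requested).
        """
        interventions = list(interventions if interventions is not None else self.interventions)
        curves = {}
        for name in interventions:
            h = self.simulate(name, mc_size=mc_size, seed=seed)
            curves[name] = self.cumulative_incidence(h, label=name)
        if self.reference in curves and len(curves) > 1:
            contrasts = contrast_table(curves, self.eval_ages, reference=self.reference)
        else:
            contrasts = pd.DataFrame()
        return curves, contrasts

    # -- bootstrap -----------------------------------------------------------

    def _estimand_vector(self, curves: dict) -> pd.Series:
        vals = {}
        ref = curves[self.reference]
        for age in self.eval_ages:
            for cause in list(CAUSES) + ["all_cause"]:
                c = None if cause == "all_cause" else cause
                vals[f"deaths_per_1000_{self.reference}_age{age}_{cause}"] = per_1000(
                    ref.value_at(age, c)
                )
                for name in curves:
                    if name == self.reference:
                        continue
                    if cause == "all_cause":
                        rd = sum(risk_difference(curves[name], ref, age, cz) for cz in CAUSES)
                    else:
                        rd = risk_difference(curves[name], ref, age, c)
                    vals[f"excess_per_1000_{name}_age{age}_{cause}"] = per_1000(rd)
        return pd.Series(vals)

    def bootstrap(
        self,
        B: Optional[int] = None,
        seed: Optional[int] = None,
        mc_size: Optional[int] = None,
        interventions: Optional[Sequence[str]] = None,
        keep_draws: bool = False,
        max_failure_fraction: float = 0.05,
    ) -> BootstrapResult:
        """Worker-level nonparametric bootstrap with percentile 95% CIs."""
        cfg = self.model.config["pipeline"]
        B = int(B if B is not None else cfg["bootstrap_replicates"])
        if B < 2:
            raise ValueError("bootstrap needs at least 2 replicates")
        if B < 50:
            logger.warning("bootstrap with B=%d replicates: percentile CIs will be crude", B)
        interventions = list(interventions if interventions is not None else self.interventions)
        if self.reference not in interventions:
            interventions = [self.reference] + interventions
        mc = mc_size or self.mc_size
        master = np.random.SeedSequence(self.seed if seed is None else seed)
        ss_point, *ss_reps = master.spawn(B + 1)

        curves, _ = self.estimate(interventions, mc_size=mc, seed=ss_point)
        point = self._estimand_vector(curves)

        n = self.model.n_workers
        draws = []
        n_failed = 0
        for b, ss in enumerate(ss_reps):
            rng = np.random.default_rng(ss)
            counts = np.bincount(rng.integers(0, n, size=n), minlength=n).astype(float)
            try:
                suite_b = self.model._fit_suite(worker_weights=counts)
            except ModelFitError as err:
                n_failed += 1
                logger.warning("bootstrap replicate %d failed to fit: %s", b, err)
                if n_failed > max_failure_fraction * B:
                    raise RuntimeError(
                        f"more than {max_failure_fraction:.0%} of bootstrap replicates "
                        f"failed to fit ({n_failed}/{b + 1} so far)"
                    )
                continue
            boot_baseline = self.model.baseline.iloc[
                np.repeat(np.arange(n), counts.astype(int))
            ].reset_index(drop=True)
            curves_b = {}
            ss_sims = ss.spawn(len(interventions))
            for name, ssi in zip(interventions, ss_sims):
                h = simulate_pseudo_cohort(suite_b, boot_baseline, name, mc_size=mc, seed=ssi)
                curves_b[name] = self.cumulative_incidence(h, label=name)
            draws.append(self._estimand_vector(curves_b))
        if len(draws) < 2:
            raise RuntimeError("too few successful bootstrap replicates")
        draws_df = pd.DataFrame(draws)
        lo = draws_df.quantile(0.025)
        hi = draws_df.quantile(0.975)
        table = pd.DataFrame(
            {
                "estimand": point.index,
                "point": point.to_numpy(),
                "ci_lower": lo.reindex(point.index).to_numpy(),
                "ci_upper": hi.reindex(point.index).to_numpy(),
            }
        )
        return BootstrapResult(
            table=table, B=B, n_failed=n_failed, draws=draws_df if keep_draws else None
        )

    # -- diagnostics ---------------------------------------------------------

    def calibration_report(
        self, mc_size: Optional[int] = None, seed: Optional[int] = None
    ) -> CalibrationReport:
        """Observed data vs the simulated natural course (model-fit check)."""
        h = self.simulate("natural_course", mc_size=mc_size, seed=seed)
        return calibration_report(
            self.model.history,
            h,
            pp=self.model.pp,
            age_start=self.age_start,
            age_max=self.model.max_age,
        )

    def hwsb_diagnostic(
        self, age: int = 70, mc_size: Optional[int] = None, seed: Optional[int] = None
    ) -> dict:
        """Compare the g-formula excess with a covariate-only ("conventional")

        contrast that removes exposure from the death models but leaves the
        employment dynamics on their natural-course paths — the part of the
        effect a regression adjusted for employment status can represent.
        When exposure drives workers out of employment and employment itself
        carries mortality information, the conventional contrast understates
        the full intervention effect (healthy-worker-survivor bias pathway).
        """
        seed = self.seed if seed is None else seed
        mc = mc_size or self.mc_size
        h_nat = self.simulate("natural_course", mc_size=mc, seed=seed)
        h_never = self.simulate("never_exposed", mc_size=mc, seed=seed)
        cif_nat = self.cumulative_incidence(h_nat)
        cif_never = self.cumulative_incidence(h_never)

        zeroed = {}
        for name in MODEL_NAMES:
            m = self.suite[name]
            if name.startswith("d_"):
                params = m.params.copy()
                for i, t in enumerate(m.param_names):
                    if t.startswith("w_") or t == "pre_entry_exposure":
                        params[i] = 0.0
                zeroed[name] = dc_replace(m, params=params)
            else:
                zeroed[name] = m
        suite0 = ModelSuite(
            models=zeroed,
            design=self.suite.design,
            coeffs=self.suite.coeffs,
            lag_spec=self.suite.lag_spec,
            max_age=self.suite.max_age,
            admin_end_year=self.suite.admin_end_year,
        )
        h_direct = simulate_pseudo_cohort(
            suite0, self.model.baseline, "natural_course", mc_size=mc, seed=seed
        )
        cif_direct = self.cumulative_incidence(h_direct)
        all_cause = lambda c: sum(c.value_at(age, cz) for cz in CAUSES)
        return {
            "age": age,
            "gformula_excess_per_1000": per_1000(all_cause(cif_nat) - all_cause(cif_never)),
            "conventional_excess_per_1000": per_1000(all_cause(cif_nat) - all_cause(cif_direct)),
        }


def calibration_report(
    history: pd.DataFrame,
    nc_histories: SimulatedHistories,
    pp: Optional[pd.DataFrame] = None,
    age_start: int = 20,
    age_max: int = 90,
) -> CalibrationReport:
    """Side-by-side observed vs natural-course summaries (see Results method)."""
    obs_out = worker_outcomes(history)
    cif_obs = cumulative_incidence(obs_out, CAUSES, age_start, age_max, label="observed")
    cif_sim = cumulative_incidence(nc_histories, CAUSES, age_start, age_max, label="natural_course")

    diff = np.abs(cif_obs.cif.to_numpy() - cif_sim.cif.to_numpy())
    by70 = cif_obs.ages < 70
    max70 = float(diff[by70].max())
    maxall = float(diff.max())

    if pp is not None:
        wid, _ = pd.factorize(pp["worker_id"], sort=False)
        obs_cum = _grouped_cumsum(pp["increment"].to_numpy(), wid)
    else:
        from .exposure import CATEGORY_LEVELS, ExposureCoefficients

        hs = history.sort_values(["worker_id", "age"], kind="mergesort")
        wid, _ = pd.factorize(hs["worker_id"], sort=False)
        level = {c: i for i, c in enumerate(CATEGORY_LEVELS)}
        inc = ExposureCoefficients().increments()[hs["exposure_category"].map(level)]
        obs_cum = _grouped_cumsum(inc, wid)
    sim_cum = _person_time_cumexp_simulated(nc_histories)
    expo = pd.DataFrame(
        {
            "source": ["observed", "natural_course"],
            "q25": [np.quantile(obs_cum, 0.25), np.quantile(sim_cum, 0.25)],
            "median": [np.quantile(obs_cum, 0.5), np.quantile(sim_cum, 0.5)],
            "q75": [np.quantile(obs_cum, 0.75), np.quantile(sim_cum, 0.75)],
        }
    )

    h = history.sort_values(["worker_id", "age"], kind="mergesort")
    g = h.groupby("worker_id", sort=False)
    entry_o = g["age"].first().to_numpy()
    exit_o = g["age"].last().to_numpy()
    age_min_o = int(entry_o.min())
    emp_piv = np.zeros((len(entry_o), age_max - age_min_o), dtype=np.int8)
    wcodes, _ = pd.factorize(h["worker_id"], sort=False)
    ai = h["age"].to_numpy() - age_min_o
    emp_piv[wcodes, ai] = h["employed"].to_numpy(dtype=np.int8)
    emp_obs = _employment_by_age(entry_o, exit_o, emp_piv, age_min_o, "observed")
    emp_sim = _employment_by_age(
        nc_histories.entry_age, nc_histories.exit_age, nc_histories.emp,
        nc_histories.age_min, "natural_course",
    )
    employment = emp_obs.merge(emp_sim, on="age", how="outer").sort_values("age")

    return CalibrationReport(
        cif_observed=cif_obs,
        cif_simulated=cif_sim,
        exposure_summary=expo,
        employment_by_age=employment.reset_index(drop=True),
        max_cif_discrepancy_by70=max70,
        max_cif_discrepancy=maxall,
    )


def bootstrap_cis(
    baseline: pd.DataFrame, history: pd.DataFrame, config=None, **kwargs
) -> BootstrapResult:
    """Fit the suite and compute worker-level bootstrap percentile CIs."""
    res = GFormulaModel(baseline, history, config).fit()
    return res.bootstrap(**kwargs)


def run_analysis(config=None, outdir=None) -> dict:
    """Execute the full pipeline and write the results bundle.

    Stages: load-or-generate tables -> expand -> fit -> simulate all
    interventions -> estimate -> bootstrap -> calibration.  Any stage failure
    aborts with a stage-named message.  Outputs (tab-separated text) land in
    ``outdir``: results table, fitted-model files, CIF curves, calibration
    report, run log.
    """
    cfg = load_config(config)
    io_cfg = cfg.get("io", {}) or {}
    outdir = Path(outdir or io_cfg.get("outdir", "gfcohort_results"))
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []
    t0 = time.time()

    def stage(name):
        log_lines.append(f"stage {name}: t+{time.time() - t0:.1f}s")

    def fail(name, err):
        raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    try:
        if io_cfg.get("baseline") and io_cfg.get("history"):
            baseline = pd.read_csv(io_cfg["baseline"], sep="\t")
            history = pd.read_csv(io_cfg["history"], sep="\t")
        else:
            from .synthetic import GeneratorParams, generate_cohort

            params = GeneratorParams.from_config(cfg)
            baseline, history, _ = generate_cohort(params, seed=cfg["pipeline"]["seed"])
    except Exception as err:  # noqa: BLE001
        fail("load", err)
    stage("load")

    try:
        res = GFormulaModel(baseline, history, cfg).fit()
    except Exception as err:  # noqa: BLE001
        fail("fit", err)
    stage("fit")

    try:
        curves, contrasts = res.estimate()
    except Exception as err:  # noqa: BLE001
        fail("simulate", err)
    stage("simulate")

    bootstrap_res = None
    B = cfg["pipeline"].get("bootstrap_replicates")
    if B and B >= 2 and len(res.interventions) > 1:
        try:
            bootstrap_res = res.bootstrap(B=B)
        except Exception as err:  # noqa: BLE001
            fail("bootstrap", err)
    stage("bootstrap")

    try:
        calib = res.calibration_report()
    except Exception as err:  # noqa: BLE001
        fail("calibration", err)
    stage("calibration")

    # ---- write artifacts
    (outdir / "models").mkdir(exist_ok=True)
    for name in MODEL_NAMES:
        (outdir / "models" / f"{name}.txt").write_text(res.suite[name].to_text())
    contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False)
    curve_frames = []
    for name, c in curves.items():
        f = c.to_frame()
        f.insert(0, "intervention", name)
        curve_frames.append(f)
    pd.concat(curve_frames).to_csv(outdir / "cif_curves.tsv", sep="\t", index=False)
    if bootstrap_res is not None:
        bootstrap_res.table.to_csv(outdir / "bootstrap_cis.tsv", sep="\t", index=False)
    calib.to_frame().to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    (outdir / "calibration.txt").write_text(calib.to_text())
    (outdir / "summary.txt").write_text(res.summary() + "\n")
    import sys

    log_lines.insert(0, f"seed: {cfg['pipeline']['seed']}")
    log_lines.insert(1, f"python: {sys.version.split()[0]}; numpy: {np.__version__}; pandas: {pd.__version__}")
    log_lines.append(
        "convergence: "
        + ", ".join(f"{n}={res.suite[n].converged}" for n in MODEL_NAMES)
    )
    if bootstrap_res is not None:
        log_lines.append(f"bootstrap: B={bootstrap_res.B}, failed={bootstrap_res.n_failed}")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "results": res,
        "curves": curves,
        "contrasts": contrasts,
        "bootstrap": bootstrap_res,
        "calibration": calib,
        "outdir": outdir,
    }
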