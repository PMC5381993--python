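"""Synthetic occupational-cohort generator with known generating models.

The generator emulates a mid-century smelter workforce: ~8,000 male workers
entering follow-up after a completed year of employment, followed on the age
scale until death from one of three competing causes (respiratory cancer,
heart disease, other), age 90, or an administrative end of follow-up.  While
employed, each worker-year carries a light/medium/heavy exposure-intensity
category drawn from a proportional-odds model; the hazard of leaving work
rises steeply with exposure accrued over the preceding five years, which is
the confounding loop that produces healthy-worker-survivor structure
(exposure -> leaving work -> no further exposure, with employment status also
entering the death models).

Annual histories are produced by running the simulation engine forward from
truth-coefficient model objects under the natural course, so every generating
coefficient corresponds one-to-one to a coefficient the fitting step
estimates; the exact values are returned as a :class:`TruthRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import default_config, exposure_from_config, lag_from_config, model_specs_from_config
from .engine import MODEL_NAMES, ModelSuite, simulate_pseudo_cohort
from .exposure import ExposureCoefficients, LagSpec
from .models import FittedModel, ModelSpec
from .personperiod import DesignInfo

__all__ = ["GeneratorParams", "TruthRecord", "generate_cohort", "build_truth_suite", "write_tables"]

BASELINE_COLUMNS = [
    "worker_id",
    "entry_age",
    "entry_year",
    "birth_year",
    "us_born",
    "pre_entry_years_worked",
    "pre_entry_exposure_mgm3yr",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Generating parameters; defaults come from the packaged config file."""

    n_workers: int
    entry_age_median: float
    entry_age_sigma: float
    entry_age_min: int
    entry_age_max: int
    entry_year_start: int
    entry_year_end: int
    admin_end_year: int
    max_age: int
    p_us_born: float
    p_exposed_at_entry: float
    p_long_tenure: float
    long_tenure_geometric_p: float
    pre_entry_category_probs: tuple
    knots: tuple
    coefficients: dict  # model name -> {design column name: value}
    model_specs: dict = field(default_factory=dict)  # model name -> ModelSpec
    exposure: ExposureCoefficients = field(default_factory=ExposureCoefficients)
    lag: LagSpec = field(default_factory=LagSpec)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_workers <= 0:
            raise ValueError("n_workers must be positive")
        if self.entry_age_sigma <= 0:
            raise ValueError("degenerate entry-age distribution: spread must be positive")
        if self.entry_year_end >= self.admin_end_year:
            raise ValueError("entry window must precede the administrative end year")
        if not (0 < self.max_age):
            raise ValueError("max_age must be positive")
        probs = np.asarray(self.pre_entry_category_probs, dtype=float)
        if probs.shape != (3,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("pre_entry_category_probs must be 3 non-negative values summing to 1")

    @classmethod
    def from_config(cls, cfg: Optional[dict] = None, **overrides) -> "GeneratorParams":
        cfg = cfg if cfg is not None else default_config()
        g = cfg["generator"]
        params = cls(
            n_workers=g["n_workers"],
            entry_age_median=g["entry_age_median"],
            entry_age_sigma=g["entry_age_sigma"],
            entry_age_min=g["entry_age_min"],
            entry_age_max=g["entry_age_max"],
            entry_year_start=g["entry_year_start"],
            entry_year_end=g["entry_year_end"],
            admin_end_year=g["admin_end_year"],
            max_age=g["max_age"],
            p_us_born=g["p_us_born"],
            p_exposed_at_entry=g["p_exposed_at_entry"],
            p_long_tenure=g["p_long_tenure"],
            long_tenure_geometric_p=g["long_tenure_geometric_p"],
            pre_entry_category_probs=tuple(g["pre_entry_category_probs"]),
            knots=tuple(g["knots"]),
            coefficients={k: dict(v) for k, v in g["coefficients"].items()},
            model_specs=model_specs_from_config(cfg),
            exposure=exposure_from_config(cfg),
            lag=lag_from_config(cfg),
        )
        return replace(params, **overrides) if overrides else params

    # -- convenience accessors mirroring the scientifically meaningful knobs --

    @property
    def leave_work_exposure_coefficient(self) -> float:
        return self.coefficients["leave_work"]["w_recent"]

    def with_null_exposure_effects(self, null_leave_work: bool = False) -> "GeneratorParams":
        """Copy with every exposure->death coefficient set to zero.

        The exposure->leaving-work coefficient is kept (healthy-worker-survivor
        structure present) unless ``null_leave_work`` is also requested.
        """
        coefs = {k: dict(v) for k, v in self.coefficients.items()}
        for model in ("d_resp", "d_heart", "d_other"):
            for key in list(coefs[model]):
                if key.startswith("w_") or key == "pre_entry_exposure":
                    coefs[model][key] = 0.0
        if null_leave_work:
            coefs["leave_work"]["w_recent"] = 0.0
        return replace(self, coefficients=coefs)


@dataclass(frozen=True)
class TruthRecord:
    """Exact generating coefficients, keyed like the fitted models' terms."""

    coefficients: Dict[str, Dict[str, float]]

    def __getitem__(self, model: str) -> Dict[str, float]:
        return self.coefficients[model]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "term": t, "value": v}
            for m, terms in self.coefficients.items()
            for t, v in terms.items()
        ]
        return pd.DataFrame(rows)


def build_truth_suite(params: GeneratorParams) -> ModelSuite:
    """Model objects carrying the generating coefficients (for the engine)."""
    design = DesignInfo(knots=params.knots)
    models = {}
    for name in MODEL_NAMES:
        spec = params.model_specs[name]
        coefs = params.coefficients[name]
        if spec.family == "binary_logit":
            expected = design.column_names(spec.covariates, intercept=True)
            n_thresh = 0
        else:
            expected = ["thresh_1", "thresh_2"] + design.column_names(
                spec.covariates, intercept=False
            )
            n_thresh = 2
        missing = set(expected) - set(coefs)
        extra = set(coefs) - set(expected)
        if missing or extra:
            raise ValueError(
                f"generating coefficients for {name!r} do not match the model "
                f"specification (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        models[name] = FittedModel.from_params(
            kind=spec.family,
            outcome=name,
            param_names=expected,
            params=[coefs[c] for c in expected],
            spec=spec,
            n_thresholds=n_thresh,
        )
    return ModelSuite(
        models=models,
        design=design,
        coeffs=params.exposure,
        lag_spec=params.lag,
        max_age=params.max_age,
        admin_end_year=params.admin_end_year,
    )


def _draw_baselines(params: GeneratorParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_workers
    mu = np.log(params.entry_age_median)
    entry_age = np.clip(
        np.round(rng.lognormal(mu, params.entry_age_sigma, size=n)),
        params.entry_age_min,
        params.entry_age_max,
    ).astype(int)
    entry_year = rng.integers(params.entry_year_start, params.entry_year_end + 1, size=n)
    us_born = rng.random(n) < params.p_us_born

    long_tenure = rng.random(n) < params.p_long_tenure
    extra = np.where(long_tenure, rng.geometric(params.long_tenure_geometric_p, size=n), 0)
    # nobody works before age 16
    extra = np.minimum(extra, np.maximum(entry_age - 17, 0))
    pre_years = 1 + extra

    # category mix of pre-entry years: chained binomials (vector-friendly multinomial)
    p_l, p_m, p_h = params.pre_entry_category_probs
    n_heavy = rng.binomial(pre_years, p_h)
    n_medium = rng.binomial(pre_years - n_heavy, p_m / (1.0 - p_h))
    n_light = pre_years - n_heavy - n_medium
    inc = params.exposure.increments()
    pre_exp = n_light * inc[1] + n_medium * inc[2] + n_heavy * inc[3]
    pre_exp = np.where(rng.random(n) < params.p_exposed_at_entry, pre_exp, 0.0)

    return pd.DataFrame(
        {
            "worker_id": np.arange(n),
            "entry_age": entry_age,
            "entry_year": entry_year,
            "birth_year": entry_year - entry_age,
            "us_born": us_born.astype(int),
            "pre_entry_years_worked": pre_years.astype(float),
            "pre_entry_exposure_mgm3yr": pre_exp,
        }
    )


def generate_cohort(
    params: GeneratorParams, seed: Optional[int] = None
) -> tuple:
    """Generate (baseline table, annual history table, TruthRecord).

    Identical seeds produce bit-identical tables.  Every worker enters with at
    least one completed year of pre-entry employment; annual records run from
    entry age to the earliest of death, the age cap, or the administrative end
    of follow-up; exposure categories appear only in employed years; at most
    one death per worker.
    """
    seed = seed if seed is not None else params.seed
    if seed is None:
        raise ValueError("a seed is required (GeneratorParams.seed or the seed argument)")
    ss = np.random.SeedSequence(int(seed))
    ss_base, ss_hist = ss.spawn(2)
    baseline = _draw_baselines(params, np.random.default_rng(ss_base))
    suite = build_truth_suite(params)
    histories = simulate_pseudo_cohort(
        suite,
        baseline,
        "natural_course",
        mc_size=params.n_workers,
        seed=ss_hist,
        identity_baselines=True,
    )
    history = histories.to_history_frame()
    truth = TruthRecord(
        coefficients={name: suite[name].params_dict() for name in MODEL_NAMES}
    )
    return baseline, history, truth


def write_tables(
    baseline: pd.DataFrame,
    history: pd.DataFrame,
    truth: Optional[TruthRecord],
    outdir,
) -> None:
    """Write the generator outputs as tab-separated text files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    baseline.to_csv(outdir / "baseline.tsv", sep="\t", index=False)
    history.to_csv(outdir / "history.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
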