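"""Two-period toy problem with an exact nonparametric g-formula oracle.

The toy has two time points, a binary exposure ``A_t``, one binary
time-varying confounder ``L_t`` (employment), and a single death outcome
``Y_t``, with the joint distribution specified through explicit conditional
probability tables in temporal order:

    L1  ->  A1 | L1  ->  Y1 | L1, A1  ->  L2 | L1, A1  ->  A2 | L1, A1, L2
        ->  Y2 | L1, A1, L2, A2        (all among survivors of period 1)

Because the state space is tiny (16 survivor histories), the standardized
risk under any intervention can be computed exactly by enumeration — the
plug-in nonparametric g-formula.  The same toy supports the parametric path:
draw a finite sample, fit saturated pooled logistic models, and run the
Monte Carlo g-formula; with saturated models the Monte Carlo risk converges
to the oracle value, which is the core correctness property of the
parametric algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .models import FittedModel, fit_pooled_logistic, predict_hazard

__all__ = [
    "ToyCohort",
    "generate_toy_two_period",
    "nonparametric_gformula_oracle",
    "sample_toy",
    "fit_toy_models",
    "simulate_toy",
    "CONFOUNDED_TOY",
]


def _table(arr, shape, name):
    a = np.asarray(arr, dtype=float)
    if a.shape != shape:
        raise ValueError(f"{name} must have shape {shape}, got {a.shape}")
    if ((a < 0) | (a > 1)).any():
        raise ValueError(f"{name} entries must be probabilities")
    return a


@dataclass(frozen=True)
class ToyCohort:
    """Explicit joint distribution of the two-period toy (via conditionals).

    Index convention: ``pY1[l1, a1]``, ``pL2[l1, a1]`` (P(L2=1 | survived)),
    ``pA2[l1, a1, l2]``, ``pY2[l1, a1, l2, a2]``.
    """

    pL1: float
    pA1: np.ndarray      # (2,)   P(A1=1 | L1)
    pY1: np.ndarray      # (2,2)
    pL2: np.ndarray      # (2,2)
    pA2: np.ndarray      # (2,2,2)
    pY2: np.ndarray      # (2,2,2,2)

    def joint_histories(self) -> pd.DataFrame:
        """Exact probability of every (L1, A1, Y1, L2, A2, Y2) history."""
        rows = []
        for l1, a1 in product((0, 1), repeat=2):
            base = (self.pL1 if l1 else 1 - self.pL1) * (
                self.pA1[l1] if a1 else 1 - self.pA1[l1]
            )
            py1 = self.pY1[l1, a1]
            rows.append({"L1": l1, "A1": a1, "Y1": 1, "L2": -1, "A2": -1, "Y2": -1,
                         "prob": base * py1})
            for l2, a2, y2 in product((0, 1), repeat=3):
                p = (
                    base
                    * (1 - py1)
                    * (self.pL2[l1, a1] if l2 else 1 - self.pL2[l1, a1])
                    * (self.pA2[l1, a1, l2] if a2 else 1 - self.pA2[l1, a1, l2])
                    * (self.pY2[l1, a1, l2, a2] if y2 else 1 - self.pY2[l1, a1, l2, a2])
                )
                rows.append({"L1": l1, "A1": a1, "Y1": 0, "L2": l2, "A2": a2, "Y2": y2,
                             "prob": p})
        df = pd.DataFrame(rows)
        if abs(df["prob"].sum() - 1.0) > 1e-12:
            raise AssertionError("toy joint distribution does not sum to 1")
        return df


def generate_toy_two_period(
    pL1: float, pA1, pY1, pL2, pA2, pY2
) -> ToyCohort:
    """Validate the conditional tables and build a ToyCohort."""
    if not 0 <= pL1 <= 1:
        raise ValueError("pL1 must be a probability")
    toy = ToyCohort(
        pL1=float(pL1),
        pA1=_table(pA1, (2,), "pA1"),
        pY1=_table(pY1, (2, 2), "pY1"),
        pL2=_table(pL2, (2, 2), "pL2"),
        pA2=_table(pA2, (2, 2, 2), "pA2"),
        pY2=_table(pY2, (2, 2, 2, 2), "pY2"),
    )
    joint = toy.joint_histories()
    if abs(joint["prob"].sum() - 1.0) > 1e-9:
        raise ValueError("probabilities do not sum to 1")
    return toy


#: a default confounded toy: prior exposure raises the chance of leaving
#: (L2=0), employment affects both later exposure and death — the same
#: structure, in miniature, as the occupational cohort.
CONFOUNDED_TOY = generate_toy_two_period(
    pL1=0.7,
    pA1=[0.2, 0.6],
    pY1=[[0.10, 0.25], [0.05, 0.15]],
    pL2=[[0.75, 0.45], [0.85, 0.55]],
    pA2=[[[0.10, 0.55], [0.15, 0.70]], [[0.12, 0.60], [0.20, 0.80]]],
    pY2=[
        [[[0.12, 0.28], [0.10, 0.22]], [[0.08, 0.20], [0.06, 0.16]]],
        [[[0.10, 0.24], [0.08, 0.18]], [[0.06, 0.16], [0.05, 0.12]]],
    ],
)


def _intervened(a_fixed: Optional[int], model_prob: float, a: int) -> float:
    """P(A=a) under the intervention (degenerate) or the natural course."""
    if a_fixed is None:
        return model_prob if a else 1 - model_prob
    return 1.0 if a == a_fixed else 0.0


def nonparametric_gformula_oracle(toy: ToyCohort, intervention: str) -> float:
    """Exact standardized two-period death risk by exhaustive enumeration.

    ``intervention`` is ``"never_exposed"`` (A=0 both periods),
    ``"always_exposed"`` (A=1 both), or ``"natural_course"``.
    """
    if intervention == "never_exposed":
        a_fix = 0
    elif intervention == "always_exposed":
        a_fix = 1
    elif intervention == "natural_course":
        a_fix = None
    else:
        raise ValueError(
            f"intervention {intervention!r} not defined for the toy "
            "(expected never_exposed / always_exposed / natural_course)"
        )
    risk = 0.0
    for l1 in (0, 1):
        pl1 = toy.pL1 if l1 else 1 - toy.pL1
        for a1 in (0, 1):
            pa1 = _intervened(a_fix, toy.pA1[l1], a1)
            if pa1 == 0.0:
                continue
            py1 = toy.pY1[l1, a1]
            risk += pl1 * pa1 * py1
            for l2 in (0, 1):
                pl2 = toy.pL2[l1, a1] if l2 else 1 - toy.pL2[l1, a1]
                for a2 in (0, 1):
                    pa2 = _intervened(a_fix, toy.pA2[l1, a1, l2], a2)
                    if pa2 == 0.0:
                        continue
                    risk += pl1 * pa1 * (1 - py1) * pl2 * pa2 * toy.pY2[l1, a1, l2, a2]
    return float(risk)


def sample_toy(toy: ToyCohort, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Finite sample of n individuals (period-2 fields NaN for period-1 deaths)."""
    u = rng.random((n, 6))
    l1 = (u[:, 0] < toy.pL1).astype(int)
    a1 = (u[:, 1] < toy.pA1[l1]).astype(int)
    y1 = (u[:, 2] < toy.pY1[l1, a1]).astype(int)
    l2 = (u[:, 3] < toy.pL2[l1, a1]).astype(int)
    a2 = (u[:, 4] < toy.pA2[l1, a1, l2]).astype(int)
    y2 = (u[:, 5] < toy.pY2[l1, a1, l2, a2]).astype(int)
    df = pd.DataFrame({"L1": l1, "A1": a1, "Y1": y1, "L2": l2, "A2": a2, "Y2": y2})
    dead = df["Y1"] == 1
    df.loc[dead, ["L2", "A2", "Y2"]] = np.nan
    return df


def _saturated(df: pd.DataFrame, cols) -> np.ndarray:
    """Saturated design: intercept + all main effects and interactions."""
    n = len(df)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    for r in range(1, len(cols) + 1):
        from itertools import combinations

        for combo in combinations(cols, r):
            col = np.ones(n)
            for c in combo:
                col = col * df[c].to_numpy(dtype=float)
            blocks.append(col[:, None])
            names.append(":".join(combo))
    return np.concatenate(blocks, axis=1), names


def fit_toy_models(sample: pd.DataFrame) -> Dict[str, FittedModel]:
    """Saturated pooled logistic models for every conditional of the toy."""
    models = {}
    surv = sample[sample["Y1"] == 0]

    def fit(name, df, outcome, parents):
        X, names = _saturated(df, parents)
        models[name] = fit_pooled_logistic(
            X, df[outcome].to_numpy(dtype=float), names, outcome=name
        )

    fit("A1", sample, "A1", ["L1"])
    fit("Y1", sample, "Y1", ["L1", "A1"])
    fit("L2", surv, "L2", ["L1", "A1"])
    fit("A2", surv, "A2", ["L1", "A1", "L2"])
    fit("Y2", surv, "Y2", ["L1", "A1", "L2", "A2"])
    return models


def simulate_toy(
    models: Dict[str, FittedModel],
    baseline_l1: np.ndarray,
    intervention: str,
    mc_size: int,
    seed: int,
) -> float:
    """Monte Carlo parametric g-formula risk on the toy.

    Baselines (L1 values) are resampled with replacement from the observed
    sample; each pseudo-individual is stepped through the two periods drawing
    from the fitted models, with exposure forced by the intervention.
    """
    if intervention == "never_exposed":
        a_fix = 0
    elif intervention == "always_exposed":
        a_fix = 1
    elif intervention == "natural_course":
        a_fix = None
    else:
        raise ValueError(f"intervention {intervention!r} not defined for the toy")
    ss = np.random.SeedSequence(seed)
    rb, rs = [np.random.default_rng(s) for s in ss.spawn(2)]
    l1 = baseline_l1[rb.integers(0, len(baseline_l1), size=mc_size)].astype(float)
    u = rs.random((mc_size, 5))

    def pred(name, cols):
        df = pd.DataFrame(cols)
        X, _ = _saturated(df, list(cols))
        return predict_hazard(models[name], X)

    if a_fix is None:
        a1 = (u[:, 0] < pred("A1", {"L1": l1})).astype(float)
    else:
        a1 = np.full(mc_size, float(a_fix))
    y1 = (u[:, 1] < pred("Y1", {"L1": l1, "A1": a1})).astype(float)
    l2 = (u[:, 2] < pred("L2", {"L1": l1, "A1": a1})).astype(float)
    if a_fix is None:
        a2 = (u[:, 3] < pred("A2", {"L1": l1, "A1": a1, "L2": l2})).astype(float)
    else:
        a2 = np.full(mc_size, float(a_fix))
    y2 = (u[:, 4] < pred("Y2", {"L1": l1, "A1": a1, "L2": l2, "A2": a2})).astype(float)
    dead = (y1 == 1) | ((y1 == 0) & (y2 == 1))
    return float(dead.mean())
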