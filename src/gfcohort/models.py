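"""Discrete-time hazard models: pooled binary logistic and proportional odds.

Person-period records are stacked and each outcome is fit by maximum
likelihood with a damped Newton iteration (analytic gradient and Hessian,
gradient-norm tolerance 1e-8, iteration cap 50).  Frequency weights are
supported so that worker-level bootstrap replicates can be fit without
materialising resampled tables.  Standard errors come from the inverse
observed information; AIC = 2k - 2*loglik.

The proportional-odds model uses the cumulative-logit parameterisation

    P(Y <= j | x) = expit(theta_j - x'beta),    theta_1 < ... < theta_{J-1}

so a larger linear predictor x'beta shifts mass toward higher (heavier)
categories.  With no covariates the thresholds are the logits of the
cumulative category frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ModelFitError",
    "fit_pooled_logistic",
    "fit_proportional_odds",
    "predict_hazard",
    "predict_category_probs",
]

GRAD_TOL = 1e-8
MAX_ITER = 50


class ModelFitError(RuntimeError):
    """Raised when a model cannot be fit (degenerate outcome, separation,

    singular information, or non-convergence).  Never absorbed silently."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, covariates, family and risk-set filter.

    ``risk_set`` is a symbolic key resolved against the person-period table:
    ``at_risk`` (all person-periods), ``employed``/``unemployed`` (current
    status, requiring the next period's status to be observed for the
    employment-transition outcomes), matching how the simulation draws each
    transition.
    """

    outcome: str
    covariates: tuple
    family: str = "binary_logit"
    risk_set: str = "at_risk"

    def __post_init__(self) -> None:
        if self.family not in ("binary_logit", "proportional_odds"):
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class FittedModel:
    kind: str
    outcome: str
    param_names: list
    params: np.ndarray
    cov_params: Optional[np.ndarray] = None
    llf: Optional[float] = None
    nobs: float = 0.0
    converged: bool = True
    n_iter: int = 0
    spec: Optional[ModelSpec] = None
    n_thresholds: int = 0

    @property
    def bse(self) -> Optional[np.ndarray]:
        if self.cov_params is None:
            return None
        return np.sqrt(np.diag(self.cov_params))

    @property
    def aic(self) -> Optional[float]:
        if self.llf is None:
            return None
        return 2.0 * len(self.params) - 2.0 * self.llf

    @property
    def beta(self) -> np.ndarray:
        """Slope vector (excludes ordinal thresholds)."""
        return self.params[self.n_thresholds :]

    @property
    def thresholds(self) -> np.ndarray:
        return self.params[: self.n_thresholds]

    @classmethod
    def from_params(
        cls,
        kind: str,
        outcome: str,
        param_names: Sequence[str],
        params: Sequence[float],
        spec: Optional[ModelSpec] = None,
        n_thresholds: int = 0,
    ) -> "FittedModel":
        """Build a model object from known coefficients (truth models)."""
        return cls(
            kind=kind,
            outcome=outcome,
            param_names=list(param_names),
            params=np.asarray(params, dtype=float),
            spec=spec,
            n_thresholds=n_thresholds,
        )

    def params_dict(self) -> dict:
        return dict(zip(self.param_names, self.params.tolist()))

    def to_text(self) -> str:
        """Serialise estimates to a small tab-separated text block."""
        lines = [
            f"# outcome: {self.outcome}",
            f"# family: {self.kind}",
            f"# nobs: {self.nobs:g}",
            f"# loglik: {'NA' if self.llf is None else repr(self.llf)}",
            f"# aic: {'NA' if self.aic is None else repr(self.aic)}",
            f"# converged: {self.converged}",
            "term\testimate\tstd_error",
        ]
        bse = self.bse
        for i, name in enumerate(self.param_names):
            se = "NA" if bse is None else repr(float(bse[i]))
            lines.append(f"{name}\t{self.params[i]!r}\t{se}")
        return "\n".join(lines) + "\n"


def _check_design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    return X


def fit_pooled_logistic(
    X: np.ndarray,
    y: np.ndarray,
    param_names: Sequence[str],
    weights: Optional[np.ndarray] = None,
    outcome: str = "y",
    spec: Optional[ModelSpec] = None,
    start: Optional[np.ndarray] = None,
) -> FittedModel:
    """Maximum-likelihood logistic regression via damped Newton iteration.

    ``start`` warm-starts the iteration (e.g. at the full-sample solution when
    refitting bootstrap replicates); the solution does not depend on it.
    """
    X = _check_design(X)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("outcome length does not match design matrix")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    wsum = w.sum()
    events = float(w @ y)
    if events <= 0:
        raise ModelFitError(f"outcome {outcome!r} has no events in its risk set")
    if events >= wsum:
        raise ModelFitError(f"outcome {outcome!r} has no non-events in its risk set")

    if start is not None:
        beta = np.asarray(start, dtype=float).copy()
        if beta.shape != (k,):
            raise ValueError("start vector length does not match the design matrix")
    else:
        beta = np.zeros(k)
        # start the intercept (first all-ones column, if any) at logit of event rate
        ones_col = next((j for j in range(k) if np.all(X[:, j] == 1.0)), None)
        if ones_col is not None:
            p0 = events / wsum
            beta[ones_col] = np.log(p0 / (1.0 - p0))

    def loglik(b: np.ndarray) -> float:
        eta = X @ b
        # log expit / log(1-expit) computed stably
        return float(w @ (y * eta - np.logaddexp(0.0, eta)))

    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        p = expit(eta)
        g = X.T @ (w * (y - p))
        if np.max(np.abs(g)) < GRAD_TOL:
            converged = True
            break
        wt = w * p * (1.0 - p)
        H = X.T @ (X * wt[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            raise ModelFitError(
                f"singular information matrix fitting {outcome!r} "
                "(collinear covariates or separation)"
            )
        # cap the step length (wild Newton steps occur under near-separation)
        smax = np.max(np.abs(step))
        if smax > 20.0:
            step *= 20.0 / smax
        # step halving to guarantee ascent (tolerance relative to |loglik|)
        ll_floor = ll - 1e-9 * max(1.0, abs(ll))
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new = loglik(cand)
            if ll_new >= ll_floor:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        ll = ll_new
        if np.max(np.abs(beta)) > 1e3:
            raise ModelFitError(
                f"separation suspected fitting {outcome!r}: coefficients diverging"
            )
    else:
        it = MAX_ITER

    if np.max(np.abs(beta)) > 30.0:
        raise ModelFitError(
            f"separation suspected fitting {outcome!r}: |coefficient| > 30 at the solution"
        )
    eta = X @ beta
    p = expit(eta)
    if not converged:
        g = X.T @ (w * (y - p))
        # tolerate benign numerical floor: relative stationarity
        if np.max(np.abs(g)) < 1e-6 * max(1.0, wsum / 1e3):
            converged = True
    wt = w * p * (1.0 - p)
    H = X.T @ (X * wt[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise ModelFitError(f"singular information matrix at solution for {outcome!r}")
    if not converged:
        raise ModelFitError(
            f"logistic fit for {outcome!r} did not converge in {MAX_ITER} iterations"
        )
    return FittedModel(
        kind="binary_logit",
        outcome=outcome,
        param_names=list(param_names),
        params=beta,
        cov_params=cov,
        llf=ll,
        nobs=wsum,
        converged=converged,
        n_iter=it,
        spec=spec,
    )


def _ordinal_loglik_parts(theta, beta, X, Ymask, w):
    """Log-likelihood, gradient and Hessian of the cumulative-logit model."""
    n, k = X.shape
    J = Ymask.shape[1]
    q = (J - 1) + k
    eta = X @ beta
    # cumulative probabilities F_j = P(Y <= j), j = 0..J-2
    C = expit(theta[None, :] - eta[:, None])          # (n, J-1)
    Cfull = np.concatenate([np.zeros((n, 1)), C, np.ones((n, 1))], axis=1)
    P = np.diff(Cfull, axis=1)                        # (n, J)
    p_obs = np.clip((P * Ymask).sum(axis=1), 1e-300, None)
    ll = float(w @ np.log(p_obs))

    f = C * (1.0 - C)                                 # logistic density at theta_j - eta
    fp = f * (1.0 - 2.0 * C)                          # its derivative
    fful = np.concatenate([np.zeros((n, 1)), f, np.zeros((n, 1))], axis=1)
    fpful = np.concatenate([np.zeros((n, 1)), fp, np.zeros((n, 1))], axis=1)

    yidx = Ymask.argmax(axis=1)
    a = fful[np.arange(n), yidx + 1]                  # f at upper cut of observed cat
    b = fpb = fful[np.arange(n), yidx]                # f at lower cut
    ap = fpful[np.arange(n), yidx + 1]
    bp = fpful[np.arange(n), yidx]

    inv_p = 1.0 / p_obs
    grad = np.zeros(q)
    # dl/dtheta_j: + f(c_j)/p if j is upper cut, - f(c_{j-1})/p if lower cut
    upper_is = yidx          # theta index j == yidx   (upper cut of category yidx)
    lower_is = yidx - 1      # theta index of lower cut
    gt = np.zeros((n, J - 1))
    rows = np.arange(n)
    in_up = upper_is <= J - 2
    gt[rows[in_up], upper_is[in_up]] += (a * inv_p * w)[in_up]
    in_lo = lower_is >= 0
    gt[rows[in_lo], lower_is[in_lo]] -= (b * inv_p * w)[in_lo]
    grad[: J - 1] = gt.sum(axis=0)
    gb_scalar = -(a - b) * inv_p                      # dl/deta * -1 ... see below
    grad[J - 1 :] = X.T @ (w * gb_scalar)

    # Hessian of ll: d2p/p - (dp/p)(dp/p)'
    H = np.zeros((q, q))
    # --- outer-product part: -(dp)(dp)'/p^2, accumulated via dense per-row blocks
    # dp/dtheta rows are sparse (at most 2 nonzeros): build as (n, J-1)
    dpt = np.zeros((n, J - 1))
    dpt[rows[in_up], upper_is[in_up]] += a[in_up]
    dpt[rows[in_lo], lower_is[in_lo]] -= b[in_lo]
    dpb = -(a - b)                                    # dp/deta coefficient on x
    sw = w * inv_p * inv_p
    H[: J - 1, : J - 1] -= dpt.T @ (dpt * sw[:, None])
    cross = dpt.T @ (X * (dpb * sw)[:, None])
    H[: J - 1, J - 1 :] -= cross
    H[J - 1 :, : J - 1] -= cross.T
    H[J - 1 :, J - 1 :] -= X.T @ (X * (dpb * dpb * sw)[:, None])
    # --- second-derivative part: d2p/p
    swp = w * inv_p
    d2tt = np.zeros((n, J - 1))
    d2tt[rows[in_up], upper_is[in_up]] += ap[in_up]
    d2tt[rows[in_lo], lower_is[in_lo]] -= bp[in_lo]
    # d2p/dtheta_j dtheta_l is nonzero only on the diagonal
    H[np.arange(J - 1), np.arange(J - 1)] += (d2tt * swp[:, None]).sum(axis=0)
    # d2p/dtheta_j dbeta = -x * (fp at that cut with matching sign)
    c2 = np.zeros((n, J - 1))
    c2[rows[in_up], upper_is[in_up]] += ap[in_up]
    c2[rows[in_lo], lower_is[in_lo]] -= bp[in_lo]
    cross2 = -(c2.T @ (X * swp[:, None]))
    H[: J - 1, J - 1 :] += cross2
    H[J - 1 :, : J - 1] += cross2.T
    # d2p/dbeta dbeta' = x x' (fp(c_j) - fp(c_{j-1}))
    H[J - 1 :, J - 1 :] += X.T @ (X * ((ap - bp) * swp)[:, None])
    return ll, grad, H


def fit_proportional_odds(
    X: np.ndarray,
    y: np.ndarray,
    param_names: Sequence[str],
    weights: Optional[np.ndarray] = None,
    outcome: str = "y",
    spec: Optional[ModelSpec] = None,
    n_categories: int = 3,
    start: Optional[np.ndarray] = None,
) -> FittedModel:
    """Maximum-likelihood proportional-odds (cumulative logit) regression.

    ``y`` holds ordered category codes 0..J-1; ``param_names`` names the
    covariate columns of ``X`` (threshold names are prepended).
    """
    X = _check_design(X)
    y = np.asarray(y)
    n, k = X.shape
    J = n_categories
    if y.shape != (n,):
        raise ValueError("outcome length does not match design matrix")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    present = [j for j in range(J) if w[y == j].sum() > 0]
    if len(present) < J:
        missing = sorted(set(range(J)) - set(present))
        raise ModelFitError(
            f"ordinal outcome {outcome!r}: categories {missing} absent from the risk set"
        )
    Ymask = np.zeros((n, J))
    Ymask[np.arange(n), y.astype(int)] = 1.0

    if start is not None:
        params = np.asarray(start, dtype=float).copy()
        if params.shape != (J - 1 + k,):
            raise ValueError("start vector length does not match the design matrix")
    else:
        # start at marginal cumulative logits, zero slopes
        freq = (Ymask * w[:, None]).sum(axis=0) / w.sum()
        cum = np.cumsum(freq)[:-1]
        theta = np.log(cum / (1.0 - cum))
        params = np.concatenate([theta, np.zeros(k)])

    ll, g, H = _ordinal_loglik_parts(params[: J - 1], params[J - 1 :], X, Ymask, w)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        if np.max(np.abs(g)) < GRAD_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            raise ModelFitError(f"singular information matrix fitting {outcome!r}")
        smax = np.max(np.abs(step))
        if smax > 20.0:
            step *= 20.0 / smax
        ll_floor = ll - 1e-9 * max(1.0, abs(ll))
        alpha = 1.0
        for _ in range(30):
            cand = params + alpha * step
            th = cand[: J - 1]
            if np.all(np.diff(th) > 0):
                ll_new, g_new, H_new = _ordinal_loglik_parts(th, cand[J - 1 :], X, Ymask, w)
                if ll_new >= ll_floor:
                    break
            alpha *= 0.5
        else:
            raise ModelFitError(
                f"proportional-odds fit for {outcome!r}: threshold ordering could not be "
                "maintained during optimisation"
            )
        params, ll, g, H = cand, ll_new, g_new, H_new
        if np.max(np.abs(params)) > 1e3:
            raise ModelFitError(f"separation suspected fitting {outcome!r}")
    if np.max(np.abs(params)) > 30.0:
        raise ModelFitError(
            f"separation suspected fitting {outcome!r}: |coefficient| > 30 at the solution"
        )
    if not converged and np.max(np.abs(g)) < 1e-6 * max(1.0, w.sum() / 1e3):
        converged = True
    if not converged:
        raise ModelFitError(
            f"proportional-odds fit for {outcome!r} did not converge in {MAX_ITER} iterations"
        )
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        raise ModelFitError(f"singular information matrix at solution for {outcome!r}")
    names = [f"thresh_{j}" for j in range(1, J)] + list(param_names)
    return FittedModel(
        kind="proportional_odds",
        outcome=outcome,
        param_names=names,
        params=params,
        cov_params=cov,
        llf=ll,
        nobs=float(w.sum()),
        converged=converged,
        n_iter=it,
        spec=spec,
        n_thresholds=J - 1,
    )


def predict_hazard(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Discrete-time hazard: inverse-logit of the linear predictor."""
    if model.kind != "binary_logit":
        raise ValueError("predict_hazard requires a binary_logit model")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.params):
        raise ValueError(
            f"design has {X.shape[1]} columns, model {model.outcome!r} expects "
            f"{len(model.params)}"
        )
    return expit(X @ model.params)


def predict_category_probs(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Per-category probabilities from the cumulative-logit model: (n, J)."""
    if model.kind != "proportional_odds":
        raise ValueError("predict_category_probs requires a proportional_odds model")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    theta = model.thresholds
    beta = model.beta
    if X.shape[1] != len(beta):
        raise ValueError(
            f"design has {X.shape[1]} columns, model {model.outcome!r} expects {len(beta)}"
        )
    eta = X @ beta
    C = expit(theta[None, :] - eta[:, None])
    n = X.shape[0]
    Cfull = np.concatenate([np.zeros((n, 1)), C, np.ones((n, 1))], axis=1)
    return np.diff(Cfull, axis=1)
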