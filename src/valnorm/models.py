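"""Value-adaptation models and their fitting.

Four competing accounts of how a pooled hemodynamic response amplitude A
depends on the safe offer V_safe under a risk context V_risky (the SD of
the block's gamble):

- difference (nondivisive):      A = a + b * (V_safe - V_risky)
- basic divisive normalization:  A = a + b * V_safe / (V_safe + V_risky)
- enhanced divisive norm.:       A = A_max * V_safe / (sigma + V_safe + V_risky)
- full divisive normalization:   A = A_max * (V_safe + beta) / (sigma + V_safe + V_risky)

A_max is the maximum pooled activity, sigma the semisaturation constant
(response slope), and beta the baseline pooled activity.  The ratio
A_max * beta / sigma summarizes the predicted background activity in the
absence of stimulation.  The two linear models are fit by ordinary least
squares on the transformed regressor; the two saturating models by bounded
nonlinear least squares with a deterministic multi-start grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MODEL_NAMES",
    "LinearModelParams",
    "SaturatingModelParams",
    "ModelFit",
    "predict_difference",
    "predict_basic",
    "predict_enhanced",
    "predict_full",
    "predict",
    "background_activity",
    "aic",
    "fit_model",
    "predict_fit",
]

MODEL_NAMES = ("difference", "basic", "enhanced", "full")
N_PARAMS = {"difference": 2, "basic": 2, "enhanced": 2, "full": 3}

SIGMA_BOUNDS = (1e-6, 1e4)
BETA_BOUNDS = (0.0, 1e6)
AMAX_BOUNDS = (-1e6, 1e6)


@dataclass(frozen=True)
class LinearModelParams:
    """Intercept and scaling of the two linear models."""

    a: float
    b: float


@dataclass(frozen=True)
class SaturatingModelParams:
    """Parameters of the saturating (divisive) models.

    ``beta`` is None for the enhanced model, which has no baseline pool.
    """

    a_max: float
    sigma: float
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be nonnegative")


@dataclass
class ModelFit:
    model: str
    params: LinearModelParams | SaturatingModelParams
    rss: float
    n: int
    k: int
    aic: float
    converged: bool


def predict_difference(p: LinearModelParams, v_safe, v_risky):
    return p.a + p.b * (np.asarray(v_safe, float) - np.asarray(v_risky, float))


def predict_basic(p: LinearModelParams, v_safe, v_risky):
    v_safe = np.asarray(v_safe, float)
    v_risky = np.asarray(v_risky, float)
    denom = v_safe + v_risky
    if np.any(denom <= 0):
        raise ValueError("v_safe + v_risky must be positive")
    return p.a + p.b * v_safe / denom


def predict_enhanced(p: SaturatingModelParams, v_safe, v_risky):
    v_safe = np.asarray(v_safe, float)
    v_risky = np.asarray(v_risky, float)
    denom = p.sigma + v_safe + v_risky
    if np.any(denom <= 0):
        raise ValueError("sigma + v_safe + v_risky must be positive")
    return p.a_max * v_safe / denom


def predict_full(p: SaturatingModelParams, v_safe, v_risky):
    if p.beta is None:
        raise ValueError("full model requires beta")
    v_safe = np.asarray(v_safe, float)
    v_risky = np.asarray(v_risky, float)
    denom = p.sigma + v_safe + v_risky
    if np.any(denom <= 0):
        raise ValueError("sigma + v_safe + v_risky must be positive")
    return p.a_max * (v_safe + p.beta) / denom


_PREDICTORS = {
    "difference": predict_difference,
    "basic": predict_basic,
    "enhanced": predict_enhanced,
    "full": predict_full,
}


def predict(model: str, params, v_safe, v_risky):
    """Evaluate any of the four models."""
    return _PREDICTORS[model](params, v_safe, v_risky)


def predict_fit(fit: ModelFit, v_safe, v_risky):
    return predict(fit.model, fit.params, v_safe, v_risky)


def background_activity(p: SaturatingModelParams) -> float:
    """Predicted background activity A_max * beta / sigma."""
    if p.beta is None:
        raise ValueError("background activity requires beta (full model)")
    return p.a_max * p.beta / p.sigma


_RSS_FLOOR = 1e-300  # keeps log finite on (numerically) perfect fits


def aic(rss: float, n: int, k: int, corrected: bool = False) -> float:
    """Gaussian-likelihood AIC: n * ln(rss / n) + 2k (AICc optional)."""
    value = n * np.log(max(rss, _RSS_FLOOR) / n) + 2 * k
    if corrected:
        if n - k - 1 <= 0:
            raise ValueError("AICc undefined for n <= k + 1")
        value += 2 * k * (k + 1) / (n - k - 1)
    return float(value)


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[LinearModelParams, float]:
    X = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return LinearModelParams(a=float(coef[0]), b=float(coef[1])), float(resid @ resid)


def _nl_residuals(model: str):
    if model == "enhanced":
        def fun(theta, vs, vr, y):
            a_max, sigma = theta
            return a_max * vs / (sigma + vs + vr) - y
    else:
        def fun(theta, vs, vr, y):
            a_max, sigma, beta = theta
            return a_max * (vs + beta) / (sigma + vs + vr) - y
    return fun


def _start_grid(model: str, vs: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    med = float(np.median(vs))
    a0 = float(np.max(np.abs(y)))
    if a0 == 0:
        a0 = 1.0
    sigmas = [0.1 * med, med, 10 * med, 100 * med]
    starts = []
    for s in sigmas:
        s = float(np.clip(s, SIGMA_BOUNDS[0] * 10, SIGMA_BOUNDS[1] / 10))
        if model == "enhanced":
            starts.append(np.array([a0, s]))
        else:
            for b0 in (0.0, med):
                starts.append(np.array([a0, s, b0]))
    return starts


def fit_model(
    model: str,
    v_safe,
    v_risky,
    amplitude,
    *,
    corrected_aic: bool = False,
    x0: np.ndarray | None = None,
) -> ModelFit:
    """Fit one model to (V_safe, V_risky, amplitude) observations.

    Linear models use closed-form least squares; saturating models use
    bounded nonlinear least squares.  ``x0`` warm-starts the nonlinear
    optimizer with a single start (used by leave-one-out refits);
    otherwise a deterministic multi-start grid is searched and the best
    RSS kept.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    vs = np.asarray(v_safe, float).ravel()
    vr = np.asarray(v_risky, float).ravel()
    y = np.asarray(amplitude, float).ravel()
    if vr.size == 1:
        vr = np.full_like(vs, vr[0])
    if not (vs.size == vr.size == y.size):
        raise ValueError("v_safe, v_risky and amplitude must align")
    k = N_PARAMS[model]
    n = vs.size
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} observations, got {n}")
    if np.unique(vs).size < 2:
        raise ValueError("need at least 2 distinct v_safe values")

    if model == "difference":
        params, rss = _linear_fit(vs - vr, y)
        return ModelFit(model, params, rss, n, k, aic(rss, n, k, corrected_aic), True)
    if model == "basic":
        params, rss = _linear_fit(vs / (vs + vr), y)
        return ModelFit(model, params, rss, n, k, aic(rss, n, k, corrected_aic), True)

    fun = _nl_residuals(model)
    if model == "enhanced":
        lo = np.array([AMAX_BOUNDS[0], SIGMA_BOUNDS[0]])
        hi = np.array([AMAX_BOUNDS[1], SIGMA_BOUNDS[1]])
    else:
        lo = np.array([AMAX_BOUNDS[0], SIGMA_BOUNDS[0], BETA_BOUNDS[0]])
        hi = np.array([AMAX_BOUNDS[1], SIGMA_BOUNDS[1], BETA_BOUNDS[1]])
    starts = [np.asarray(x0, float)] if x0 is not None else _start_grid(model, vs, y)
    best = None
    for start in starts:
        start = np.clip(start, lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                fun, start, bounds=(lo, hi), args=(vs, vr, y), method="trf",
                max_nfev=2000,
            )
        except Exception:  # pragma: no cover - optimizer failure on one start
            continue
        rss = float(2 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:  # pragma: no cover
        raise RuntimeError("nonlinear fit failed from every start")
    rss, res = best
    if model == "enhanced":
        params = SaturatingModelParams(a_max=float(res.x[0]), sigma=float(res.x[1]))
    else:
        params = SaturatingModelParams(
            a_max=float(res.x[0]), sigma=float(res.x[1]), beta=float(res.x[2])
        )
    return ModelFit(
        model, params, rss, n, k, aic(rss, n, k, corrected_aic), bool(res.status > 0)
    )
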