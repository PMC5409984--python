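"""Model-comparison machinery.

Tools to decide which value-adaptation model best explains a beta series:
windowed Delta-AIC time courses (positive values favor the last-named
model), leave-one-participant-out cross-validated RMSE, Pearson
correlation distributions compared between experiments with two-sample
Kolmogorov-Smirnov tests and Gaussian kernel-density summaries, and a
previous-trial covariate control that residualizes amplitudes on the
preceding trial's condition before refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import MODEL_NAMES, ModelFit, fit_model, predict_fit
from .preprocessing import BetaSeries, WindowBank

__all__ = [
    "DeltaAicCourse",
    "CvResult",
    "CorrelationSummary",
    "fit_window_course",
    "delta_aic",
    "loo_cv",
    "correlation_summary",
    "previous_trial_control",
]

log = logging.getLogger(__name__)


@dataclass
class DeltaAicCourse:
    model_pair: tuple[str, str]
    values: np.ndarray  # one per window; positive favors the last-named model
    window_starts_s: np.ndarray


@dataclass
class CvResult:
    model: str
    rmse_per_participant: list[float]
    mean_rmse: float


@dataclass
class CorrelationSummary:
    model: str
    r_by_experiment: dict[str, np.ndarray]
    kde_grid: np.ndarray
    kde_by_experiment: dict[str, np.ndarray]
    ks_statistic: float
    ks_p: float
    n_excluded: int = 0


def fit_window_course(
    bs: BetaSeries, model: str, average_channels: bool = True
) -> tuple[np.ndarray, list[list[ModelFit]]]:
    """Fit one model per window (channel-averaged betas pooled over cells).

    Returns the per-window AIC array (channels x windows, channels == 1
    after averaging) together with the fits.
    """
    work = bs.average_channels() if average_channels else bs
    C, W, _ = work.beta.shape
    vs = work.cells["safe_value"].to_numpy(float)
    vr = work.cells["v_risky"].to_numpy(float)
    aics = np.full((C, W), np.nan)
    fits: list[list[ModelFit]] = []
    for c in range(C):
        row = []
        for w in range(W):
            y = work.beta[c, w]
            ok = np.isfinite(y)
            fit = fit_model(model, vs[ok], vr[ok], y[ok])
            aics[c, w] = fit.aic
            row.append(fit)
        fits.append(row)
    return aics, fits


def delta_aic(
    aic_first: np.ndarray,
    aic_last: np.ndarray,
    bank: WindowBank,
    model_pair: tuple[str, str] = ("first", "last"),
) -> DeltaAicCourse:
    """Per-window channel mean of AIC(first) - AIC(last).

    Positive values mean the last-named model fits relatively better.
    """
    aic_first = np.atleast_2d(np.asarray(aic_first, float))
    aic_last = np.atleast_2d(np.asarray(aic_last, float))
    if aic_first.shape != aic_last.shape:
        raise ValueError("AIC arrays must align on channel x window")
    if aic_first.shape[1] != bank.count:
        raise ValueError("AIC arrays must have one column per window")
    values = np.nanmean(aic_first - aic_last, axis=0)
    return DeltaAicCourse(
        model_pair=model_pair, values=values, window_starts_s=bank.starts
    )


def loo_cv(model: str, table: pd.DataFrame) -> CvResult:
    """Leave-one-participant-out cross-validated RMSE.

    ``table`` is a long amplitude table with columns participant, v_safe,
    v_risky, amplitude.  For each held-out participant the model is fitted
    to the pooled observations of everyone else and scored by the RMSE of
    its predictions on the held-out rows.  Nonlinear refits warm-start from
    the all-data fit.
    """
    table = table.dropna(subset=["amplitude"])
    participants = table["participant"].unique()
    if len(participants) < 2:
        raise ValueError("leave-one-out requires at least 2 participants")
    full = fit_model(
        model,
        table["v_safe"].to_numpy(),
        table["v_risky"].to_numpy(),
        table["amplitude"].to_numpy(),
    )
    x0 = None
    if model == "enhanced":
        x0 = np.array([full.params.a_max, full.params.sigma])
    elif model == "full":
        x0 = np.array([full.params.a_max, full.params.sigma, full.params.beta])
    rmses = []
    for p in participants:
        held = table["participant"] == p
        train = table[~held]
        fit = fit_model(
            model,
            train["v_safe"].to_numpy(),
            train["v_risky"].to_numpy(),
            train["amplitude"].to_numpy(),
            x0=x0,
        )
        pred = predict_fit(
            fit, table.loc[held, "v_safe"].to_numpy(), table.loc[held, "v_risky"].to_numpy()
        )
        resid = table.loc[held, "amplitude"].to_numpy() - pred
        rmses.append(float(np.sqrt(np.mean(resid**2))))
    return CvResult(model=model, rmse_per_participant=rmses, mean_rmse=float(np.mean(rmses)))


def _silverman_kde(r: np.ndarray, grid: np.ndarray) -> np.ndarray:
    kde = stats.gaussian_kde(r, bw_method="silverman")
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    return dens / area if area > 0 else dens


def correlation_summary(
    model: str,
    table: pd.DataFrame,
    value_col: str = "amplitude",
    pred_col: str = "prediction",
    grid_points: int = 401,
    by_context: bool = True,
) -> CorrelationSummary:
    """Per-participant Pearson r between predictions and observations,
    summarized per experiment with a Silverman-bandwidth Gaussian KDE over
    r in [-1, 1] and compared between experiments with a two-sample KS test
    (exact form when both samples have <= 25 participants).

    ``table`` needs columns participant, experiment, ``pred_col`` and
    ``value_col``.  With ``by_context`` (default) r is computed per risk
    context and averaged within participant, so that a context's own value
    range carries the correlation; otherwise all rows of a participant are
    pooled.  Units whose prediction vector has zero variance are excluded
    (logged).
    """
    r_by_exp: dict[str, list[float]] = {}
    n_excluded = 0
    unit_cols = ["experiment", "participant"] + (
        ["context"] if by_context and "context" in table.columns else []
    )
    unit_r: dict[tuple, list[float]] = {}
    for keys, sub in table.groupby(unit_cols):
        exp, p = keys[0], keys[1]
        pred = sub[pred_col].to_numpy(float)
        obs = sub[value_col].to_numpy(float)
        ok = np.isfinite(pred) & np.isfinite(obs)
        if ok.sum() < 3:
            n_excluded += 1
            log.warning("correlation_summary: <3 points for unit %s", (keys,))
            continue
        if np.std(pred[ok]) == 0 or np.std(obs[ok]) == 0:
            n_excluded += 1
            log.warning("correlation_summary: zero-variance series for unit %s", (keys,))
            continue
        r = float(stats.pearsonr(pred[ok], obs[ok]).statistic)
        unit_r.setdefault((exp, p), []).append(r)
    for (exp, _p), rs in unit_r.items():
        r_by_exp.setdefault(exp, []).append(float(np.mean(rs)))
    grid = np.linspace(-1, 1, grid_points)
    kde_by_exp = {
        exp: _silverman_kde(np.asarray(rs), grid) for exp, rs in r_by_exp.items() if len(rs) > 1
    }
    exps = sorted(r_by_exp)
    if len(exps) == 2:
        a, b = (np.asarray(r_by_exp[e]) for e in exps)
        method = "exact" if (len(a) <= 25 and len(b) <= 25) else "asymp"
        ks = stats.ks_2samp(a, b, method=method)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = np.nan, np.nan
    return CorrelationSummary(
        model=model,
        r_by_experiment={e: np.asarray(v) for e, v in r_by_exp.items()},
        kde_grid=grid,
        kde_by_experiment=kde_by_exp,
        ks_statistic=ks_stat,
        ks_p=ks_p,
        n_excluded=n_excluded,
    )


def previous_trial_control(
    table: pd.DataFrame,
    value_col: str = "amplitude",
    group_cols: tuple[str, ...] = ("participant",),
) -> pd.DataFrame:
    """Covary out the previous trial's condition from trial amplitudes.

    ``table`` must be trial-ordered with columns block, trial, context,
    safe_value and ``value_col``.  Within each group, amplitudes are
    residualized on previous-trial condition covariates (previous-context
    indicators + previous safe value) and the grand mean is added back.
    First trials of each block have no predecessor: they are excluded from
    the residualization design and returned unadjusted (``adjusted`` column
    marks rows).

    Note that in this blocked design the previous context equals the
    current context for every non-first trial, so the adjustment also
    absorbs between-context amplitude level differences — the price of the
    trial-history control; within-context value slopes are untouched.
    """
    out = table.copy().reset_index(drop=True)
    out["adjusted"] = False
    adj_col = f"{value_col}_adj"
    out[adj_col] = out[value_col].astype(float)
    for _, idx in out.groupby(list(group_cols)).groups.items():
        sub = out.loc[idx].sort_values(["block", "trial"])
        prev_ctx = sub["context"].shift(1)
        prev_safe = sub["safe_value"].shift(1)
        usable = (sub["trial"] > sub["trial"].min()) & prev_ctx.notna()
        if usable.sum() < 8:
            continue
        rows = sub.index[usable]
        dummies = pd.get_dummies(prev_ctx[usable], drop_first=True, dtype=float)
        X = np.column_stack(
            [np.ones(usable.sum()), dummies.to_numpy(),
             prev_safe[usable].to_numpy(float)]
        )
        y = sub.loc[usable, value_col].to_numpy(float)
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        out.loc[rows, adj_col] = (y - X @ coef) + y.mean()
        out.loc[rows, "adjusted"] = True
    return out
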