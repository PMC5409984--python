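"""Per-participant slope estimation and group-level ANOVAs.

Slopes of response time, % risky choice, and tHb amplitude against the
safe value are estimated per participant and condition cell by ordinary
least squares (a quadratic fit is kept alongside for display).  Group
inference uses a balanced split-plot (univariate repeated-measures) ANOVA:
one between-subject factor (experiment) and one or two within-subject
factors (context, and secondary load in the two-load design), each within
effect tested against its interaction with subjects nested in groups.
Post-hoc comparisons are Bonferroni-corrected pairwise t tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import SaturatingModelParams, background_activity, fit_model

__all__ = [
    "AnovaResult",
    "compute_slopes",
    "mixed_anova",
    "posthoc_pairwise",
    "fit_participant_params",
    "parameter_analysis",
]

log = logging.getLogger(__name__)


def compute_slopes(
    table: pd.DataFrame,
    measure: str,
    x_col: str | None = None,
    value_col: str | None = None,
    group_cols: tuple[str, ...] = ("participant", "experiment", "load", "context"),
) -> pd.DataFrame:
    """Per-cell linear slope (and quadratic display fit) against safe value.

    measure: 'rt' (uses rt_s, missed trials dropped), 'risky_choice_pct'
    (percentage risky per safe level, then regressed), or 'thb' (amplitude
    column of a beta table).
    """
    if measure == "rt":
        x_col = x_col or "safe_value"
        value_col = value_col or "rt_s"
        work = table[~table["missed"].astype(bool)] if "missed" in table else table
    elif measure == "risky_choice_pct":
        x_col = x_col or "safe_value"
        work = table[~table["missed"].astype(bool)] if "missed" in table else table
    elif measure == "thb":
        x_col = x_col or "v_safe"
        value_col = value_col or "amplitude"
        work = table
    else:
        raise ValueError(f"unknown measure {measure!r}")

    group_cols = tuple(c for c in group_cols if c in work.columns)
    rows = []
    for keys, sub in work.groupby(list(group_cols)):
        if measure == "risky_choice_pct":
            per_level = sub.groupby(x_col)["chose_risky"].mean() * 100.0
            x = per_level.index.to_numpy(float)
            y = per_level.to_numpy(float)
        else:
            sub = sub.dropna(subset=[value_col])
            x = sub[x_col].to_numpy(float)
            y = sub[value_col].to_numpy(float)
        if np.unique(x).size < 3:
            raise ValueError(
                f"need >= 3 distinct safe values per cell (cell {keys})"
            )
        slope = float(np.polyfit(x, y, 1)[0])
        quad = np.polyfit(x, y, 2)
        rec = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        rec.update(
            measure=measure,
            slope=slope,
            quad_a=float(quad[0]),
            quad_b=float(quad[1]),
            quad_c=float(quad[2]),
        )
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    table: pd.DataFrame  # Source, SS, df1, df2, F, p
    posthoc: pd.DataFrame | None = None
    n_comparisons: int = 0

    def effect(self, source: str) -> pd.Series:
        hit = self.table[self.table["Source"] == source]
        if hit.empty:
            raise KeyError(source)
        return hit.iloc[0]


def _cell_mean_array(
    df: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> tuple[np.ndarray, list, list[list]]:
    """Replicate-averaged cell means, shape (subjects, levels1[, levels2])."""
    subjects = sorted(df[subject].unique())
    level_lists = [sorted(df[w].unique()) for w in within]
    shape = (len(subjects), *[len(lv) for lv in level_lists])
    Y = np.full(shape, np.nan)
    grouped = df.groupby([subject, *within])[dv].mean()
    for idx, val in grouped.items():
        s = subjects.index(idx[0])
        pos = tuple(level_lists[i].index(idx[1 + i]) for i in range(len(within)))
        Y[(s, *pos)] = val
    if np.isnan(Y).any():
        missing = int(np.isnan(Y).sum())
        raise ValueError(
            f"unbalanced design: {missing} empty subject x within cells"
        )
    return Y, subjects, level_lists


def mixed_anova(
    df: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
    between: str | None = None,
    posthoc: bool = True,
) -> AnovaResult:
    """Split-plot repeated-measures ANOVA.

    Supports one between-subject factor plus one or two within-subject
    factors; every within effect is tested against its interaction with
    subjects nested in groups.  Requires each subject to have every within
    cell (replicates are averaged); between-group sizes may differ.
    """
    within = [within] if isinstance(within, str) else list(within)
    if len(within) not in (1, 2):
        raise NotImplementedError("one or two within factors supported")
    Y, subjects, level_lists = _cell_mean_array(df, dv, subject, within)
    N = len(subjects)
    if between is not None and df[between].nunique() < 2:
        log.warning("mixed_anova: between factor %r has one level; dropped", between)
        between = None
    if between is not None:
        grp_of = df.groupby(subject)[between].first()
        groups = sorted(grp_of.unique())
        g_idx = np.array([groups.index(grp_of[s]) for s in subjects])
    else:
        groups = ["_all_"]
        g_idx = np.zeros(N, int)
    a = len(groups)
    n_g = np.array([(g_idx == g).sum() for g in range(a)])
    if np.any(n_g < 2) and a > 1:
        raise ValueError("each between group needs >= 2 subjects")

    def f_and_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int):
        """F ratio with the degenerate zero-variance cases made explicit."""
        ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
        if ms_err == 0:
            return (0.0, 1.0) if ms_eff == 0 else (np.inf, 0.0)
        F = ms_eff / ms_err
        return F, float(stats.f.sf(F, df_eff, df_err))

    cells_per_subj = int(np.prod(Y.shape[1:]))
    m = Y.mean()
    m_s = Y.reshape(N, -1).mean(axis=1)
    m_g = np.array([m_s[g_idx == g].mean() for g in range(a)])
    rows = []

    # between-subjects stratum
    ss_A = cells_per_subj * float(np.sum(n_g * (m_g - m) ** 2))
    ss_S = cells_per_subj * float(np.sum((m_s - m_g[g_idx]) ** 2))
    df_S = N - a
    if between is not None:
        F_A, p_A = f_and_p(ss_A, a - 1, ss_S, df_S)
        rows.append(
            dict(Source=between, SS=ss_A, df1=a - 1, df2=df_S, F=F_A, p=p_A)
        )

    def group_mean(arr: np.ndarray) -> np.ndarray:
        """Mean over subjects within each between group, keeping other axes."""
        return np.stack([arr[g_idx == g].mean(axis=0) for g in range(a)])

    def add_within(axis: int, name: str) -> None:
        b = Y.shape[axis]
        other = [ax for ax in range(1, Y.ndim) if ax != axis]
        m_sb = Y.mean(axis=tuple(other)) if other else Y  # (N, b)
        m_gb = group_mean(m_sb)                            # (a, b)
        m_b = (n_g[:, None] * m_gb).sum(axis=0) / N        # (b,)
        c_mult = cells_per_subj // b
        ss_B = N * c_mult * float(np.sum((m_b - m) ** 2))
        ss_BS = c_mult * float(
            np.sum((m_sb - m_s[:, None] - m_gb[g_idx] + m_g[g_idx, None]) ** 2)
        )
        df_B = b - 1
        df_BS = (b - 1) * (N - a)
        F_B, p_B = f_and_p(ss_B, df_B, ss_BS, df_BS)
        rows.append(
            dict(Source=name, SS=ss_B, df1=df_B, df2=df_BS, F=F_B, p=p_B)
        )
        if between is not None:
            ss_AB = c_mult * float(
                np.sum(
                    n_g[:, None]
                    * (m_gb - m_g[:, None] - m_b[None, :] + m) ** 2
                )
            )
            df_AB = (a - 1) * (b - 1)
            F_AB, p_AB = f_and_p(ss_AB, df_AB, ss_BS, df_BS)
            rows.append(
                dict(Source=f"{name} * {between}", SS=ss_AB, df1=df_AB,
                     df2=df_BS, F=F_AB, p=p_AB)
            )

    for i, name in enumerate(within):
        add_within(axis=1 + i, name=name)

    if len(within) == 2:
        b, c = Y.shape[1], Y.shape[2]
        m_sbc = Y                                  # (N, b, c)
        m_gbc = group_mean(Y)                      # (a, b, c)
        m_bc = (n_g[:, None, None] * m_gbc).sum(axis=0) / N
        m_sb = Y.mean(axis=2)
        m_sc = Y.mean(axis=1)
        m_gb = group_mean(m_sb)
        m_gc = group_mean(m_sc)
        m_b = (n_g[:, None] * m_gb).sum(axis=0) / N
        m_c = (n_g[:, None] * m_gc).sum(axis=0) / N
        ss_BC = N * float(
            np.sum((m_bc - m_b[:, None] - m_c[None, :] + m) ** 2)
        )
        resid = (
            m_sbc
            - m_sb[:, :, None]
            - m_sc[:, None, :]
            - m_gbc[g_idx]
            + m_s[:, None, None]
            + m_gb[g_idx][:, :, None]
            + m_gc[g_idx][:, None, :]
            - m_g[g_idx][:, None, None]
        )
        ss_BCS = float(np.sum(resid**2))
        df_BC = (b - 1) * (c - 1)
        df_BCS = (b - 1) * (c - 1) * (N - a)
        F_BC, p_BC = f_and_p(ss_BC, df_BC, ss_BCS, df_BCS)
        rows.append(
            dict(Source=f"{within[0]} * {within[1]}", SS=ss_BC, df1=df_BC,
                 df2=df_BCS, F=F_BC, p=p_BC)
        )
        if between is not None:
            dev = (
                m_gbc
                - m_gb[:, :, None]
                - m_gc[:, None, :]
                - m_bc[None, :, :]
                + m_g[:, None, None]
                + m_b[None, :, None]
                + m_c[None, None, :]
                - m
            )
            ss_ABC = float(np.sum(n_g[:, None, None] * dev**2))
            df_ABC = (a - 1) * (b - 1) * (c - 1)
            F_ABC, p_ABC = f_and_p(ss_ABC, df_ABC, ss_BCS, df_BCS)
            rows.append(
                dict(
                    Source=f"{within[0]} * {within[1]} * {between}",
                    SS=ss_ABC, df1=df_ABC, df2=df_BCS, F=F_ABC, p=p_ABC,
                )
            )

    result = AnovaResult(table=pd.DataFrame(rows))
    if posthoc:
        ph = posthoc_pairwise(df, dv, within, subject, between)
        result.posthoc = ph
        result.n_comparisons = len(ph)
    return result


def posthoc_pairwise(
    df: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
    between: str | None = None,
) -> pd.DataFrame:
    """All pairwise cell comparisons with Bonferroni adjustment.

    Within each between group, every pair of within cells is compared with
    a paired t test; for each within cell, between groups are compared with
    an independent t test.  The Bonferroni multiplier m is the number of
    comparisons actually performed (reported in the output).
    """
    within = [within] if isinstance(within, str) else list(within)
    work = df.copy()
    work["_cell"] = work[within].astype(str).agg(" / ".join, axis=1)
    cell_means = work.groupby(
        [subject, "_cell", *( [between] if between else [] )]
    )[dv].mean().reset_index()
    cells = sorted(cell_means["_cell"].unique())
    groups = sorted(cell_means[between].unique()) if between else ["_all_"]
    rows = []
    for g in groups:
        sub = cell_means if between is None else cell_means[cell_means[between] == g]
        wide = sub.pivot(index=subject, columns="_cell", values=dv)
        for c1, c2 in itertools.combinations(cells, 2):
            t, p = stats.ttest_rel(wide[c1], wide[c2])
            rows.append(dict(group=g, cell_a=c1, cell_b=c2, kind="within",
                             t=float(t), p_raw=float(p)))
    if between is not None and len(groups) >= 2:
        for cell in cells:
            sub = cell_means[cell_means["_cell"] == cell]
            for g1, g2 in itertools.combinations(groups, 2):
                t, p = stats.ttest_ind(
                    sub.loc[sub[between] == g1, dv], sub.loc[sub[between] == g2, dv]
                )
                rows.append(dict(group=f"{g1} vs {g2}", cell_a=cell, cell_b=cell,
                                 kind="between", t=float(t), p_raw=float(p)))
    out = pd.DataFrame(rows)
    m = len(out)
    out["m"] = m
    out["p_bonf"] = np.minimum(1.0, out["p_raw"] * m)
    return out


def fit_participant_params(
    table: pd.DataFrame,
    by: tuple[str, ...] = ("participant", "context"),
    carry_cols: tuple[str, ...] = ("experiment", "load"),
) -> pd.DataFrame:
    """Fit the full divisive normalization model per participant (and
    context), returning a_max, sigma, beta, and the background-activity
    ratio A_max * beta / sigma per fit."""
    rows = []
    for keys, sub in table.groupby(list(by)):
        sub = sub.dropna(subset=["amplitude"])
        fit = fit_model(
            "full",
            sub["v_safe"].to_numpy(),
            sub["v_risky"].to_numpy(),
            sub["amplitude"].to_numpy(),
        )
        p: SaturatingModelParams = fit.params
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        for c in carry_cols:
            if c in sub.columns:
                rec[c] = sub[c].iloc[0]
        rec.update(
            a_max=p.a_max,
            sigma=p.sigma,
            beta=p.beta,
            background=background_activity(p),
            rss=fit.rss,
            converged=fit.converged,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def parameter_analysis(
    params: pd.DataFrame,
    within: str | list[str] = "context",
    between: str | None = "experiment",
    subject: str = "participant",
) -> dict[str, AnovaResult]:
    """ANOVAs on the fitted full-model parameters a_max, sigma, beta and
    the background-activity ratio.  Non-converged fits are excluded (count
    logged)."""
    work = params
    if "converged" in params.columns:
        bad = int((~params["converged"].astype(bool)).sum())
        if bad:
            log.warning("parameter_analysis: excluding %d non-converged fits", bad)
            work = params[params["converged"].astype(bool)]
            # listwise removal keeps the within design balanced
            wcols = [within] if isinstance(within, str) else list(within)
            expected = int(np.prod([params[w].nunique() for w in wcols]))
            n_cells = work.groupby(subject).size()
            keep = n_cells[n_cells == expected].index
            dropped = set(work[subject]) - set(keep)
            if dropped:
                log.warning(
                    "parameter_analysis: dropping %d participants with "
                    "incomplete cells: %s", len(dropped), sorted(dropped)
                )
                work = work[work[subject].isin(keep)]
    out = {}
    for dv in ("a_max", "sigma", "beta", "background"):
        out[dv] = mixed_anova(work, dv, within=within, subject=subject, between=between)
    return out
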