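"""End-to-end orchestration: simulate -> preprocess -> fit -> compare -> stats.

A run is fully reproducible from a :class:`PipelineConfig` plus its master
seed; per-participant randomness is derived with ``np.random.SeedSequence``
spawning.  The report bundle contains TSV tables, a JSON run log, and
figures (slope curves, Delta-AIC time courses, correlation KDEs, parameter
bars).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import (
    correlation_summary,
    delta_aic,
    fit_window_course,
    loo_cv,
)
from .group_stats import (
    compute_slopes,
    fit_participant_params,
    mixed_anova,
    parameter_analysis,
)
from .models import MODEL_NAMES, fit_model, predict_fit
from .preprocessing import compute_thb, detrend, flag_motion, make_window_bank, peak_average, sliding_glm
from .synthetic import (
    default_ground_truth,
    perturb_truth,
    simulate_behavior,
    simulate_recording,
    write_recording,
)
from .task_design import generate_session

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    study: int = 1
    experiments: tuple[str, ...] = ("dual", "single")
    n_per_group: int = 6
    generating_model: str = "full"
    noise_sd: float = 0.05
    drift_amplitude: float = 0.2
    param_cv: float = 0.1
    n_channels: int = 16
    fs_hz: float = 7.81
    window_count: int = 40
    window_length_s: float = 2.5
    window_step_s: float = 0.18
    motion_spike_rate_per_min: float = 0.0
    save_recordings: bool = False
    out_dir: str = "valnorm_out"
    seed: int = 0
    # extra GroundTruth keyword overrides (e.g. miss_prob, hrf_peak_range_s)
    truth_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        cfg = cls(**data)
        if isinstance(cfg.experiments, list):
            cfg.experiments = tuple(cfg.experiments)
        return cfg

    def to_json(self) -> str:
        d = asdict(self)
        d["experiments"] = list(self.experiments)
        return json.dumps(d, indent=2)


def _truth_for(cfg: PipelineConfig, seed: int):
    overrides = dict(cfg.truth_overrides)
    if "hrf_peak_range_s" in overrides:
        overrides["hrf_peak_range_s"] = tuple(overrides["hrf_peak_range_s"])
    return default_ground_truth(
        cfg.generating_model,
        seed=seed,
        noise_sd=cfg.noise_sd,
        drift_amplitude=cfg.drift_amplitude,
        param_cv=cfg.param_cv,
        motion_spike_rate_per_min=cfg.motion_spike_rate_per_min,
        **overrides,
    )


def simulate_cohort(cfg: PipelineConfig, out_dir: Path | None = None):
    """Simulate sessions, behavior and recordings for the whole cohort.

    Returns (sessions, behaviors, recordings) keyed by (experiment, index).
    """
    ss = np.random.SeedSequence(cfg.seed)
    base_truth = _truth_for(cfg, cfg.seed)
    sessions, behaviors, recordings = {}, {}, {}
    n_total = len(cfg.experiments) * cfg.n_per_group
    children = ss.spawn(n_total)
    i = 0
    for experiment in cfg.experiments:
        for p in range(cfg.n_per_group):
            rng = np.random.default_rng(children[i])
            design_seed = int(rng.integers(0, 2**31 - 1))
            session = generate_session(cfg.study, experiment, design_seed)
            truth_p = perturb_truth(base_truth, rng)
            behavior = simulate_behavior(session, truth_p, rng)
            rec = simulate_recording(
                session, behavior, truth_p, rng, n_channels=cfg.n_channels, fs_hz=cfg.fs_hz
            )
            key = (experiment, p)
            sessions[key], behaviors[key], recordings[key] = session, behavior, rec
            if out_dir is not None and cfg.save_recordings:
                write_recording(rec, out_dir / f"sub-{experiment}-{p:02d}.h5")
            i += 1
    return sessions, behaviors, recordings


def preprocess_cohort(cfg: PipelineConfig, recordings: dict):
    """Detrend, motion-flag, and run the sliding GLM for every recording."""
    bank = make_window_bank(cfg.window_count, cfg.window_length_s, cfg.window_step_s)
    beta_series, amp_rows = {}, []
    for (experiment, p), rec in recordings.items():
        thb = detrend(compute_thb(rec), rec.fs_hz)
        flags = flag_motion(thb, rec.fs_hz)
        missed = None
        bs = sliding_glm(thb, rec.events, rec.fs_hz, bank=bank, flags=flags, missed=missed)
        beta_series[(experiment, p)] = bs
        amp = peak_average(bs)
        amp["participant"] = f"{experiment}-{p:02d}"
        amp["experiment"] = experiment
        amp = amp.rename(columns={"safe_value": "v_safe"})
        amp_rows.append(amp)
    amplitude_table = pd.concat(amp_rows, ignore_index=True)
    return beta_series, amplitude_table


def compare_models(cfg: PipelineConfig, beta_series: dict, amplitude_table: pd.DataFrame):
    """Delta-AIC courses, LOO-CV RMSE, and correlation summaries."""
    bank = make_window_bank(cfg.window_count, cfg.window_length_s, cfg.window_step_s)
    aic_by_model = {}
    for model in MODEL_NAMES:
        per_exp = {}
        for experiment in cfg.experiments:
            courses = [
                fit_window_course(bs, model)[0]
                for (exp, _), bs in beta_series.items()
                if exp == experiment
            ]
            per_exp[experiment] = np.vstack([c.mean(axis=0) for c in courses])
        aic_by_model[model] = per_exp
    pairs = [("difference", "full"), ("basic", "full"), ("enhanced", "full")]
    courses = {}
    for experiment in cfg.experiments:
        for first, last in pairs:
            courses[(experiment, first, last)] = delta_aic(
                aic_by_model[first][experiment].mean(axis=0, keepdims=True),
                aic_by_model[last][experiment].mean(axis=0, keepdims=True),
                bank,
                model_pair=(first, last),
            )
    cv = {
        model: {
            experiment: loo_cv(
                model, amplitude_table[amplitude_table["experiment"] == experiment]
            )
            for experiment in cfg.experiments
        }
        for model in MODEL_NAMES
    }
    # per-participant own-fit predictions -> correlation distributions
    corr = {}
    for model in MODEL_NAMES:
        tabs = []
        for p_id, sub in amplitude_table.dropna(subset=["amplitude"]).groupby("participant"):
            fit = fit_model(
                model, sub["v_safe"].to_numpy(), sub["v_risky"].to_numpy(),
                sub["amplitude"].to_numpy(),
            )
            sub = sub.copy()
            sub["prediction"] = predict_fit(
                fit, sub["v_safe"].to_numpy(), sub["v_risky"].to_numpy()
            )
            tabs.append(sub)
        corr[model] = correlation_summary(model, pd.concat(tabs, ignore_index=True))
    return courses, cv, corr


def group_statistics(cfg: PipelineConfig, behaviors: dict, amplitude_table: pd.DataFrame):
    """Slope tables and group ANOVAs for behavior, hemodynamics and params."""
    beh = []
    for (experiment, p), b in behaviors.items():
        b = b.copy()
        b["participant"] = f"{experiment}-{p:02d}"
        beh.append(b)
    behavior_table = pd.concat(beh, ignore_index=True)
    within = ["context"] if cfg.study == 1 else ["context", "load"]
    slopes, anovas = {}, {}
    for measure in ("rt", "risky_choice_pct", "thb"):
        table = behavior_table if measure != "thb" else amplitude_table
        s = compute_slopes(table, measure)
        slopes[measure] = s
        anovas[measure] = mixed_anova(
            s, "slope", within=[w for w in within if w in s.columns],
            subject="participant", between="experiment",
        )
    by = ("participant", "context") if cfg.study == 1 else ("participant", "context", "load")
    params = fit_participant_params(amplitude_table, by=by)
    params["experiment"] = params["participant"].str.split("-").str[0]
    param_within = ["context"] if cfg.study == 1 else ["context", "load"]
    param_anovas = parameter_analysis(params, within=param_within)
    return behavior_table, slopes, anovas, params, param_anovas


def _plot_slopes(amplitude_table: pd.DataFrame, out: Path) -> None:
    experiments = sorted(amplitude_table["experiment"].unique())
    fig, axes = plt.subplots(1, len(experiments), figsize=(5 * len(experiments), 4),
                             squeeze=False)
    for ax, experiment in zip(axes[0], experiments):
        sub = amplitude_table[amplitude_table["experiment"] == experiment]
        for ctx, cdf in sub.groupby("context"):
            mean = cdf.groupby("v_safe")["amplitude"].mean()
            coef = np.polyfit(mean.index, mean.values, 2)
            xs = np.linspace(mean.index.min(), mean.index.max(), 50)
            ax.plot(mean.index, mean.values, "o", ms=3, label=ctx)
            ax.plot(xs, np.polyval(coef, xs), "-", lw=1)
        ax.set_title(f"{experiment}-alternative")
        ax.set_xlabel("safe value (CHF)")
        ax.set_ylabel("tHb amplitude (a.u.)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)


def _plot_delta_aic(courses: dict, out: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for (experiment, first, last), course in courses.items():
        ax.plot(course.window_starts_s, course.values,
                label=f"{experiment}: {first} vs {last}")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("window start (s)")
    ax.set_ylabel(r"$\Delta$AIC (positive favors last)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)


def _plot_correlations(corr: dict, out: Path) -> None:
    fig, axes = plt.subplots(1, len(corr), figsize=(4 * len(corr), 3.5), squeeze=False)
    for ax, (model, summary) in zip(axes[0], corr.items()):
        for experiment, dens in summary.kde_by_experiment.items():
            ax.plot(summary.kde_grid, dens, label=experiment)
        ax.set_title(f"{model} (KS p={summary.ks_p:.3g})", fontsize=9)
        ax.set_xlabel("Pearson r")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)


def _plot_params(params: pd.DataFrame, out: Path) -> None:
    fig, axes = plt.subplots(1, 4, figsize=(13, 3.2))
    for ax, dv in zip(axes, ("a_max", "sigma", "beta", "background")):
        agg = params.groupby("experiment")[dv].agg(["mean", "sem"])
        ax.bar(agg.index, agg["mean"], yerr=agg["sem"], capsize=3)
        ax.set_title(dv)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle to cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        sessions, behaviors, recordings = simulate_cohort(cfg, out)
        stage = "preprocess"
        beta_series, amplitude_table = preprocess_cohort(cfg, recordings)
        stage = "compare"
        courses, cv, corr = compare_models(cfg, beta_series, amplitude_table)
        stage = "stats"
        behavior_table, slopes, anovas, params, param_anovas = group_statistics(
            cfg, behaviors, amplitude_table
        )
        stage = "report"
        amplitude_table.to_csv(out / "amplitudes.tsv", sep="\t", index=False)
        behavior_table.to_csv(out / "behavior.tsv", sep="\t", index=False)
        params.to_csv(out / "model_params.tsv", sep="\t", index=False)
        for measure, s in slopes.items():
            s.to_csv(out / f"slopes_{measure}.tsv", sep="\t", index=False)
            anovas[measure].table.to_csv(out / f"anova_{measure}.tsv", sep="\t", index=False)
        for dv, res in param_anovas.items():
            res.table.to_csv(out / f"anova_param_{dv}.tsv", sep="\t", index=False)
        cv_rows = [
            dict(model=m, experiment=e, mean_rmse=r.mean_rmse)
            for m, per in cv.items()
            for e, r in per.items()
        ]
        pd.DataFrame(cv_rows).to_csv(out / "loo_rmse.tsv", sep="\t", index=False)
        course_rows = [
            dict(experiment=e, first=f, last=l, window_start_s=float(t), delta_aic=float(v))
            for (e, f, l), c in courses.items()
            for t, v in zip(c.window_starts_s, c.values)
        ]
        pd.DataFrame(course_rows).to_csv(out / "delta_aic.tsv", sep="\t", index=False)
        _plot_slopes(amplitude_table, out / "fig_slopes.png")
        _plot_delta_aic(courses, out / "fig_delta_aic.png")
        _plot_correlations(corr, out / "fig_correlation_kde.png")
        _plot_params(params, out / "fig_parameters.png")
        run_log = dict(
            valnorm_version=__version__,
            python=platform.python_version(),
            numpy=np.__version__,
            seed=cfg.seed,
            config=json.loads(cfg.to_json()),
            ks_p_full=corr["full"].ks_p,
        )
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
        (out / "config.json").write_text(cfg.to_json())
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return dict(
        amplitude_table=amplitude_table,
        behavior_table=behavior_table,
        beta_series=beta_series,
        courses=courses,
        cv=cv,
        corr=corr,
        slopes=slopes,
        anovas=anovas,
        params=params,
        param_anovas=param_anovas,
        out_dir=out,
    )
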