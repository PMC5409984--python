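"""Synthetic behavioral and hemodynamic data with known ground truth.

The generator is the forward counterpart of the analysis chain: trial
response amplitudes come from one of the four value-adaptation models
(:mod:`valnorm.models`), choices from a logistic rule on the value
difference, response times from a quadratic choice-difficulty law, and the
optical recording from HRF convolution plus drift and white noise.  Every
downstream stage can therefore be tested against the injected truth.

Default generating parameters (the simulated study conditions):

- full divisive normalization with context-dependent maximum pooled
  activity and semisaturation (A_max 1.2 / sigma 30-40 CHF in low-risk
  contexts, A_max 0.9 / sigma 70-90 CHF in high-risk contexts, shared by
  both experiments) and baseline pooled activity beta = 5 CHF when the
  risk context is visually presented (dual) vs. 25 CHF when it must be
  held in memory (single); a high secondary load adds a further 15 CHF to
  beta.  This yields steeper value slopes in low-risk contexts and
  flatter slopes under memory demand, with the experiment difference
  carried by beta alone.
- recording noise SD 0.05 per chromophore sample; beta-stage amplitude
  noise SD 0.012 (calibrated to what the recording chain produces);
  between-participant parameter variability 10% (lognormal).
- 16 channels at 7.81 Hz, HRF peak delay per channel in 5-6 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from . import models as _models
from .hrf import hrf_kernel
from .task_design import (
    SessionDesign,
    gamble_context_value,
    gamble_ev,
    make_gamble_set,
)

__all__ = [
    "GroundTruth",
    "HemoRecording",
    "default_ground_truth",
    "perturb_truth",
    "trial_amplitude",
    "simulate_behavior",
    "simulate_recording",
    "simulate_cohort_amplitudes",
    "write_recording",
    "read_recording",
]

DEFAULT_FS_HZ = 7.81
DEFAULT_N_CHANNELS = 16

CONTEXT_SD = {g.label: gamble_context_value(g) for g in make_gamble_set()}
CONTEXT_EV = {g.label: gamble_ev(g) for g in make_gamble_set()}


@dataclass
class GroundTruth:
    """Generating model, parameters per condition, and nuisance settings."""

    generating_model: str = "full"
    # (context_label, experiment, load) -> parameter object
    params_by_condition: dict = field(default_factory=dict)
    noise_sd: float = 0.05
    # iid noise on beta-series amplitudes when simulating at that stage
    # directly; default matches the beta-estimate error the full recording
    # chain produces at the default recording noise
    beta_noise_sd: float = 0.012
    drift_amplitude: float = 0.2
    drift_period_range_s: tuple[float, float] = (180.0, 600.0)
    choice_temperature: float = 8.0
    risk_premium: float = 0.3
    rt_base_s: float = 0.8
    rt_difficulty_gain: float = 1.2
    rt_noise_sd: float = 0.15
    miss_prob: float = 0.01
    hrf_peak_range_s: tuple[float, float] = (5.0, 6.0)
    background_gain: float = 0.1
    motion_spike_rate_per_min: float = 0.0
    param_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be > 0")

    def params_for(self, context: str, experiment: str, load: str):
        key = (context, experiment, load)
        if key not in self.params_by_condition:
            raise KeyError(f"no parameters for condition {key}")
        return self.params_by_condition[key]


# per-context maximum pooled activity and semisaturation: low-risk contexts
# get higher gain and a smaller semisaturation constant, which is what makes
# value coding steeper when the contextual risk is low
_CONTEXT_SATURATION = {
    "lowR-lowEV": (1.2, 30.0),
    "lowR-highEV": (1.2, 40.0),
    "highR-lowEV": (0.9, 70.0),
    "highR-highEV": (0.9, 90.0),
}


def _default_params(model: str, context: str, experiment: str, load: str):
    if model == "difference":
        return _models.LinearModelParams(a=0.3, b=0.008)
    if model == "basic":
        # nonzero intercept keeps the basic model outside the sigma -> 0
        # degenerate subspace of the saturating models
        return _models.LinearModelParams(a=0.2, b=0.8)
    a_max, sigma = _CONTEXT_SATURATION[context]
    if model == "enhanced":
        return _models.SaturatingModelParams(a_max=a_max, sigma=sigma)
    beta = 5.0 if experiment == "dual" else 25.0
    if load == "high":
        beta += 15.0
    return _models.SaturatingModelParams(a_max=a_max, sigma=sigma, beta=beta)


def default_ground_truth(
    generating_model: str = "full",
    seed: int = 0,
    uniform_saturation: tuple[float, float] | None = None,
    **overrides,
) -> GroundTruth:
    """Ground truth at the default study conditions.

    Parameters are laid out for every (context, experiment, load) cell;
    with the full model, baseline pooled activity beta is higher under
    memory demand (single presentation, high secondary load).

    ``uniform_saturation`` replaces the context-dependent (A_max, sigma)
    with one shared pair, e.g. for model-recovery studies where the fitted
    models also assume context-shared parameters.
    """
    params = {}
    for g in make_gamble_set():
        for experiment in ("dual", "single"):
            for load in ("none", "low", "high"):
                p = _default_params(generating_model, g.label, experiment, load)
                if uniform_saturation is not None and isinstance(
                    p, _models.SaturatingModelParams
                ):
                    p = _models.SaturatingModelParams(
                        a_max=uniform_saturation[0],
                        sigma=uniform_saturation[1],
                        beta=p.beta,
                    )
                params[(g.label, experiment, load)] = p
    return GroundTruth(
        generating_model=generating_model,
        params_by_condition=params,
        seed=seed,
        **overrides,
    )


def perturb_truth(truth: GroundTruth, rng: np.random.Generator) -> GroundTruth:
    """Per-participant parameter variability: multiplicative lognormal jitter
    with coefficient of variation ``truth.param_cv``, shared across conditions
    so that condition contrasts stay at their nominal values on the log scale."""
    if truth.param_cv <= 0:
        return truth
    sd = np.sqrt(np.log1p(truth.param_cv**2))
    factors = {name: float(rng.lognormal(-0.5 * sd**2, sd)) for name in ("p1", "p2", "p3")}
    new = {}
    for key, p in truth.params_by_condition.items():
        if isinstance(p, _models.LinearModelParams):
            new[key] = _models.LinearModelParams(a=p.a * factors["p1"], b=p.b * factors["p2"])
        else:
            beta = None if p.beta is None else p.beta * factors["p3"]
            new[key] = _models.SaturatingModelParams(
                a_max=p.a_max * factors["p1"], sigma=p.sigma * factors["p2"], beta=beta
            )
    return replace(truth, params_by_condition=new)


def trial_amplitude(
    truth: GroundTruth, condition: tuple[str, str, str], v_safe: float
) -> float:
    """Noise-free response amplitude for one trial under the generating model."""
    context, experiment, load = condition
    params = truth.params_for(context, experiment, load)
    return float(
        _models.predict(truth.generating_model, params, v_safe, CONTEXT_SD[context])
    )


def risky_choice_probability(truth: GroundTruth, context: str, v_safe) -> np.ndarray:
    """Analytic P(choose risky) under the logistic choice rule."""
    utility_gap = (
        CONTEXT_EV[context]
        - truth.risk_premium * CONTEXT_SD[context]
        - np.asarray(v_safe, float)
    )
    return 1.0 / (1.0 + np.exp(-utility_gap / truth.choice_temperature))


def simulate_behavior(
    design: SessionDesign, truth: GroundTruth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate choices and response times for every trial of a session.

    Choices follow a logistic in (EV_risky - risk_premium * SD - V_safe);
    RT follows a base plus a quadratic choice-difficulty term, truncated at
    the 5 s response window, with a small miss probability.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    rows = []
    for block in design.blocks:
        for t in block.trials:
            ctx = t.gamble.label
            p = float(risky_choice_probability(truth, ctx, t.safe_value))
            missed = bool(rng.uniform() < truth.miss_prob)
            if missed:
                chose, rt = None, None
            else:
                chose = bool(rng.uniform() < p)
                difficulty = (1.0 - abs(2.0 * p - 1.0)) ** 2
                rt = (
                    truth.rt_base_s
                    + truth.rt_difficulty_gain * difficulty
                    + abs(rng.normal(0.0, truth.rt_noise_sd))
                )
                rt = min(rt, 5.0)
            rows.append(
                dict(
                    block=t.block_index,
                    trial=t.trial_index,
                    context=ctx,
                    risk_level=t.gamble.risk_level,
                    ev_level=t.gamble.ev_level,
                    load=block.load,
                    experiment=design.experiment,
                    safe_value=t.safe_value,
                    p_risky=p,
                    chose_risky=chose,
                    rt_s=rt,
                    missed=missed,
                )
            )
    return pd.DataFrame(rows)


@dataclass
class HemoRecording:
    """Channel x sample hemoglobin time series with events."""

    o2hb: np.ndarray
    hhb: np.ndarray
    fs_hz: float
    events: pd.DataFrame
    channel_names: list[str] = field(default_factory=list)
    true_hrf_peak_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.o2hb = np.asarray(self.o2hb, float)
        self.hhb = np.asarray(self.hhb, float)
        if self.o2hb.shape != self.hhb.shape:
            raise ValueError("o2hb and hhb must have the same shape")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not self.channel_names:
            self.channel_names = [f"CH{i + 1:02d}" for i in range(self.o2hb.shape[0])]

    @property
    def channel_count(self) -> int:
        return self.o2hb.shape[0]

    @property
    def n_samples(self) -> int:
        return self.o2hb.shape[1]


def simulate_recording(
    design: SessionDesign,
    behavior: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    n_channels: int = DEFAULT_N_CHANNELS,
    fs_hz: float = DEFAULT_FS_HZ,
) -> HemoRecording:
    """Forward-model a multichannel recording for one session.

    Per trial an impulse of height ``trial_amplitude`` at choice onset is
    convolved with a per-channel double-gamma HRF (peak delay drawn from
    ``truth.hrf_peak_range_s``).  O2Hb carries +4/3 and HHb -1/3 of the
    response so their sum is the modeled total-hemoglobin change.  Slow
    sinusoidal drift, white noise and (optionally) brief motion spikes are
    added per chromophore, plus a blockwise baseline offset proportional to
    the condition's background activity A_max * beta / sigma.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    events = design.events_table()
    duration_s = float(events["onset"].iloc[-1]) + 30.0
    n = int(np.ceil(duration_s * fs_hz))
    missed = behavior["missed"].to_numpy() if "missed" in behavior else np.zeros(len(events), bool)
    events = events.assign(missed=missed)  # carried so the GLM can exclude them

    impulses = np.zeros(n)
    amplitudes = np.zeros(len(events))
    for i, row in enumerate(events.itertuples()):
        if missed[i]:
            continue
        condition = (row.context, row.presentation, row.load)
        amp = trial_amplitude(truth, condition, row.safe_value)
        amplitudes[i] = amp
        impulses[int(round(row.onset * fs_hz))] += amp

    baseline = np.zeros(n)
    if truth.generating_model == "full":
        for block in design.blocks:
            ctx = block.gamble.label
            p = truth.params_for(ctx, design.experiment, block.load)
            bg = _models.background_activity(p)
            start = int(round(block.trials[0].onset_s * fs_hz))
            end = (
                int(round((block.trials[-1].onset_s + block.trials[-1].iti_s) * fs_hz))
                if block is not design.blocks[-1]
                else n
            )
            baseline[start:end] = truth.background_gain * bg

    peaks = rng.uniform(*truth.hrf_peak_range_s, size=n_channels)
    o2hb = np.empty((n_channels, n))
    hhb = np.empty((n_channels, n))
    t = np.arange(n) / fs_hz
    for c in range(n_channels):
        kernel = hrf_kernel(fs_hz, peaks[c])
        signal = fftconvolve(impulses, kernel)[:n] + baseline
        chans = []
        # O2Hb rises, HHb falls; fractions sum to 1 so tHb = o2hb + hhb
        for frac in (4.0 / 3.0, -1.0 / 3.0):
            drift = 0.0
            if truth.drift_amplitude > 0:
                period = rng.uniform(*truth.drift_period_range_s)
                phase = rng.uniform(0, 2 * np.pi)
                drift = truth.drift_amplitude * np.sin(2 * np.pi * t / period + phase)
            noise = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else 0.0
            chans.append(frac * signal + drift + noise)
        if truth.motion_spike_rate_per_min > 0:
            n_spikes = rng.poisson(truth.motion_spike_rate_per_min * duration_s / 60.0)
            for _ in range(n_spikes):
                s0 = rng.integers(0, n - int(fs_hz))
                width = int(round(0.5 * fs_hz))
                spike = rng.choice([-1.0, 1.0]) * 20.0 * max(truth.noise_sd, 0.05)
                for ch in chans:
                    ch[s0 : s0 + width] += spike
        o2hb[c], hhb[c] = chans
    return HemoRecording(
        o2hb=o2hb, hhb=hhb, fs_hz=fs_hz, events=events, true_hrf_peak_s=peaks
    )


def simulate_cohort_amplitudes(
    n_participants: int,
    truth: GroundTruth,
    experiment: str = "dual",
    load: str = "none",
    n_levels: int = 10,
    seed: int | np.random.Generator = 0,
    return_truth: bool = False,
):
    """Simulate per-level response amplitudes for a cohort directly at the
    beta-series stage (bypassing the hemodynamic forward model).

    Each participant gets jittered parameters (``truth.param_cv``) and, per
    context, ``n_levels`` evenly spaced safe values with iid Gaussian noise
    of SD ``truth.beta_noise_sd`` on the amplitudes.  This is the input
    scale of the model-comparison and group-level analyses.  With
    ``return_truth`` a second table holds each participant's true
    per-condition parameters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for p_idx in range(n_participants):
        p_truth = perturb_truth(truth, rng)
        for g in make_gamble_set():
            vs = np.linspace(g.low_outcome, g.high_outcome, n_levels)
            vr = gamble_context_value(g)
            clean = np.array(
                [trial_amplitude(p_truth, (g.label, experiment, load), v) for v in vs]
            )
            noisy = clean + rng.normal(0.0, truth.beta_noise_sd, size=n_levels)
            for v, a in zip(vs, noisy):
                rows.append(
                    dict(
                        participant=p_idx,
                        experiment=experiment,
                        load=load,
                        context=g.label,
                        risk_level=g.risk_level,
                        ev_level=g.ev_level,
                        v_safe=float(v),
                        v_risky=float(vr),
                        amplitude=float(a),
                    )
                )
            if return_truth:
                p = p_truth.params_for(g.label, experiment, load)
                rec = dict(participant=p_idx, experiment=experiment, load=load,
                           context=g.label)
                if isinstance(p, _models.LinearModelParams):
                    rec.update(a=p.a, b=p.b)
                else:
                    rec.update(a_max=p.a_max, sigma=p.sigma, beta=p.beta)
                truth_rows.append(rec)
    table = pd.DataFrame(rows)
    if return_truth:
        return table, pd.DataFrame(truth_rows)
    return table


# ---------------------------------------------------------------------------
# Serialization: SNIRF-style HDF5 (.h5/.snirf) or TSV + JSON sidecar


def write_recording(rec: HemoRecording, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".snirf", ".hdf5"):
        with h5py.File(path, "w") as f:
            nirs = f.create_group("nirs")
            nirs.create_dataset("o2hb", data=rec.o2hb)
            nirs.create_dataset("hhb", data=rec.hhb)
            nirs.attrs["fs_hz"] = rec.fs_hz
            nirs.attrs["channel_names"] = [n.encode() for n in rec.channel_names]
            nirs.create_dataset("events_tsv", data=rec.events.to_csv(sep="\t", index=False))
            if rec.true_hrf_peak_s is not None:
                nirs.create_dataset("true_hrf_peak_s", data=rec.true_hrf_peak_s)
    else:
        base = path.with_suffix("")
        for name, mat in (("o2hb", rec.o2hb), ("hhb", rec.hhb)):
            pd.DataFrame(mat.T, columns=rec.channel_names).to_csv(
                f"{base}_{name}.tsv", sep="\t", index=False
            )
        rec.events.to_csv(f"{base}_events.tsv", sep="\t", index=False)
        meta = {"fs_hz": rec.fs_hz, "channel_names": rec.channel_names}
        if rec.true_hrf_peak_s is not None:
            meta["true_hrf_peak_s"] = list(map(float, rec.true_hrf_peak_s))
        Path(f"{base}.json").write_text(json.dumps(meta, indent=2))


def read_recording(path: str | Path) -> HemoRecording:
    path = Path(path)
    if path.suffix in (".h5", ".snirf", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "nirs" not in f:
                raise ValueError(f"{path}: missing group 'nirs'")
            nirs = f["nirs"]
            for ds in ("o2hb", "hhb", "events_tsv"):
                if ds not in nirs:
                    raise ValueError(f"{path}: missing dataset 'nirs/{ds}'")
            if "fs_hz" not in nirs.attrs:
                raise ValueError(f"{path}: missing required field 'fs_hz'")
            import io

            events = pd.read_csv(io.StringIO(nirs["events_tsv"][()].decode()), sep="\t")
            peaks = (
                np.asarray(nirs["true_hrf_peak_s"]) if "true_hrf_peak_s" in nirs else None
            )
            return HemoRecording(
                o2hb=np.asarray(nirs["o2hb"]),
                hhb=np.asarray(nirs["hhb"]),
                fs_hz=float(nirs.attrs["fs_hz"]),
                events=events,
                channel_names=[
                    n.decode() if isinstance(n, bytes) else str(n)
                    for n in nirs.attrs["channel_names"]
                ],
                true_hrf_peak_s=peaks,
            )
    base = path.with_suffix("")
    meta_path = Path(f"{base}.json")
    if not meta_path.exists():
        raise ValueError(f"{path}: missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if "fs_hz" not in meta:
        raise ValueError(f"{meta_path}: missing required field 'fs_hz'")
    o2hb = pd.read_csv(f"{base}_o2hb.tsv", sep="\t").to_numpy().T
    hhb = pd.read_csv(f"{base}_hhb.tsv", sep="\t").to_numpy().T
    events = pd.read_csv(f"{base}_events.tsv", sep="\t")
    peaks = np.asarray(meta["true_hrf_peak_s"]) if "true_hrf_peak_s" in meta else None
    return HemoRecording(
        o2hb=o2hb,
        hhb=hhb,
        fs_hz=float(meta["fs_hz"]),
        events=events,
        channel_names=list(meta.get("channel_names", [])),
        true_hrf_peak_s=peaks,
    )
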