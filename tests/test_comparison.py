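import numpy as np
import pandas as pd
import pytest

import valnorm as vn
from valnorm.comparison import (
    correlation_summary,
    delta_aic,
    fit_window_course,
    loo_cv,
    previous_trial_control,
)
from valnorm.models import fit_model, predict_fit
from valnorm.preprocessing import compute_thb, detrend, make_window_bank, sliding_glm


def test_delta_aic_identity_and_antisymmetry():
    bank = make_window_bank()
    rng = np.random.default_rng(3)
    a = rng.normal(size=(4, 40))
    b = rng.normal(size=(4, 40))
    zero = delta_aic(a, a, bank)
    np.testing.assert_array_equal(zero.values, np.zeros(40))
    fwd = delta_aic(a, b, bank, ("m1", "m2"))
    rev = delta_aic(b, a, bank, ("m2", "m1"))
    np.testing.assert_allclose(fwd.values, -rev.values)
    with pytest.raises(ValueError):
        delta_aic(a[:, :10], b[:, :10], bank)


def test_delta_aic_course_favors_generator_and_peaks_at_hrf(study1_session):
    """Recording simulated from the full normalization model: the windowed
    difference-vs-full AIC course favors the full model and is largest near
    the response peak."""
    truth = vn.default_ground_truth(
        "full", seed=13, noise_sd=0.1, drift_amplitude=0.1, param_cv=0.0,
        miss_prob=0.0, hrf_peak_range_s=(5.5, 5.5),
    )
    session = vn.generate_session(1, "single", seed=13)
    beh = vn.simulate_behavior(session, truth)
    rec = vn.simulate_recording(session, beh, truth, n_channels=2)
    bs = sliding_glm(detrend(compute_thb(rec), rec.fs_hz), rec.events, rec.fs_hz)
    aic_diff, _ = fit_window_course(bs, "difference")
    aic_full, _ = fit_window_course(bs, "full")
    course = delta_aic(aic_diff, aic_full, bs.bank, ("difference", "full"))
    centers = course.window_starts_s + bs.bank.length_s / 2
    peak_w = int(np.argmax(course.values))
    assert course.values[peak_w] > 0  # favors the full model
    assert abs(centers[peak_w] - 5.5) <= 1.5  # near the true HRF peak
    # advantage larger around the response peak than on the rising edge
    near = course.values[(centers >= 4.0) & (centers <= 7.0)]
    early = course.values[centers < 2.5]
    assert near.mean() > 0
    assert near.mean() > early.mean()


def test_loo_cv_perfect_generalization_and_degenerate_data():
    vs = np.tile(np.linspace(10, 50, 9), 2)
    vr = np.full(18, 20.0)
    rows = []
    for p in range(4):
        amp = vn.predict_full(vn.SaturatingModelParams(1.0, 30.0, 10.0), vs, vr)
        rows.append(pd.DataFrame(dict(participant=p, v_safe=vs, v_risky=vr, amplitude=amp)))
    table = pd.concat(rows, ignore_index=True)
    cv = loo_cv("full", table)
    assert cv.mean_rmse == pytest.approx(0.0, abs=1e-6)
    assert len(cv.rmse_per_participant) == 4
    # constant amplitudes: every model collapses to its intercept-like fit
    const = table.assign(amplitude=0.5)
    rmses = {m: loo_cv(m, const).mean_rmse for m in ("difference", "basic", "full")}
    vals = list(rmses.values())
    assert max(vals) - min(vals) < 1e-3
    with pytest.raises(ValueError):
        loo_cv("full", table[table["participant"] == 0])


def test_correlation_summary_perfect_and_degenerate_units():
    rng = np.random.default_rng(8)
    rows = []
    for exp in ("dual", "single"):
        for p in range(6):
            obs = rng.normal(size=12)
            rows.append(
                pd.DataFrame(
                    dict(
                        participant=f"{exp}{p}", experiment=exp,
                        context="lowR-lowEV", amplitude=obs, prediction=obs,
                    )
                )
            )
    # one degenerate unit: constant predictions
    rows.append(
        pd.DataFrame(
            dict(participant="bad", experiment="dual", context="lowR-lowEV",
                 amplitude=rng.normal(size=12), prediction=np.ones(12))
        )
    )
    summary = correlation_summary("full", pd.concat(rows, ignore_index=True))
    for exp in ("dual", "single"):
        np.testing.assert_allclose(summary.r_by_experiment[exp], 1.0)
    assert summary.n_excluded == 1
    assert len(summary.r_by_experiment["dual"]) == 6  # bad unit dropped


def test_correlation_kde_normalized_and_ks_form():
    rng = np.random.default_rng(9)
    rows = []
    for exp, shift in (("dual", 0.3), ("single", -0.3)):
        for p in range(15):
            x = rng.normal(size=20)
            y = shift * x + rng.normal(size=20)
            rows.append(pd.DataFrame(dict(
                participant=f"{exp}{p}", experiment=exp, context="c",
                amplitude=y, prediction=x,
            )))
    summary = correlation_summary("basic", pd.concat(rows, ignore_index=True))
    for dens in summary.kde_by_experiment.values():
        assert np.trapezoid(dens, summary.kde_grid) == pytest.approx(1.0, abs=1e-3)
    assert 0 <= summary.ks_statistic <= 1
    assert summary.ks_p < 0.05  # opposite-sign couplings separate cleanly


def _trial_table(rng, carryover=0.0, n_participants=6):
    """Trial-ordered amplitudes with an optional additive previous-context
    effect.  The baseline signal is centered within context so that, absent
    carryover, the amplitudes are genuinely independent of the previous
    trial's condition."""
    ctx_effect = {"lowR-lowEV": 0.0, "lowR-highEV": 1.0, "highR-lowEV": 2.0,
                  "highR-highEV": 3.0}
    rows = []
    for p in range(n_participants):
        session = vn.generate_session(1, "dual", seed=100 + p)
        ev = session.events_table()
        prev_ctx = ev["context"].shift(1)
        centered = ev["safe_value"] - ev.groupby("context")["safe_value"].transform("mean")
        amp = 0.5 + 0.01 * centered + rng.normal(0, 0.05, len(ev))
        carry = prev_ctx.map(ctx_effect).fillna(0.0) * carryover
        rows.append(pd.DataFrame(dict(
            participant=p, block=ev["block"], trial=ev["trial"],
            context=ev["context"], safe_value=ev["safe_value"],
            amplitude=amp + carry,
        )))
    return pd.concat(rows, ignore_index=True)


def test_previous_trial_control_is_noop_without_carryover():
    """Without carryover the only variance the adjustment can remove is the
    chance fit of the previous-trial covariates, so adjusted values track
    the originals closely (within-context slopes untouched)."""
    rng = np.random.default_rng(11)
    table = _trial_table(rng, carryover=0.0)
    adj = previous_trial_control(table)
    a = adj.loc[adj["adjusted"]]
    sd = table["amplitude"].std()
    assert np.abs(a["amplitude_adj"] - a["amplitude"]).mean() < 0.5 * sd
    assert np.corrcoef(a["amplitude_adj"], a["amplitude"])[0, 1] > 0.85
    # within-context slopes against safe value are essentially unchanged
    for (_, _), sub in a.groupby(["participant", "context"]):
        s0 = np.polyfit(sub["safe_value"], sub["amplitude"], 1)[0]
        s1 = np.polyfit(sub["safe_value"], sub["amplitude_adj"], 1)[0]
        assert s1 == pytest.approx(s0, abs=5e-3)
    # first trial of each block is never adjusted
    assert not adj.loc[adj["trial"] == 0, "adjusted"].any()


def test_previous_trial_control_removes_injected_carryover():
    rng = np.random.default_rng(12)
    table = _trial_table(rng, carryover=0.5)
    adj = previous_trial_control(table)
    used = adj[adj["adjusted"]]
    prev_ctx = []
    for _, sub in adj.groupby("participant"):
        sub = sub.sort_values(["block", "trial"])
        prev_ctx.append(sub["context"].shift(1))
    adj = adj.assign(prev_context=pd.concat(prev_ctx))
    used = adj[adj["adjusted"]]

    def eta_sq(values, groups):
        grand = values.mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for _, g in values.groupby(groups))
        ss_t = ((values - grand) ** 2).sum()
        return ss_b / ss_t

    before = eta_sq(used["amplitude"], used["prev_context"])
    after = eta_sq(used["amplitude_adj"], used["prev_context"])
    assert before > 0.3  # the injected carryover is large
    assert after < 0.02  # and the adjustment removes it
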