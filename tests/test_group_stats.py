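import numpy as np
import pandas as pd
import pytest
from scipy import stats

import valnorm as vn
from valnorm.group_stats import (
    compute_slopes,
    fit_participant_params,
    mixed_anova,
    parameter_analysis,
    posthoc_pairwise,
)
from valnorm.models import LinearModelParams, SaturatingModelParams
from valnorm.synthetic import GroundTruth
from valnorm.task_design import make_gamble_set


def test_slopes_recover_exact_line_and_flat_measure():
    vs = np.linspace(10, 50, 9)
    base = pd.DataFrame(
        dict(participant="p0", experiment="dual", load="none",
             context="lowR-lowEV", v_safe=vs)
    )
    lin = base.assign(amplitude=0.2 + 0.013 * vs)
    out = compute_slopes(lin, "thb")
    assert out["slope"].iloc[0] == pytest.approx(0.013)
    assert out["quad_a"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    flat = base.assign(amplitude=0.7)
    assert compute_slopes(flat, "thb")["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        compute_slopes(base.assign(v_safe=20.0, amplitude=1.0), "thb")


def test_slope_shift_invariance_and_scale_equivariance():
    rng = np.random.default_rng(1)
    vs = np.linspace(10, 50, 9)
    y = 0.3 + 0.01 * vs + rng.normal(0, 0.05, 9)
    df = pd.DataFrame(dict(participant="p", experiment="d", load="none",
                           context="c", v_safe=vs, amplitude=y))
    s0 = compute_slopes(df, "thb")["slope"].iloc[0]
    s_shift = compute_slopes(df.assign(amplitude=y + 5.0), "thb")["slope"].iloc[0]
    assert s_shift == pytest.approx(s0)
    s_scaled = compute_slopes(df.assign(v_safe=vs * 2.0), "thb")["slope"].iloc[0]
    assert s_scaled == pytest.approx(s0 / 2.0)


def test_choice_slopes_negative_in_every_context():
    """% risky choice falls with the safe value (analytic logistic sign);
    many pooled sessions make the per-level frequencies stable."""
    truth = vn.default_ground_truth("full", seed=0, miss_prob=0.0)
    behs = []
    for s in range(30):
        session = vn.generate_session(1, "dual", seed=500 + s)
        behs.append(vn.simulate_behavior(session, truth,
                                         np.random.default_rng(600 + s)))
    beh = pd.concat(behs, ignore_index=True).assign(participant="p0")
    slopes = compute_slopes(beh, "risky_choice_pct")
    assert len(slopes) == 4
    assert (slopes["slope"] < 0).all()


def test_rt_slopes_drop_missed_trials():
    truth = vn.default_ground_truth("full", seed=3, miss_prob=0.3)
    session = vn.generate_session(2, "dual", seed=3)
    beh = vn.simulate_behavior(session, truth).assign(participant="p0")
    slopes = compute_slopes(beh, "rt")
    assert np.isfinite(slopes["slope"]).all()


def test_mixed_anova_matches_pingouin():
    """Split-plot engine vs pingouin on a seeded one-within mixed design."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    rows = []
    for s in range(14):
        grp = "dual" if s < 8 else "single"
        base = rng.normal(0, 1)
        for b in range(4):
            rows.append(dict(subject=f"s{s:02d}", group=grp, B=f"b{b}",
                             y=base + 0.5 * b * (grp == "single") + rng.normal(0, 1)))
    df = pd.DataFrame(rows)
    mine = mixed_anova(df, "y", within="B", subject="subject", between="group",
                       posthoc=False)
    ref = pg.mixed_anova(data=df, dv="y", within="B", subject="subject",
                         between="group").set_index("Source")
    assert mine.effect("group")["F"] == pytest.approx(ref.loc["group", "F"])
    assert mine.effect("B")["F"] == pytest.approx(ref.loc["B", "F"])
    assert mine.effect("B * group")["F"] == pytest.approx(ref.loc["Interaction", "F"])
    assert mine.effect("B")["p"] == pytest.approx(ref.loc["B", "p_unc"])


def test_two_within_anova_matches_R_aov():
    """Frozen oracle: R `aov(y ~ group*B*C + Error(subject/(B*C)))` on the
    identical seeded dataset (both rng streams drawn in sequence)."""
    rng = np.random.default_rng(7)
    for s in range(14):  # advance the stream exactly as the 1-within set did
        rng.normal(0, 1)
        for b in range(4):
            rng.normal(0, 1)
    rows = []
    for s in range(10):
        grp = "g1" if s < 5 else "g2"
        base = rng.normal(0, 1)
        for b in range(3):
            for c in range(2):
                rows.append(dict(subject=f"s{s:02d}", group=grp, B=f"b{b}",
                                 C=f"c{c}",
                                 y=base + 0.4 * b + 0.6 * c * (grp == "g2")
                                 + 0.3 * b * c + rng.normal(0, 1)))
    res = mixed_anova(pd.DataFrame(rows), "y", within=["B", "C"],
                      subject="subject", between="group", posthoc=False)
    expected = {  # F and p values printed by R aov
        "group": (0.890507, 0.372962, 1, 8),
        "B": (10.532716, 0.001206, 2, 16),
        "B * group": (1.795839, 0.197873, 2, 16),
        "C": (10.452388, 0.012003, 1, 8),
        "C * group": (0.181876, 0.681010, 1, 8),
        "B * C": (0.036312, 0.964419, 2, 16),
        "B * C * group": (6.011306, 0.011295, 2, 16),
    }
    for source, (F, p, df1, df2) in expected.items():
        row = res.effect(source)
        assert row["F"] == pytest.approx(F, rel=1e-4), source
        assert row["p"] == pytest.approx(p, abs=1e-5), source
        assert (row["df1"], row["df2"]) == (df1, df2)


def test_within_F_equals_squared_paired_t():
    rng = np.random.default_rng(15)
    a = rng.normal(0, 1, 12)
    b = a + 0.4 + rng.normal(0, 1, 12)
    df = pd.DataFrame(
        dict(subject=np.repeat(np.arange(12), 2), B=np.tile(["x", "y"], 12),
             y=np.column_stack([a, b]).ravel())
    )
    res = mixed_anova(df, "y", within="B", subject="subject", posthoc=False)
    t, _ = stats.ttest_rel(a, b)
    assert res.effect("B")["F"] == pytest.approx(t**2)


def test_null_effects_give_zero_F():
    df = pd.DataFrame(
        dict(subject=np.repeat(np.arange(6), 3), B=np.tile(["x", "y", "z"], 6),
             grp=np.repeat(["g1", "g2"], 9),
             y=np.repeat(np.arange(6, dtype=float), 3))  # subject offsets only
    )
    res = mixed_anova(df, "y", within="B", subject="subject", between="grp",
                      posthoc=False)
    assert res.effect("B")["F"] == 0.0 and res.effect("B")["p"] == 1.0


def test_unbalanced_within_cells_rejected():
    df = pd.DataFrame(dict(subject=["a", "a", "b"], B=["x", "y", "x"],
                           y=[1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match="unbalanced"):
        mixed_anova(df, "y", within="B", subject="subject")


def test_posthoc_bonferroni_bookkeeping():
    rng = np.random.default_rng(17)
    rows = []
    for s in range(10):
        grp = "g1" if s < 5 else "g2"
        for b in ("x", "y", "z"):
            rows.append(dict(subject=s, grp=grp, B=b, y=rng.normal()))
    ph = posthoc_pairwise(pd.DataFrame(rows), "y", within="B",
                          subject="subject", between="grp")
    # 3 within pairs per group (2 groups) + 3 between comparisons
    assert len(ph) == 9
    assert (ph["m"] == 9).all()
    np.testing.assert_allclose(
        ph["p_bonf"], np.minimum(1.0, ph["p_raw"] * 9)
    )


def _uniform_truth(by_context_amax=None, beta_by_experiment=None, sigma=60.0):
    """Full-model truth with hand-chosen per-cell parameters."""
    params = {}
    for g in make_gamble_set():
        for experiment in ("dual", "single"):
            for load in ("none", "low", "high"):
                a_max = (by_context_amax or {}).get(g.label, 1.0)
                beta = (beta_by_experiment or {}).get(experiment, 10.0)
                params[(g.label, experiment, load)] = SaturatingModelParams(
                    a_max=a_max, sigma=sigma, beta=beta
                )
    return GroundTruth(generating_model="full", params_by_condition=params,
                       param_cv=0.08, beta_noise_sd=0.012)


def test_parameter_anova_detects_context_amax_only():
    """Ground truth varies A_max by context only (2:1): the context effect
    lands on a_max and not on beta."""
    truth = _uniform_truth(by_context_amax={
        "lowR-lowEV": 1.4, "lowR-highEV": 1.4, "highR-lowEV": 0.7,
        "highR-highEV": 0.7,
    }, sigma=40.0)
    tab = vn.simulate_cohort_amplitudes(16, truth, "dual", "none",
                                        n_levels=21, seed=21)
    params = fit_participant_params(tab, by=("participant", "context"))
    res = parameter_analysis(params, between=None)
    assert res["a_max"].effect("context")["p"] < 0.05
    assert res["beta"].effect("context")["p"] > 0.05


def test_parameter_anova_detects_experiment_beta_only():
    """Cohorts differing only in baseline pooled activity (5 vs 40 CHF):
    the experiment effect lands on beta and background, sparing a_max and
    sigma."""
    truth = _uniform_truth(beta_by_experiment={"dual": 5.0, "single": 40.0})
    rng = np.random.default_rng(33)
    dual = vn.simulate_cohort_amplitudes(12, truth, "dual", "none",
                                         n_levels=21, seed=rng)
    single = vn.simulate_cohort_amplitudes(12, truth, "single", "none",
                                           n_levels=21, seed=rng)
    single["participant"] += 100
    tab = pd.concat([dual, single], ignore_index=True)
    params = fit_participant_params(tab, by=("participant", "context"))
    res = parameter_analysis(params)
    assert res["beta"].effect("experiment")["p"] < 0.01
    assert res["background"].effect("experiment")["p"] < 0.05
    assert res["a_max"].effect("experiment")["p"] > 0.05
    assert res["sigma"].effect("experiment")["p"] > 0.05
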