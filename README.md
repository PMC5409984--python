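# valnorm

Adaptive value normalization analysis for fNIRS risky-choice experiments.

`valnorm` is a simulation and analysis pipeline for studying how prefrontal
hemodynamic responses adapt to the value context of a risky decision, and
how working-memory demand constrains that adaptation. It simulates the
behavioral task and multichannel near-infrared recordings from a known
ground truth, estimates trial-locked Δ[tHb] response amplitudes with a
sliding-window GLM, fits four competing models of value adaptation, and
runs the model-comparison and group-level statistics that test the
mechanism.

## The task and the models

Participants repeatedly choose between a safe payout `V_safe` (varying
trial to trial) and a 50/50 gamble whose outcome spread defines the *risk
context* `V_risky` (the SD of its two outcomes; four contexts: CHF 15/45,
40/80, 10/50, 30/90). In the **dual** presentation both options are shown;
in the **single** presentation the gamble must be held in working memory.
A secondary symbol-sequence task can add further memory **load**.

Four models of the pooled response amplitude `A` are compared:

| model | form | parameters |
|---|---|---|
| difference | `A = a + b (V_safe − V_risky)` | a, b |
| basic normalization | `A = a + b V_safe / (V_safe + V_risky)` | a, b |
| enhanced normalization | `A = A_max V_safe / (σ + V_safe + V_risky)` | A_max, σ |
| full normalization | `A = A_max (V_safe + β) / (σ + V_safe + V_risky)` | A_max, σ, β |

`A_max` is the maximum pooled activity, `σ` the semisaturation constant
(response slope), and `β` the baseline pooled activity. The ratio
`A_max·β/σ` summarizes the predicted **background activity** in the absence
of stimulation. The mechanistic claim the pipeline tests: memory demand
raises `β`, which raises background activity and flattens the normalized
value slopes.

## Worked example

```python
import valnorm as vn
from valnorm.preprocessing import compute_thb, detrend, sliding_glm, peak_average
from valnorm.group_stats import fit_participant_params

session = vn.generate_session(study=1, experiment="dual", seed=7)
truth = vn.default_ground_truth("full", seed=7, uniform_saturation=(1.0, 60.0))
behavior = vn.simulate_behavior(session, truth)
recording = vn.simulate_recording(session, behavior, truth)   # 16 ch @ 7.81 Hz

thb = detrend(compute_thb(recording), recording.fs_hz)
betas = sliding_glm(thb, recording.events, recording.fs_hz)   # 40 windows
amplitudes = peak_average(betas)                              # 4-7 s plateau
amplitudes = amplitudes.rename(columns={"safe_value": "v_safe"})
amplitudes["participant"] = "p1"
params = fit_participant_params(amplitudes, by=("participant",))
print(params[["a_max", "sigma", "beta", "background"]].round(3).to_string(index=False))
```

prints (one pooled full-model fit for this simulated participant):

```
 a_max  sigma  beta  background
 0.991 67.016 2.504       0.037
```

i.e. a maximum pooled activity of ≈0.99 amplitude units, a semisaturation
constant of ≈67 CHF, a baseline pooled activity of ≈2.5 CHF, and a
predicted background activity `A_max·β/σ` ≈ 0.04 — near the generating
values (A_max = 1, σ = 60, β = 5 before the ±10% participant-level
variability), estimated from a single 40-trial session.

The full pipeline — cohorts of participants in both presentation modes,
Δ-AIC time courses, leave-one-participant-out RMSE, correlation KDEs and
KS tests, slope and parameter ANOVAs with Bonferroni post hocs, figures —
runs from one config:

```bash
valnorm all --seed 11 --out results/demo
```

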