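# Methods

## The model and the mechanism under test

The pipeline centers on four accounts of how a pooled prefrontal
hemodynamic response amplitude `A` depends on a safe offer `V_safe` under a
risk context `V_risky` (the SD of the block's 50/50 gamble, in CHF):

1. difference: `A = a + b (V_safe − V_risky)`
2. basic normalization: `A = a + b V_safe / (V_safe + V_risky)`
3. enhanced normalization: `A = A_max V_safe / (σ + V_safe + V_risky)`
4. full normalization: `A = A_max (V_safe + β) / (σ + V_safe + V_risky)`

The full model's β is baseline pooled activity; `A_max·β/σ` is the
predicted background activity absent stimulation. The mechanistic question
is whether working-memory demand (remembering the gamble, or a secondary
symbol sequence) raises β, which both raises background activity and
flattens the slope of `A` against `V_safe`:
`∂A/∂V_safe = A_max (σ + V_risky − β)/(σ + V_safe + V_risky)²` is strictly
decreasing in β.

A caveat on context adaptation: the claim that this slope also decreases as
`V_risky` grows holds only in the σ-dominant regime —
`∂slope/∂V_risky ∝ V_safe + 2β − σ − V_risky` — so with small σ the
measured slope can *increase* with context risk. The property tests check
the adaptation claim where it provably holds (σ ≥ V_safe + 2β).

## Synthetic study conditions

The generator's defaults define the simulated studies:

- **Task.** Study 1: 8 blocks × 5 trials, two blocks per gamble, 10 safe
  levels per context split 5+5 over its blocks. Study 2: 4 blocks × 21
  trials, 21 safe levels, secondary load balanced low/high. Timing: 0.5 s
  fixation, 8 s context cue, 0.5 s blank, 5 s choice window, uniform
  10–12 s ITIs; Study 2 prepends a 2 s load-sequence display. Safe offers
  are an evenly spaced grid over the gamble's outcome range, shuffled, with
  the within-context mean constrained to one grid step of the gamble EV.
- **Response amplitudes.** Full normalization with context-dependent
  saturation — A_max 1.2 / σ 30–40 CHF in low-risk contexts, A_max 0.9 /
  σ 70–90 CHF in high-risk contexts, shared by both presentation modes —
  and β = 5 CHF (dual) vs 25 CHF (single), +15 CHF under high secondary
  load. With context-independent (A_max, σ) the measured slopes are nearly
  equal across contexts (the V_risky effect cancels against each context's
  shifted value range), so context-dependent saturation is what produces
  the steeper low-risk coding the analyses look for; the experiment/load
  difference is carried by β alone. The basic model's default intercept is
  nonzero (a = 0.2) because a = 0 lies in the σ→0 subspace that the
  saturating models reproduce exactly, which would make model selection
  ill-posed.
- **Behavior.** P(risky) is logistic in
  `EV_gamble − 0.3·SD_gamble − V_safe` with temperature 8 CHF; RT is
  0.8 s + 1.2 s·(1 − |2P − 1|)² plus half-normal noise (SD 0.15 s),
  truncated at the 5 s window; 1% of trials are missed and carry no
  response.
- **Recording.** 16 channels at 7.81 Hz. Per trial an impulse of the
  model amplitude at choice onset is convolved with a double-gamma HRF
  (unit-scale gamma peaking at a per-channel delay drawn from 5–6 s,
  undershoot at 16 s with ratio 1/6, kernel peak-normalized). O2Hb carries
  +4/3 and HHb −1/3 of the response so tHb = O2Hb + HHb reconstructs it
  with a negative-going HHb. Added per chromophore: sinusoidal drift
  (amplitude 0.2, period 180–600 s, random phase), white noise (SD 0.05),
  and optional 0.5 s motion spikes. A blockwise baseline offset of
  0.1 × A_max·β/σ embodies the background-activity level.
- **Beta-stage shortcut.** Cohort-level analyses can simulate amplitudes
  directly at the beta-series stage with iid noise SD 0.012 — calibrated
  once to the beta-estimate error the full recording chain produces at the
  default recording noise — plus 10% lognormal between-participant
  parameter variability (shared across conditions, preserving contrasts).

What the generator does **not** emulate: optical-density physics and the
Beer–Lambert conversion, physiological oscillations (cardiac, respiratory,
Mayer waves), short-channel superficial contamination, spatially correlated
channel noise, and any learning or sequential dependence in behavior.
Passing tests therefore show the *estimation and inference chain* is
correct under its assumed signal model, not that the chain is robust to
every artifact of real recordings.

## Preprocessing and beta estimation

- tHb = O2Hb + HHb is the analyzed signal.
- Detrending projects out a mean + linear + discrete-cosine drift basis up
  to 1/128 Hz (the cosine-set high-pass standard for hemodynamic GLMs; an
  IIR Butterworth at so low a relative cutoff is numerically ill-behaved).
- Motion flagging: samples where the 1 s moving SD of the derivative
  exceeds 5× its channel median are excluded from all regressions.
- The sliding-window GLM uses 40 windows of 2.5 s stepped by 0.18 s
  (spanning ~9.7 s; the window count is taken as the binding constant).
  One regressor per condition cell (safe level × context × load; per-trial
  mode behind a switch), built by convolving the cell's onset impulses with
  the HRF and evaluated at the window's samples — neighboring trials'
  overlapping responses (the undershoot spans the 15–17 s trial spacing)
  are therefore modeled, and an intercept makes estimates offset-invariant.
  The same drift basis is projected out of the regressors as out of the
  data; filtering only the data would bias betas by ~4–8% because blocked
  designs have genuine low-frequency content.
- The HRF peak delay is adapted per channel by scanning 3–8 s in 0.5 s
  steps and keeping the delay minimizing whole-series RSS; on noise-free
  data the chain then recovers injected amplitudes essentially exactly
  (the tests bound the error at 2%), and the chosen delay is within one
  grid step of the simulated one.
- Missed trials carry no regressor; cells with no usable trials report NaN.
- Slope analyses use betas averaged over the windows inside 4–7 s.

## Fitting, comparison, and group statistics

- Linear models are closed-form least squares; saturating models use
  bounded nonlinear least squares (trf) with a deterministic multi-start
  grid (A_max from the observed maximum; σ ∈ {0.1, 1, 10, 100}× median
  V_safe; β ∈ {0, median V_safe}). Bounds: σ ∈ [1e-6, 1e4], β ≥ 0,
  |A_max| ≤ 1e6. AIC = n·ln(RSS/n) + 2k (AICc behind a flag; RSS floored
  at 1e-300 so perfect fits stay finite). Leave-one-participant-out
  refits warm-start from the pooled estimate.
- Per-context three-parameter fits are weakly identified when β is large
  (σ̂ can run to a bound and the background ratio becomes heavy-tailed);
  group comparisons of background activity therefore hold on medians and
  on the ANOVA, and parameter-level analyses favor the 21-level design.
- Correlation summaries compute Pearson r per context and average within
  participant (pooling contexts lets context-level amplitude offsets
  dominate and reverses the presented-vs-remembered ordering); KDEs use a
  Gaussian kernel with Silverman bandwidth, renormalized on [−1, 1]; the
  two-sample KS test is exact when both groups have ≤ 25 participants.
- Group inference is a balanced split-plot repeated-measures ANOVA (one
  between factor, one or two within factors, each within effect tested
  against its interaction with subjects nested in groups), validated
  against pingouin (one within) and R `aov` (two within). Zero-variance
  strata report F = 0, p = 1 rather than 0/0. Post hocs are Bonferroni-
  corrected pairwise t tests with the multiplier equal to the number of
  comparisons performed. Greenhouse–Geisser correction is not applied.
- The previous-trial control residualizes amplitudes on previous-context
  indicators and previous safe value. In this blocked design the previous
  context equals the current context on all non-first trials, so the
  adjustment also absorbs between-context amplitude levels (within-context
  slopes are untouched); first trials of a block are returned unadjusted.

## Problem sizes

Cohort analyses run at 20 participants per presentation mode. Parameter
recovery uses 10 cohorts from the full model (context-uniform saturation
(1.0, 60), under memory load so β is identifiable); model selection uses
25 cohorts per generating model (100 total), scored by mean per-participant
AIC and LOO-RMSE; the acceptance script uses 5 and 8 cohorts respectively.
The mechanism cohort uses the 21-level grid — per-context fits on 10
levels are too ridge-prone for stable parameter ANOVAs. Null calibrations
run 200–250 replicates.

## Known limitations

- Off-grid HRF peak delays bias amplitudes multiplicatively by up to
  ~10% per channel; this scales Â_max but leaves σ̂, β̂ and all
  within-participant contrasts essentially intact.
- The pooled (context-shared) fit is misspecified under the
  context-dependent defaults; recovery studies therefore use
  context-uniform truths.
- The split-plot ANOVA assumes each subject contributes every within cell;
  unbalanced within designs are rejected, and non-converged fits trigger
  listwise participant removal (logged) in the parameter analysis.
- Enhanced-vs-full LOO-RMSE is a near-tie when the generator is the
  enhanced model (the full model nests it and one extra parameter costs
  almost nothing out of sample), so selection win rates are reported over
  all four generators jointly.
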