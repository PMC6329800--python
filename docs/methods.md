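# Methods

This note documents the models, statistical conventions, numerical choices
and known limitations of `fsrpe`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Task model

Each trial presents two stimuli that are featurewise complements: one of
each color, at opposite locations, moving in opposite directions. Only
color predicts reward, deterministically: the chosen stimulus is rewarded
iff its color is the block's rewarded color. The rewarded color alternates
between blocks without any cue. A block runs at least 30 and at most 100
trials and ends as soon as the running accuracy over the last 12 trials
reaches 0.90 (checked from trial 30 on). Event times (fixation, first and
second feature onset, dimming, outcome) are drawn uniformly from the task's
per-event ranges; which of color/motion appears first is counterbalanced at
random. Fixation breaks and other non-choice errors are not simulated —
the analyses they would be excluded from never see them.

**Ideal-observer learning criterion.** The learning trial of a block is
estimated with a binomial state-space smoother: the latent
probability-correct follows a reflected Gaussian random walk (step SD 0.05)
on a 199-point grid over (0, 1) with a uniform prior; outcomes are
Bernoulli; the posterior is obtained by forward–backward recursion. The
learning trial is the earliest trial whose lower 95% posterior bound
exceeds chance (0.5 for a binary choice) and stays above chance for the
rest of the block. Because smoothing conditions on future outcomes, the
criterion can anticipate an accuracy transition by a few trials; the exact
variant used in the original analyses is unpublished, so this construction is declared rather than asserted to match.

## Reinforcement-learning model family

State: six feature values `V[d, f]` (3 dimensions × 2 features),
initialized at the prior `V0 = 0.5`, and dimension weights `w` initialized
uniform. Per trial, with chosen features `f_d`:

- stimulus value `V_stim = Σ_d w_d · V[d, f_d]` (the F-S variant uses the
  color value alone; unweighted variants fix `w_d = 1/3`);
- choice: softmax in the value difference,
  `P(choose A) = 1 / (1 + exp(−β (V_A − V_B)))`;
- prediction error `RPE = R − V_stim`, `R ∈ {0, 1}`;
- chosen-feature update `V[d, f_d] ← V[d, f_d] + η g_d RPE` with
  `g_d = w_d` for the dimension-weighted variants and `g_d = 1` otherwise
  (color only for F-S), clipped to [0, 1] — a feature near a bound can
  otherwise overshoot when the stimulus value is pulled away by the other
  features;
- decay variants pull every nonchosen-stimulus feature toward the prior:
  `V ← ω V + (1 − ω) V0`;
- weighted variants update `w` toward each dimension's share of
  predictiveness `s_d = |V[d,0] − V[d,1]|`:
  `w_d ← (1 − ϕ) w_d + ϕ s_d / Σ s` (uniform target when all `s_d = 0`),
  then renormalize.

The exact update equations used in the original analyses are
unpublished; the forms above are standard in the
attention-weighted-RL literature and are used self-consistently for both
simulation and fitting, so all quantitative checks are self-consistency and
recovery checks. Some accounts label the weighting rate α; here it is ϕ
throughout. State never resets at block boundaries (reversals are uncued to
the learner) and always resets at session boundaries.

**Parameters.** η (learning rate), ϕ (dimension-weighting rate), ω (decay
retention) ∈ [0, 1]; β (inverse temperature) ∈ [0, 20]. Free parameters per
variant: F-NS/F-S (η, β); F-DW (+ϕ); F-Dec (+ω); F-DW-Dec (all four).
Published fitted values used as the reference generating set:
η = 0.22, β = 3.55, ϕ = 0.68, ω = 0.92 (second animal: 0.25 / 2.79 /
0.98 / 0.68).

**Fitting.** Negative log likelihood of the chosen stimulus over all choice
trials, probability floored at 1e−9. The trial loop is compiled with numba
and verified against a pure-Python reference implementation to 1e−12.
Optimization is multi-start (default 10 starts: the template values plus
uniform draws within bounds): each start runs at most 20 Nelder–Mead
iterations and hands off to bounded L-BFGS-B, and the winner receives a
final tight-tolerance polish. Ten starts are deliberate: the likelihood of
the dimension-weighted decay variants is shallow and locally wiggly in ϕ,
and with 4 starts the fits visibly under-converge (higher NLL, biased-low
ϕ). Cross-validation splits
*blocks* 80/20 (never trials, to avoid leakage through the sequential
state); the learner still traverses every trial in order, only the summed
likelihood is restricted. AIC = 2k + 2·NLL.

**Recovery under the study conditions.** Simulating 50 sessions × 9 blocks
(~14,700 trials) at the published parameter set and refitting recovers,
as medians over 10 replicates (seed 1): η 0.225, β 3.44, ϕ 0.672, ω 0.923 —
within 0.01 / 3% of the generating values (seeds 3 and 42 agree to ~0.01).
Single fits take ~9 s.

A note on the behavior this generates: the simulated agent reaches ~80%
accuracy with mean block length ~33 trials and learning trials within
~5–10 trials of a reversal — somewhat faster than the recorded animals
(asymptote ~75%, blocks ~45 trials, learning in ~17 trials), a consequence
of the declared update rules being more efficient than whatever exact
unpublished forms produced the published fits. One downstream consequence
is that positive RPEs on correct trials are compressed (mean ≈ 0.12,
SD ≈ 0.15 under the generating model), which matters for classifier power
(below).

## Synthetic spike trains

Spiking is inhomogeneous Poisson, piecewise-constant per trial: baseline
(default log-normal around 5 Hz) plus planted components active in
`[event + latency, event + latency + duration)`, rate floored at 0.
Regressors: reward indicator (outcome), RPE on correct trials (pRPE),
−RPE on error trials (nRPE: the regressor grows as the RPE becomes more
negative), |RPE| on all trials (uRPE/surprise); a feature condition
restricts a component to trials choosing that feature. A "transfer"
component models the attention-transfer signature: a color-onset response
on trial n+1 proportional to `1 − |RPE_n|`, active only after
preferred-color choices. What this generator does *not* emulate: correlated
noise across neurons or time, bursting and refractoriness, drift,
non-Poisson count statistics, and any mismatch between the fitted model's
RPEs and the "true" RPEs — so passing tests validate the analysis chain,
not the biological claims.

Waveforms are biphasic templates (negative trough, positive peak) sampled
at 40 kHz (25 µs step, 48 samples — long enough to hold the post-peak
repolarization landmark), with class-dependent trough-to-peak gap
(narrow 0.20 ms, broad 0.50 ms) plus sample noise and a random amplitude
scale.

## Encoding classification

Rates are spike counts in 200 ms windows across the outcome epoch −0.5 to
+1.5 s, stepped by 50 ms by default (see below). A window is indexed by its
center; "post-outcome" windows are those starting at ≥0. Conventions:

- pRPE: Spearman correlation of rate with RPE on correct trials; encoding
  means positive correlation.
- nRPE: Spearman correlation on error trials; encoding means rate rising
  as the RPE grows more negative (negative correlation with the signed
  RPE). The opposite convention (rate falling with more negative RPE) is
  available behind a flag, default off.
- uRPE: Spearman *partial* correlation of rate with |RPE| over all trials,
  partialing out the outcome sign (±1 covariate); encoding means positive
  partial correlation. With a constant covariate this degrades to the
  plain rank correlation, with a note.

p-values use the t approximation; constant rate columns give r = 0, p = 1.
A neuron encodes a signal when ≥4 consecutive post-outcome bins are
significant (p < 0.05, required sign) and no run of >2 same-sign
significant bins occurs pre-outcome; the reported window is the first
qualifying run. No multiple-comparison correction is applied across bins —
the consecutive-bin rule is the control, as in the original analyses.
Inclusion requires a mean feedback-epoch (0–1.5 s) rate ≥0.5 Hz and ≥40
choice trials in blocks learned to criterion; unlearned blocks are
discarded. Every correlation analysis requires ≥15 trials.

Feature-specific encoding (per sign × dimension): trials are split by the
chosen feature of that dimension; the two maps must differ by
`Z = (z₁ − z₂)/√(1/(N₁−3) + 1/(N₂−3))` with |Z| > 1.96 in ≥4 consecutive
post-outcome bins, and at least one split must carry a qualifying encoding
run overlapping the Z-run by ≥1 bin (the weakest reading of the joint
requirement). The pre-outcome exclusion applies to the encoding maps only,
not to the Z-run. The preferred feature is the qualifying split with the
larger peak |R|. For comparison analyses a neuron counts as nonspecific
only if it is not also feature-specific for that signal — the two
populations are disjoint by construction.

The outcome test is separate: mean rate in 0.1–0.7 s regressed on the
reward indicator (the prevalence flag), plus a per-bin regression map under
the same run rule (the latency window). The two can disagree: a clear
outcome responder can lack a clean run.

**Step size: 50 ms default, 25 ms optional.** Published descriptions of the original
analysis differ between a 25 ms and a 50 ms step. Both are supported; the default is
50 ms because of a calibration fact measured on 300–500 pure-noise neurons
(per-bin rejection exactly 0.050 two-sided / 0.025 one-sided in both
configurations): windows stepped by 25 ms share 87.5% of their spikes, so a
single noise excursion of the correlation map spans many bins and the
4-consecutive-bin rule loses its filtering power — whole-neuron false-flag
rates reach 6–10% per signal (16% for any signal). At the 50 ms step the
same rule is conservative: 0.7–1.7% per signal, 2.7% for any signal, 0.7%
per feature-specific test. The 25 ms step remains appropriate where bin
*timing* resolution matters more than whole-neuron calibration (the
latency analyses use it).

**Power.** Detectability of a planted signal is governed by
`gain × SD(regressor) / √(baseline/window)`. Under the study conditions
(5 Hz baseline, pRPE regressor SD ≈ 0.15, ~150 trials per color split), a
gain of 3 Hz per unit RPE yields per-bin correlations ≈ 0.08 — undetectable
by any 4-bin-run criterion. The calibration tests therefore plant
gain 20 Hz/unit-RPE, duration 0.6 s — a modulation depth comparable to the
strongly modulated example neurons such data sets showcase (roughly a
tripling of rate across the observed RPE range). Measured: sensitivity
0.95 for color-specific pRPE at ≥60 trials per split, preferred color
correct in 100% of detections, and sensitivity monotone in gain.

## Population statistics

Latency distributions pool, per neuron, the bin centers of the first
qualifying run (the latency-test convention; pooling all significant bins
is available for histogram-style summaries). The 25%-crossing time is the
earliest pooled bin time at which the normalized cumulative sum reaches
0.25. Group comparisons: two-sample Kolmogorov–Smirnov tests on the pooled
bin times with Bonferroni–Holm correction, plus companion rank-sum tests.
Crossing-time differences are tested by permuting neurons (not bins)
between groups, n = 500 by default, with the (b+1)/(n+1) p-value estimator.
Measured calibration: rejection rate 0.05 ± 0.02 under the null; a planted
100 ms onset offset is recovered in the crossing-time difference within one
25 ms bin and is KS-significant.

Prevalence of feature-specific encoding across dimensions is tested against
an exchangeable-dimension null: dimension labels of the feature-specific
neurons are redrawn uniformly (n = 10,000) and a dimension is flagged when
its observed proportion exceeds the null's 95th percentile. The published
one-sided-bootstrap construction is compressed beyond reconstruction; this
operationalization of "more prevalent than expected under the population of
all feature-specific RPEs" is a declared substitute. The color-tuning index
`I_col = (P_col − (P_loc+P_mot)/2)/(P_col+P_loc+P_mot)` ranges over
[−0.5, 1], 0 under a uniform split; its per-area significance uses
area-label shuffles (n = 10,000, two-sided 95% interval).

## Attention transfer

Per color-specific neuron: the 25% of eligible trials with the largest and
smallest |RPE| (eligibility follows the neuron's signal type: correct
trials for pRPE, error trials for nRPE, all choice trials for uRPE; ties
broken by trial order), split by whether trial n chose the preferred color.
On the following trials (consecutive within-block pairs only) the
normalized color-onset rate change Δ = (post − pre)/(post + pre) is
computed over pre = [−0.5, 0) and post = [0, 0.5) s (configurable; the
original windows are unpublished), defined 0 when both rates are 0 —
Δ is scale-invariant and bounded in [−1, 1], matching the published
normalization's stated range. Across neurons, paired t tests compare
low- vs high-RPE Δ within the preferred and nonpreferred conditions, with
Hedges' g (small-sample corrected); a constant nonzero paired difference
has degenerate variance and is reported not evaluable.

## Cell typing

Cortical features: trough-to-peak duration and time from the peak to 25% of
peak amplitude (configurable fraction). Striatal features: trough width at
half amplitude and the initial slope of valley decay over the first 0.1 ms
after the trough, normalized by trough depth. Landmarks are computed on a
10× linearly interpolated waveform; monophasic shapes fail extraction and
are labeled unidentified. The two standardized features are projected on
PC1 and split at the kernel-density antimode between the two largest modes;
a unimodal density falls back to the median with a low-confidence flag.
Labels are oriented so "narrow" has the shorter duration. Enrichment of
encoding in a class uses the 2×2 chi-square (no continuity correction, so
it equals the textbook formula) with the signed phi coefficient.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeds; pipeline
  stages derive their seeds from the master seed and stage name (SHA-256,
  reduced below 2³¹). Same seed ⇒ byte-identical outputs.
- Spearman maps are computed as Pearson on average ranks, vectorized across
  bins, and verified against scipy/pingouin and brute-force
  rank-then-Pearson(-residual) oracles to 1e−10.
- The Fisher z difference test is calibrated in the classical setting it
  assumes (Pearson correlations of bivariate-normal samples): empirical
  two-sided type-I error 0.0527 at |Z| > 1.96 over 10,000 replicates
  (N = 100 per group, shared ρ = 0.3). The classifier applies the same
  contrast to Spearman coefficients, whose z-transform is slightly
  over-dispersed (variance ≈ 1.06/(N−3)); the consecutive-bin rule absorbs
  the difference.
- Problem sizes used by the standard checks: 50 sessions × 9 blocks for
  fitting experiments; one 12-block session (~390 trials, matching the
  recorded sessions' ~8.7 blocks × 45 trials) for neural analyses; 500
  noise neurons for calibration; 40–60 planted neurons per power check.

## Known limitations

- All neural-analysis guarantees are under the Poisson generator above;
  real recordings' overdispersion and slow drifts would inflate the
  false-flag rates of any consecutive-bin criterion.
- The ideal-observer variant, the exact RL update forms, the transfer
  windows and normalization, and the prevalence-bootstrap construction are
  declared stand-ins for unpublished original definitions.
- The nine-variable outcome-period regression analysis of the original study
  is out of scope, as are eye movements, spike sorting, and anatomy.
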