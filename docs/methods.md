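# Methods

Statistical models, numerical choices, and default parameters behind
`tapsurv`. Notation: a *game* is one play of a trail-making assessment
(Jewels A: numbered targets; Jewels B: alternating number/letter
targets) at difficulty *level* L, the number of jewels on screen.

## 1. Survival encoding

A level-L game is encoded as L at-risk units observed from t = 0. The
k-th correct tap at within-game time t_k is an event for one unit at
t_k. When an assessment of level L_a is compared with a reference of
level L_r with L_a < L_r, the assessment contributes L_r − L_a
pseudo-jewels censored at its completion time (administrative censoring:
the shorter game simply never presented those jewels), and symmetrically
for the reference. Incomplete games can optionally be included with
their untapped jewels censored at the last observed tap.

The per-game Kaplan–Meier curve is the product-limit estimate on this
encoding; with no censoring it steps down by exactly 1/L at each
distinct tap time (k/L at a k-fold tie), reaching 0 at the final tap.

## 2. Reference path

For each (assessment type, level) the reference path's k-th tap time is
the arithmetic mean of the k-th cumulative tap times over all completed
control games of that type and level. The result is strictly increasing
by construction (means of sorted sequences). A leave-one-out mode
rebuilds the references excluding the scored subject's own games, so
control subjects are not scored against themselves; a level present in
only one control's games then loses its reference, and affected games
are reported as problems rather than silently dropped.

## 3. Cox scoring

Each assessment/reference pair is fit with a Cox proportional-hazards
model with one binary covariate x (1 = assessment, 0 = reference),
Breslow handling of tied event times. With d0, d1 events and n0, n1
at-risk units per distinct event time, the log partial likelihood, its
score, and its information have closed forms in the scalar coefficient
β, so the fit is a damped Newton iteration (step capped at 2.0,
tolerance 1e-10, ≤ 200 iterations) rather than a generic optimizer.

*Monotone likelihood.* When all assessment events fall after (or
before) all reference events, the partial likelihood is maximized at
β = ∓∞. If the unpenalized iteration escapes |β| > 10, the fit restarts
with a ridge penalty λβ², λ = 0.1, giving a finite, shrunken estimate;
such estimates are flagged `penalized` and their standard error uses the
penalized information (information + 2λ). The standard error otherwise
comes from the observed information at the maximum.

Two independent checks guard the solver: a brute-force grid maximization
of the same Breslow partial likelihood (4001-point grid over ±10
followed by interval refinement), and `lifelines`' `CoxPHFitter` on
tie-free datasets, where Efron and Breslow weights coincide.

The hazard ratio exp(β) reads as speed relative to the reference: 1 at
reference speed, < 1 slower. Uniformly rescaling an assessment's tap
times by c > 1 strictly decreases its hazard ratio whenever the scaling
changes the interleaving of assessment and reference events (the partial
likelihood depends on event ranks, not raw times).

## 4. Level and mistake adjustment

Per-game log hazard ratios y with standard errors se are adjusted by a
random-intercept linear mixed model:

    y = α + γ·(level − baseline) + δ_m + u_subject + ε,
    u_subject ~ N(0, τ²),  ε ~ N(0, σ²·se²)

with mistake count categorized as none / one / more than one (δ_m,
reference category none; the open-ended top category keeps rare
high-mistake games from acting as leverage points). Residual variances
are proportional to the known per-game sampling variances, i.e. each
game is weighted by 1/se². The model is fit by REML: for fixed variance
components the GLS solve uses per-subject Woodbury identities (block
covariance = diagonal + rank-one), and (log τ², log σ²) are profiled by
Nelder–Mead (xatol 1e-7, fatol 1e-9). With a single subject the random
intercept is unidentifiable and a weighted least squares fit
(statsmodels WLS) is used instead. The default baseline level is the
modal level among control games, so adjusted scores read "as if played
at the typical level". Mixed-model covariate categories without
contrast in the data are dropped from the design.

The *adjusted* log hazard ratio of a game is
y − γ·(level − baseline) − δ_m; its variance is taken as se² (the fixed
effects are estimated from the whole study and contribute negligibly).

## 5. Beta values

A subject's beta value over a window is the inverse-variance-weighted
mean of the adjusted log hazard ratios in the window, with weights
w = 1/se² and variance 1/Σw. Windows are the whole study and 7-day bins
anchored at each subject's first game (week 1 = days 0–6 since that
game). Jewels A and B are adjusted and aggregated separately, each with
its own adjustment model; weekly betas reuse the study-wide adjustment
model rather than refitting per week.

## 6. Group comparison and weekly correlations

Study-wide betas are compared between groups with a Welch two-sample
t-test (a Mann–Whitney rank alternative is available). Per-subject
weekly correlation matrices are pairwise-complete Pearson correlations
across weekly streams (weekly betas, step counts, survey scores); a cell
is reported missing — not zero — when fewer than 3 weeks observe both
streams. The matrix is symmetric with unit diagonal wherever a stream
has enough data.

## 7. Synthetic data generator

`simulate_study` generates a complete study from a seed: touch-event
logs, weekly step/survey streams, and a ground-truth table of every
subject's injected effects. Per game, inter-tap gaps are exponential
(optionally Weibull with shape k, same mean) with rate

    rate = base_tap_rate · exp(level_effect·level + group effect
                               + subject effect + weekly state),

where the group effect applies to patients only and is task-specific,
the subject effect is N(0, subject_sd²) drawn once per subject, and the
weekly state is N(0, weekly_sd²) drawn per subject-week and shared with
that week's streams through the coupling coefficients. Incorrect
touches are injected per tap with probability mistake_prob. Weekly game
counts are Poisson at configured per-group rates.

Defaults emulate the study design the pipeline targets:

| parameter | default | rationale |
|---|---|---|
| n_control / n_patient | 17 / 18 | study group sizes |
| weeks | 12 | study duration |
| games_per_week | controls 8/12 per task; patients 24/12 (A), 22/12 (B) | reported mean completed assessments over 12 weeks; patients engage ~3× more |
| level_dist | {2: .25, 3: .35, 4: .25, 5: .15} | heterogeneous difficulty, mid levels most common |
| base_tap_rate | 0.5 /s | ~2 s per tap at covariate zero — plausible trail-making pace |
| level_effect | −0.1 | harder boards slow tapping |
| group_effect_A / group_effect_B | 0 / −0.8 | deficit on the task-switching task only |
| subject_sd | 0.3 | between-subject spread in tap speed |
| mistake_prob | 0.05 | occasional wrong touches |
| step_mean / step_sd | 6000 / 1500 | daily-step-like weekly counts |
| survey_mean / survey_sd | 10 / 3 | opaque symptom-scale-like scores |
| stream_missing_prob | 0.1 | occasional missed surveys/sensor gaps |

What the generator emulates: two groups with task-specific hazard
shifts, heterogeneous levels, mistakes, group-asymmetric adherence,
subject heterogeneity, optional weekly cognitive drift coupled to
passive streams, stream missingness. What it omits: learning effects
over repeated play, within-game fatigue or per-jewel difficulty
gradients, circadian/time-of-day structure, dropout, and device
artifacts.

### A note on the estimand

The group difference in mean beta is a monotone transform of the
injected log-rate shift, not the shift itself: the Cox log hazard ratio
against a *mean* reference path amplifies a log-rate difference by a
factor depending on level mix and censoring (≈ 1.3 at the defaults, so
an injected −0.8 appears as ≈ −1.05 in beta units). Recovery tests
therefore assert sign, detection, and null calibration rather than
numerical equality with the injected shift.

## 8. Verification problem sizes

- Solver vs. grid oracle: 200 random two-game datasets, levels ≤ 4,
  agreement to |Δ log β| < 1e-5.
- Parameter recovery: 300 seeded replicates of the full default study
  per arm (effect and null); joint detection (correct sign, B-test
  rejects, A-test does not) ≥ 95%; null B rejection rate within
  [0.02, 0.08] at α = 0.05. One replicate ≈ 0.3 s.
- Level invariance: cohorts playing only easy ({2,3}) vs. only hard
  ({4,5}) levels, scored against a mixed-level reference cohort, give
  statistically indistinguishable adjusted betas.
- Correlation recovery: with noiseless step–state coupling and high
  adherence, the weekly beta/step correlation exceeds 0.9; deterministic
  linear streams correlate at exactly 1.

## 9. Limitations

- The reference path averages cumulative tap times, which is not the
  mean of the control survival curves; it is a simple, monotone summary
  and the scoring convention, not an estimator of a population curve.
- Proportional hazards across a game is an approximation; per-tap
  hazards likely vary with remaining board complexity.
- The ridge fallback biases extreme games toward zero; such games carry
  wide standard errors and little weight in betas, but their point
  estimates should not be read individually.
- Weekly betas reuse the study-wide adjustment model; with strong
  time-varying level effects a windowed refit would differ.
- The mixed model treats per-game standard errors as known; with very
  few events per game they are themselves noisy.
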