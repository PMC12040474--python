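# Methods

## Observer model

Binary timing judgements (simultaneity or agency) are modelled as a
two-criterion classification of a noisy internal asynchrony estimate.
For a trial at response–stimulus asynchrony Δt (ms, keypress-leading
positive), the non-lapse probability of "yes" is

    p(Δt) = Φ((Δt − (τ − Δδ/2)) / σ_L) − Φ((Δt − (τ + Δδ/2)) / (e^m σ_L)),

a difference of two normal CDFs: τ is the midpoint between the low and
high decision criteria (psychometric central tendency, ms), Δδ their
separation (width of the "yes" window, ms), σ_L the Gaussian noise on
the left flank and m the log ratio of right- to left-flank noise.  The
response probability mixes in lapses, P = l + p − 2lp, where l ∈
[0, 0.5) is half the rate of attention lapses producing a random
response.  With unequal flank noise the CDF difference can turn
microscopically negative in the far tails; it is floored at 0 before
lapse mixing, and the gradient is zeroed on floored cells.  Yes-counts
per participant × condition × RSA cell are binomial with this
probability.

Condition structure enters through effects coding: task, modality and
lag each map to ±0.5 (simultaneity/visual/lag0 = −0.5), and the seven
predictors are the three codes and their products, so a main-effect
coefficient reads directly as a level difference and an interaction as
a difference-of-differences.  τ and m use additive predictors; Δδ and
σ_L multiply their grand means by the exponential of the same linear
form, keeping them positive.  This gives 33 free scalars per
participant.  The group level assigns each non-lapse parameter a
Gaussian location/scale pair on its linear scale (identity for τ, m
and all coefficients; log for Δδ and σ_L, i.e. lognormal naturally),
64 scalars, plus one group lapse location on the scaled-logit scale
with a fixed spread of 0.5 — 65 group scalars in all.  The fixed lapse
spread is a structural choice: lapse rates are weakly identified per
participant, and freeing their group spread invites collapse; 0.5 on
the logit scale spans roughly 0.005–0.07 at ±1 sd around a 0.02
central rate, which covers the plausible range.

## Fitting

The objective is the joint mode of the multilevel model: the sum over
participants of the binomial log likelihood and the log group density
of their parameters.  This penalized (joint-mode) maximum likelihood
avoids marginalizing over individuals; it is a mode approximation, and
its known pathologies are handled explicitly:

- **Non-centered parameterization.** The optimizer works with
  standardized offsets e (x = μ + σ·e), so the penalty contributes unit
  curvature per offset no matter how small σ gets; the centered
  parameterization stalls badly once any group sd approaches its floor.
- **Sd floor.** Group log-sds are bounded below at log(0.1) on the
  optimization scale (10 ms for ms-scale parameters, 0.1 log-units for
  the multiplicative ones).  Joint-mode estimation rewards driving a
  spread to zero by −n·log σ; with a much smaller floor the optimum
  collapses most weakly identified coefficient spreads, pinning
  individuals to the group means and producing systematic
  per-participant misfit (the overdispersion diagnostic then flags
  model-generated data).  At 0.1 the floor binds only where the data
  cannot identify the spread, well-identified spreads (στ, σδ, the
  adaptation coefficient's spread) are estimated freely, and the
  group-mean effect estimates are unchanged to within a fraction of a
  millisecond.  Because the floor contributes −n·log σ at bound, fitted
  log likelihoods should not be compared across different floors.
- **Scaling.** ms-scale parameters are divided by 100 internally; lapse
  uses a scaled logit onto [10⁻⁴, 0.5); all coordinates the optimizer
  sees are O(1).

All 33·n + 65 parameters are maximized in a single L-BFGS-B run
(memory 25, analytic gradients assembled in one vectorized pass over
all cells with segment reductions).  The run is restarted (curvature
memory cleared) until the joint objective improves by less than 10⁻³,
which guards against premature inner termination; a start is
"converged" when this stationarity is reached.  The search uses
multiple starting points: a heuristic start (τ at the yes-weighted mean
RSA, Δδ from the span of RSAs with pooled yes-rate > 0.5, σ_L a quarter
of the RSA span, coefficients 0, lapse 0.02) plus seeded Gaussian
jitters of it.  The multi-start spread of the objective and of the
headline effects is reported by `stability_check`; the likelihood
surface genuinely has distant local optima, so single-start fits should
be treated with care.

Participants with fewer than two distinct RSAs cannot constrain their
flank parameters; σ_L, m and their coefficients are pinned to the
starting group means (offsets bounded at zero) with a warning.

Effects are summarized per participant from the 8 realized cell values
of τ and Δδ: simple adaptation effects are lag150 − lag0 within each
task × modality cell; marginal effects average over the crossed
factors (in the balanced design a main effect equals the mean of its
four simple effects, and for the additive τ predictor the
difference-of-differences interactions coincide with the β
coefficients); the group estimate is the unweighted participant mean.

## Resampling inference

Permutation tests shuffle, independently per participant, the
assignment of the 8 condition labels to that participant's 8 blocks of
cells (trials within a cell stay together, preserving the RSA
structure), refit the model, and recompute the statistic; the
two-sided p-value is (1 + #{|null| ≥ |observed|}) / (B + 1), which
gives the floor 1/(B+1).  The bootstrap resamples complete
participants with replacement; SE is the sd of the statistic across
resamples and the 95% CI is observed ± 1.96·SE (normal-theory, matching
how SEs are turned into CIs here).  Cohen's d = observed / (SE·√n),
since SE·√n estimates the between-participant sd of the effect.

Refits warm-start from the observed fit (duplicated bootstrap
participants inherit its parameters) and may be capped in iterations;
with a cap in place the permutation machinery can recompute the
observed statistic through the identical budget-limited refit path, so
the B + 1 values stay exchangeable under the null regardless of the
budget.  Warm-started, budget-capped refits are an approximation for
the bootstrap: empirically the SE of the headline effect changes by
about 1% between a 60-iteration cap and full convergence, because most
of the resampling variance comes from cohort composition, not from
re-optimization.  A config switch restores full multi-start refits.

Two closed forms are exposed alongside: the CI half-width of a
resampling p-value, 1.96·√(p(1−p)/B) (0.0135 at p = 0.05, B = 999,
motivating the marginal band 0.036–0.064), and the a priori minimum
sample size for a one-sample t-test via exact noncentral-t power
iterated upward in n (44 for d = 0.5, α = 0.05, power 0.90,
two-sided).

## Overdispersion diagnostic

For each participant, the binomial log likelihood of the observed
counts at the fitted parameters is compared with 1000 replicate count
vectors drawn from the fitted cell probabilities; the reported value is
the fraction of replicates with higher likelihood (ties favour the
data).  Under a correct model evaluated at the generating parameters
the value is uniform-ish around 0.5; values above 0.95 flag extra-
binomial variance.  Parameter uncertainty is not propagated (the MLE is
treated as fixed), and evaluating at parameters fitted to the same data
biases values downward — a mean well below 0.5 on real fits indicates
optimism of the fit, not model failure.

## Synthetic data generator

The generator emulates the study design: 15 nominal RSAs (−333 … 500
ms) × 10 repetitions per condition cell.  Non-negative RSAs are
realized exactly (the stimulus is triggered from the keypress).
Stimulus-leading trials depend on predicting the keypress from the
recent tapping pace, so their realized RSA adds Gaussian prediction
error (default sd 25 ms — the empirical error sd is not published, so
this is a config knob), is snapped to the 120 Hz display frame grid
(1000/120 ms), and enters the analysable dataset with probability 0.27
(the published median retention; the across-participant distribution
of retention is unknown, so a single Bernoulli rate is used).  Jittered
stimulus-leading trials may realize at non-negative asynchronies, as
happens when early stimuli precede predicted keypresses.

Responses are Bernoulli draws from the observer model with participant
parameters drawn from the group distributions.  The "paper-like"
preset sets the group means to published estimates (τ̄ 150 ms, Δδ̄
median 311 ms, adaptation shift 34 ms and modality shift 51 ms on τ,
auditory widening 0.116 on log Δδ, others 0) and chooses spreads so the
generating standardized effects match the published ones (e.g. sd of
the adaptation coefficient 31.8 ms ⇒ d = 34/31.8 = 1.07); remaining
spreads (τ̄ sd 60 ms, log Δδ̄ sd 0.30, σ̄_L lognormal around 60 ms with
log-sd 0.40, m̄ sd 0.30, minor coefficient sds 0.15–0.30) are set to
values typical of timing psychophysics.  These are estimates used as
plausible generating values, not ground truth.  A "null" preset zeroes
all 28 condition-coefficient means for calibration studies.

What the generator does **not** emulate: sequential dependencies
between trials, drift of the keypress pace, block structure and
truncated blocks, participant dropout, and any non-temporal cues that
real observers may use (the generator's agency judgements are, by
construction, timing judgements).  Passing recovery and calibration
tests therefore shows the pipeline is correct and well calibrated for
data matching the model's assumptions — not that the model is true of
real behaviour.

## Problem sizes in the shipped studies

The calibration studies in the test suite run at reduced,
seed-controlled scales chosen as the package's defaults:

- Monte-Carlo oracle: 20 random parameter points × 10⁶ draws
  (tolerance 0.002 ≈ 4 binomial sds).
- Recovery/coverage: 20 replicate cohorts, n = 48, full design,
  single-start fits, bootstrap B = 29 with 60-iteration warm refits;
  the 95% CI must cover the generating 34 ms in ≥ 90% of replicates.
- Permutation calibration: 200 null cohorts of 8 participants on the
  9 stimulus-triggered RSAs (retention 0, so cell counts stay small),
  B = 99, capped warm refits with the observed statistic recomputed
  through the same path; rejection rate at 0.05 must fall in
  [0.02, 0.09] (with 200 simulations the acceptance band is ≈ ±2.6
  binomial sds around 0.05).
- Overdispersion: 100 participants at generating parameters (mean in
  [0.45, 0.55]); stress cohort of 12 with beta-binomial dispersion 0.2
  refit and diagnosed (majority flagged).
- End-to-end pipeline: 4 participants, B = 19/19.

## Known limitations

- Joint-mode estimation shrinks weakly identified coefficient spreads
  to the 0.1 floor; a fitted spread sitting at the floor is not
  identified by the data and should not be interpreted.
- Normal-theory CIs and the d reconstruction assume approximately
  Gaussian sampling of the group-mean effect; with n ≥ 20 participants
  this is benign, at small n percentile intervals would differ.
- Budget-capped warm refits trade exactness of each resampling refit
  for feasibility; full refits are available by config.
- The multi-start search does not guarantee the global optimum; the
  stability check quantifies, but cannot eliminate, local-optimum risk.
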