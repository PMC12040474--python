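# recalib

Multilevel observer-model analysis of sensorimotor temporal
recalibration for simultaneity and agency judgements.

## The problem

After repeated exposure to a fixed delay between a voluntary action (a
keypress) and its sensory consequence (a flash or a tone), the
perceived timing of action and consequence shifts: the delayed
stimulus starts to feel simultaneous with — and caused by — the action.
Experiments measuring this *temporal recalibration* present test
stimuli at many response–stimulus asynchronies (RSAs, ms; positive =
stimulus after keypress) and collect binary yes/no judgements
("simultaneous?" or "did you cause it?") in a within-subject
2 (task: simultaneity vs agency) × 2 (test modality: visual vs
auditory) × 2 (adaptation lag: 0 vs 150 ms) design.

`recalib` implements the full analysis pipeline for such data: a
hierarchical two-criterion psychometric observer model, penalized
maximum-likelihood fitting, permutation/bootstrap inference on the
condition effects, an overdispersion diagnostic, and a synthetic-data
generator with known ground truth so every stage is testable without
any external data.

## The model

The probability of a "yes" at asynchrony Δt is the probability that a
noisy internal estimate of Δt falls between two decision criteria,
centred on τ and separated by Δδ, with Gaussian noise σ_L on the left
flank and e^m σ_L on the right:

    p(Δt) = Φ((Δt − (τ − Δδ/2)) / σ_L) − Φ((Δt − (τ + Δδ/2)) / (e^m σ_L))

mixed with a lapse process, P(yes) = l + p − 2lp.  Per participant,
τ, log Δδ, log σ_L and m each carry an effects-coded linear predictor
over the eight design cells (three ±0.5 main-effect codes and their
products), giving 4 grand means + 28 coefficients + a lapse parameter =
33 free scalars.  Group-level Gaussian location/scale pairs for every
non-lapse parameter (log scale for Δδ and σ_L, so they are lognormal)
plus a single group lapse location add 65 more: 1649 free parameters
for a 48-participant cohort.  The joint posterior-mode objective
(data log likelihood plus group log densities) is maximized by
multi-start L-BFGS with analytic gradients.

Inference mirrors the design-based approach: permutation tests that
shuffle the 8 condition labels within each participant and refit the
whole model, and a complete-participant bootstrap for SEs, 95% CIs and
Cohen's d = effect / (SE·√n).  P-values in 0.036–0.064 are classed
"marginal" (the 95% CI around p = 0.05 at 999 permutations has
half-width 0.014).

## Worked example

Simulate a small cohort, fit it, and read off the recalibration effect:

```python
from recalib import (GeneratorConfig, generate_dataset, paper_like_group,
                     aggregate, fit, FitConfig)
from recalib.fitting import get_effect

trials, truth = generate_dataset(
    GeneratorConfig(group=paper_like_group(), n_participants=48, seed=1))
table = aggregate(trials)
result = fit(table, FitConfig(n_starts=3, seed=1))
print(round(get_effect(result, "tau", "adaptation"), 1))
print(round(result.group.mean[0] * 100, 1))
```

With this seed the run prints `39.0` and `163.6`: the fitted cohort
shows a 39.0 ms rightward shift of the psychometric midpoint after lag
adaptation (this cohort was generated from a group mean of 34 ms — the
estimate recovers the cohort's own draw) and a grand-mean central
tendency of 163.6 ms, i.e. stimuli are judged simultaneous with /
caused by the action when they lag it by roughly 160 ms.

The same pipeline is scripted in `analysis/01_simulate.py` …
`04_diagnose.py` (thin drivers writing tables under `results/`), and as
a CLI:

```bash
recalib simulate --preset paper-like --n 48 --seed 1 --out out/
recalib fit      --input out/trials.csv --starts 3 --seed 1 --out out/
recalib infer    --input out/trials.csv --fit-json out/fit.json --out out/
recalib diagnose --input out/trials.csv --fit-json out/fit.json --out out/
recalib report   --dir out/
```

To analyse real data instead, point `--input` at a long-format CSV with
columns `participant_id,task,modality,lag,rsa_ms,response`.  The
benchmark comparison against the deposited study data (archived at
osf.io/hy7k8) activates when that export is placed at
`data/osf_trials.csv`.

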