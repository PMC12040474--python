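"""Permutation and bootstrap inference over the fitted condition effects.

Reloads the fitted model, then for the family of tau and delta effects
runs within-participant condition-label permutation tests and a
complete-participant bootstrap, all refits warm-started from the
observed fit.  Writes the inferential table (estimate, SE, 95% CI,
Cohen's d, permutation p, significance class) under results/.
"""

import argparse
import json
from pathlib import Path

from recalib.fitting import FitResult
from recalib.inference import InferenceConfig, run_inference
from recalib.trials import aggregate, exclusion_filter, load_trials

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--b-perm", type=int, default=99)
    parser.add_argument("--b-boot", type=int, default=99)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    trials, _ = load_trials(SCRATCH / "trials.csv")
    trials, _ = exclusion_filter(trials)
    table = aggregate(trials)
    observed = FitResult.from_dict(json.loads((RESULTS / "fit.json").read_text()))

    config = InferenceConfig(
        B_perm=args.b_perm, B_boot=args.b_boot, seed=args.seed,
        refit_inner_maxiter=100, refit_max_outer=2,
    )
    results = run_inference(table, observed=observed, config=config)
    results.to_csv(RESULTS / "inference.csv", index=False)
    print(results.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
    print(f"wrote {RESULTS / 'inference.csv'}")


if __name__ == "__main__":
    main()
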