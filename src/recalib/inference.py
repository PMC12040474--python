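"""Permutation and bootstrap inference over fitted condition effects.

Both procedures refit the full multilevel model on resampled data:

- permutation test: independently for every participant, the assignment
  of the 8 condition labels to that participant's 8 blocks of cells is
  randomly permuted (trials within a cell stay together, preserving the
  RSA structure), the model is refit and the effect recomputed, giving
  an exact null for "condition labels are exchangeable within
  participant"; two-sided p = (1 + #{|null| >= |observed|}) / (B + 1);
- bootstrap: complete participants are resampled with replacement and
  the model refit; the SE is the sd of the effect across resamples and
  the 95% CI the normal-theory interval observed +- 1.96 SE.

Refits warm-start from the observed fit by default (a documented
approximation that makes hundreds of refits feasible); a config switch
restores full multi-start refits.  Standardized effect sizes use
d = observed / (SE * sqrt(n)), where SE * sqrt(n) estimates the
between-participant sd of the effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import EFFECT_NAMES, FitConfig, FitResult, effect_table, fit
from .model import CellData

__all__ = [
    "InferenceConfig",
    "InferenceResult",
    "permutation_test",
    "bootstrap",
    "cohens_d",
    "classify_significance",
    "pvalue_ci_halfwidth",
    "minimum_sample_size",
    "run_inference",
]

log = logging.getLogger(__name__)

#: Statistics reported by default: every effect, for tau and delta.
DEFAULT_STATISTICS = tuple(
    (param, eff) for param in ("tau", "delta") for eff in EFFECT_NAMES
)


@dataclass
class InferenceConfig:
    B_perm: int = 999
    B_boot: int = 999
    seed: int = 0
    warm_start: bool = True  # reuse the observed fit as the single start
    max_redraw_fraction: float = 0.05
    refit_max_outer: int = 5
    # optional cap on L-BFGS iterations per resampling refit; None keeps the
    # observed fit's budget.  With warm starts a modest cap trades a little
    # per-refit convergence for making hundreds of refits affordable.
    refit_inner_maxiter: int | None = None
    # recompute the observed statistic through the same budget-limited refit
    # path (applied to the unpermuted data) before comparing it with the
    # permutation nulls: with capped refits this keeps the B + 1 values
    # exactly exchangeable under the null
    refit_observed: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class InferenceResult:
    """Full inferential summary of one named effect."""

    parameter: str
    effect: str
    observed: float
    p: float = float("nan")
    n_permutations: int = 0
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    d: float = float("nan")
    significance: str = ""
    seed: int = 0


def _effect_map(result: FitResult) -> dict[tuple[str, str], float]:
    tab = effect_table(result)
    return {
        (row.parameter, row.effect): row.estimate for row in tab.itertuples(index=False)
    }


def _refit_config(base: FitConfig, config: InferenceConfig) -> FitConfig:
    d = base.to_dict()
    d["max_outer"] = config.refit_max_outer
    if config.refit_inner_maxiter is not None:
        d["inner_maxiter"] = config.refit_inner_maxiter
    d["require_convergence"] = False
    return FitConfig(**d)


def _refit(
    cells: dict[str, CellData],
    observed: FitResult,
    config: InferenceConfig,
    init_internal: np.ndarray | None,
) -> FitResult:
    fc = _refit_config(observed.config, config)
    if config.warm_start and init_internal is not None:
        return fit(cells, fc, init=(init_internal, observed.group))
    return fit(cells, fc)


def _permute_cells(
    cells: dict[str, CellData], rng: np.random.Generator
) -> dict[str, CellData]:
    """Permute the 8 condition labels within every participant."""
    out = {}
    for pid in sorted(cells):
        data = cells[pid]
        perm = rng.permutation(8)
        out[pid] = CellData(data.rsa, data.n, data.y, perm[data.cond_idx])
    return out


def permutation_null(
    cells: dict[str, CellData],
    observed: FitResult,
    statistics,
    B: int,
    config: InferenceConfig,
) -> dict[tuple[str, str], np.ndarray]:
    """Null distributions of all requested statistics from B shared refits."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(config.seed)
    nulls = {s: np.empty(B) for s in statistics}
    max_redraws = max(1, int(math.ceil(config.max_redraw_fraction * B)))
    redraws = 0
    b = 0
    while b < B:
        shuffled = _permute_cells(cells, rng)
        try:
            refit = _refit(shuffled, observed, config, observed.internal)
        except RuntimeError as exc:
            redraws += 1
            log.warning("permutation refit failed (%s); redrawing", exc)
            if redraws > max_redraws:
                raise RuntimeError(
                    f"more than {max_redraws} permutation refits failed"
                ) from exc
            continue
        emap = _effect_map(refit)
        for s in statistics:
            nulls[s][b] = emap[s]
        b += 1
    return nulls


def permutation_test(
    table,
    statistic: tuple[str, str],
    B: int = 999,
    seed: int = 0,
    observed: FitResult | None = None,
    fit_config: FitConfig | None = None,
    config: InferenceConfig | None = None,
) -> InferenceResult:
    """Permutation p-value of one named effect, e.g. ``("tau", "adaptation")``.

    ``table`` is an aggregated table or ``{pid: CellData}``; the observed
    fit is computed if not supplied.
    """
    from .trials import table_to_celldata

    cells = table if isinstance(table, dict) else table_to_celldata(table)
    config = config or InferenceConfig(seed=seed)
    config.seed = seed
    if observed is None:
        observed = fit(cells, fit_config or FitConfig())
    if config.refit_observed:
        obs_val = _effect_map(_refit(cells, observed, config, observed.internal))[statistic]
    else:
        obs_val = _effect_map(observed)[statistic]
    nulls = permutation_null(cells, observed, [statistic], B, config)[statistic]
    p = (1.0 + np.sum(np.abs(nulls) >= abs(obs_val))) / (B + 1.0)
    return InferenceResult(
        parameter=statistic[0],
        effect=statistic[1],
        observed=obs_val,
        p=float(p),
        n_permutations=B,
        significance=classify_significance(float(p)),
        seed=seed,
    )


def _resample_cells(
    cells: dict[str, CellData],
    observed: FitResult,
    rng: np.random.Generator,
) -> tuple[dict[str, CellData], np.ndarray]:
    """Resample participants with replacement; duplicated participants get
    fresh ids and warm-start from their own fitted parameters."""
    pids = observed.participant_ids
    n = len(pids)
    while True:
        idx = rng.integers(0, n, size=n)
        if np.unique(idx).size >= min(2, n):
            break
        log.warning("bootstrap resample had < 2 unique participants; redrawing")
    new_cells = {}
    init = np.empty((n, 33))
    for k, i in enumerate(sorted(idx)):
        pid = pids[i]
        new_pid = f"b{k:03d}_{pid}"
        new_cells[new_pid] = cells[pid]
        init[k] = observed.internal[i]
    return new_cells, init


def bootstrap(
    table,
    statistic: tuple[str, str],
    B: int = 999,
    seed: int = 0,
    observed: FitResult | None = None,
    fit_config: FitConfig | None = None,
    config: InferenceConfig | None = None,
) -> tuple[float, tuple[float, float]]:
    """Participant bootstrap SE and 95% normal-theory CI of one effect."""
    from .trials import table_to_celldata

    cells = table if isinstance(table, dict) else table_to_celldata(table)
    if len(cells) < 2:
        raise ValueError("bootstrap requires >= 2 participants")
    config = config or InferenceConfig(seed=seed)
    config.seed = seed
    if observed is None:
        observed = fit(cells, fit_config or FitConfig())
    obs_val = _effect_map(observed)[statistic]
    draws = bootstrap_draws(cells, observed, [statistic], B, config)[statistic]
    se = float(np.std(draws, ddof=1))
    return se, (obs_val - 1.96 * se, obs_val + 1.96 * se)


def bootstrap_draws(
    cells: dict[str, CellData],
    observed: FitResult,
    statistics,
    B: int,
    config: InferenceConfig,
) -> dict[tuple[str, str], np.ndarray]:
    """Bootstrap distributions of all requested statistics from B refits."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(config.seed)
    draws = {s: np.empty(B) for s in statistics}
    b = 0
    failures = 0
    while b < B:
        new_cells, init = _resample_cells(cells, observed, rng)
        try:
            if config.warm_start:
                refit = fit(new_cells, _refit_config(observed.config, config),
                            init=(init, observed.group))
            else:
                refit = fit(new_cells, _refit_config(observed.config, config))
        except RuntimeError as exc:
            failures += 1
            log.warning("bootstrap refit failed (%s); redrawing", exc)
            if failures > max(1, int(math.ceil(config.max_redraw_fraction * B))):
                raise
            continue
        emap = _effect_map(refit)
        for s in statistics:
            draws[s][b] = emap[s]
        b += 1
    return draws


def cohens_d(observed: float, se: float, n: int) -> float:
    """Standardized effect size observed / (SE * sqrt(n)).

    For a mean over n i.i.d. participants, SE * sqrt(n) estimates the
    between-participant sd of the per-participant effect, making this
    the one-sample Cohen's d.  Undefined (NaN) when SE is 0.
    """
    if se == 0:
        return float("nan")
    return observed / (se * math.sqrt(n))


def classify_significance(p: float) -> str:
    """Partition p-values into significant / marginal / nonsignificant.

    The marginal band [0.036, 0.064] is the 95% CI around p = 0.05 with
    999 permutations (see :func:`pvalue_ci_halfwidth`).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    if p < 0.036:
        return "significant"
    if p <= 0.064:
        return "marginal"
    return "nonsignificant"


def pvalue_ci_halfwidth(p: float, B: int) -> float:
    """Half-width 1.96 sqrt(p(1-p)/B) of the CI of a resampling p-value."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    if B < 1:
        raise ValueError("B must be >= 1")
    return 1.96 * math.sqrt(p * (1.0 - p) / B)


def minimum_sample_size(
    d: float, alpha: float = 0.05, power: float = 0.90, two_sided: bool = True,
    n_max: int = 1_000_000,
) -> int:
    """Smallest n giving a one-sample t-test the target power at effect d.

    Exact noncentral-t power, iterating n upward: with df = n - 1 and
    noncentrality d * sqrt(n), power = P(|T| > t_crit) (two-sided) or
    P(T > t_crit) (one-sided).
    """
    if d <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("need d > 0 and alpha, power in (0, 1)")
    for n in range(2, n_max + 1):
        df = n - 1
        nc = d * math.sqrt(n)
        if two_sided:
            tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
            pw = 1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        else:
            tcrit = stats.t.ppf(1.0 - alpha, df)
            pw = 1.0 - stats.nct.cdf(tcrit, df, nc)
        if pw >= power:
            return n
    raise ValueError(f"power {power} unattainable for d={d} within n <= {n_max}")


def run_inference(
    table,
    observed: FitResult | None = None,
    statistics=DEFAULT_STATISTICS,
    config: InferenceConfig | None = None,
    fit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Permutation + bootstrap summary for a family of effects.

    All statistics share the same B_perm permutation refits and B_boot
    bootstrap refits.  Returns one row per effect: estimate (ms), SE,
    95% CI, Cohen's d, permutation p and its significance class.
    """
    from .trials import table_to_celldata

    cells = table if isinstance(table, dict) else table_to_celldata(table)
    config = config or InferenceConfig()
    if observed is None:
        observed = fit(cells, fit_config or FitConfig())
    emap = _effect_map(observed)
    n = len(observed.participant_ids)

    nulls = permutation_null(cells, observed, statistics, config.B_perm, config)
    boot_cfg = InferenceConfig(**{**config.to_dict(), "seed": config.seed + 1})
    boots = bootstrap_draws(cells, observed, statistics, config.B_boot, boot_cfg)

    rows = []
    for s in statistics:
        obs_val = emap[s]
        p = float(
            (1.0 + np.sum(np.abs(nulls[s]) >= abs(obs_val))) / (config.B_perm + 1.0)
        )
        se = float(np.std(boots[s], ddof=1))
        rows.append(
            {
                "parameter": s[0],
                "effect": s[1],
                "estimate": obs_val,
                "se": se,
                "ci_low": obs_val - 1.96 * se,
                "ci_high": obs_val + 1.96 * se,
                "d": cohens_d(obs_val, se, n),
                "p": p,
                "significance": classify_significance(p),
            }
        )
    return pd.DataFrame(rows)
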