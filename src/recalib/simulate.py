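"""Synthetic trial-level data with the structure the analysis assumes.

The generator emulates the within-subject 2 (task: simultaneity vs
agency) x 2 (test modality: visual vs auditory) x 2 (adaptation lag: 0
vs 150 ms) design: 15 nominal RSAs per cell with 10 repetitions each.
Trials at non-negative RSAs are realized exactly as intended (the
stimulus is triggered from the keypress).  Stimulus-leading trials
depend on predicting the keypress, so their realized RSA gets Gaussian
prediction error, is snapped to the display frame grid, and survives
into the analysable dataset only with a fixed retention probability
(the study recovered a median of 27% of them).

Responses are drawn from the two-criterion observer model with each
participant's parameters drawn from group-level distributions, so the
generated datasets carry known ground truth for parameter-recovery
studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit

from .model import (
    CELLS,
    LAPSE_HI,
    LAPSE_LO,
    GroupParams,
    ParticipantParams,
    condition_params,
    detection_probability,
    effects_code,
    response_probability,
)
from .trials import FRAME_MS, bin_to_frames

__all__ = [
    "DesignSpec",
    "GeneratorConfig",
    "paper_like_group",
    "null_group",
    "draw_participant",
    "simulate_trials",
    "generate_dataset",
    "inject_overdispersion",
    "truth_to_json",
]

#: Nominal RSA grid (ms): 6 stimulus-leading, 9 stimulus-lagging values.
DEFAULT_RSA_GRID = (
    -333.0, -250.0, -133.0, -100.0, -66.0, -33.0,
    0.0, 33.0, 66.0, 100.0, 133.0, 250.0, 333.0, 417.0, 500.0,
)


@dataclass
class DesignSpec:
    """Factor structure and trial accounting of one synthetic dataset."""

    rsa_grid: tuple = DEFAULT_RSA_GRID
    reps_per_rsa: int = 10
    negative_rsa_retention: float = 0.27
    frame_ms: float = FRAME_MS
    rsa_jitter_sd: float = 25.0  # keypress-time prediction error, ms

    def __post_init__(self) -> None:
        grid = tuple(float(v) for v in self.rsa_grid)
        if sorted(set(grid)) != list(grid):
            raise ValueError("rsa_grid must be sorted and unique")
        if not (0.0 <= self.negative_rsa_retention <= 1.0):
            raise ValueError("negative_rsa_retention must lie in [0, 1]")
        if self.reps_per_rsa < 1:
            raise ValueError("reps_per_rsa must be >= 1")
        self.rsa_grid = grid


@dataclass
class GeneratorConfig:
    group: GroupParams
    n_participants: int
    design: DesignSpec = field(default_factory=DesignSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def _lapse_logit(lapse: float) -> float:
    return float(logit((lapse - LAPSE_LO) / (LAPSE_HI - LAPSE_LO)))


def _group_from_natural(
    tau_mean_ms: float,
    tau_sd_ms: float,
    delta_mean_ms: float,
    log_delta_sd: float,
    sigmaL_mean_ms: float,
    log_sigmaL_sd: float,
    m_mean: float,
    m_sd: float,
    lapse: float,
    beta_tau_mean_ms: dict[str, float],
    beta_tau_sd_ms: dict[str, float],
    beta_delta_mean: dict[str, float],
    beta_delta_sd: dict[str, float],
    beta_sigma_sd: float,
    beta_m_sd: float,
) -> GroupParams:
    from .model import BETA_NAMES

    mean = np.zeros(32)
    sd = np.zeros(32)
    mean[0], sd[0] = tau_mean_ms / 100.0, tau_sd_ms / 100.0
    mean[1], sd[1] = math.log(delta_mean_ms / 100.0), log_delta_sd
    mean[2], sd[2] = math.log(sigmaL_mean_ms / 100.0), log_sigmaL_sd
    mean[3], sd[3] = m_mean, m_sd
    for j, b in enumerate(BETA_NAMES):
        mean[4 + j] = beta_tau_mean_ms.get(b, 0.0) / 100.0
        sd[4 + j] = beta_tau_sd_ms.get(b, 20.0) / 100.0
        mean[11 + j] = beta_delta_mean.get(b, 0.0)
        sd[11 + j] = beta_delta_sd.get(b, 0.15)
        sd[18 + j] = beta_sigma_sd
        sd[25 + j] = beta_m_sd
    return GroupParams(mean=mean, sd=sd, lapse_mean=_lapse_logit(lapse))


def paper_like_group() -> GroupParams:
    """Generating preset with group means at the published estimates.

    Grand-mean central tendency 150 ms, lognormal criterion separation
    with median 311 ms, a 34 ms adaptation shift and a 51 ms modality
    shift on tau, and an auditory widening of the yes-window of about
    36 ms (log-scale coefficient 0.116).  These are estimates from real
    data used as plausible generating values, not ground truth about
    behaviour.  Between-participant spreads of the tau effects are set
    so the generating standardized effect sizes match the published
    ones (e.g. 34 ms / 31.8 ms = 1.07 for adaptation).
    """
    return _group_from_natural(
        tau_mean_ms=150.0,
        tau_sd_ms=60.0,
        delta_mean_ms=311.0,
        log_delta_sd=0.30,
        sigmaL_mean_ms=60.0,
        log_sigmaL_sd=0.40,
        m_mean=0.0,
        m_sd=0.30,
        lapse=0.02,
        beta_tau_mean_ms={"a": 34.0, "s": 51.0},
        beta_tau_sd_ms={"a": 31.8, "s": 49.0, "t": 30.0},
        beta_delta_mean={"s": 0.116},
        beta_delta_sd={"s": 0.29},
        beta_sigma_sd=0.15,
        beta_m_sd=0.15,
    )


def null_group() -> GroupParams:
    """Paper-like spreads but every condition-effect mean set to zero.

    Used for calibration studies where the null hypothesis of no
    condition effects must hold exactly in the generating process.
    """
    g = paper_like_group()
    mean = g.mean.copy()
    mean[4:] = 0.0  # all 28 condition-coefficient means
    return GroupParams(mean=mean, sd=g.sd.copy(), lapse_mean=g.lapse_mean)


def draw_participant(group: GroupParams, seed) -> ParticipantParams:
    """Draw one participant from the group-level distributions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return group.draw(rng)


def simulate_trials(
    p: ParticipantParams, design: DesignSpec, seed, participant_id: str = "p01"
) -> pd.DataFrame:
    """Simulate one participant's test trials across all 8 cells.

    Non-negative nominal RSAs are realized exactly; negative ones get
    Gaussian keypress-prediction jitter, frame binning, and independent
    retention.  Responses are Bernoulli draws from the lapse-mixed
    observer-model probability at the realized RSA.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = np.asarray(design.rsa_grid)
    reps = design.reps_per_rsa
    rows_task, rows_mod, rows_lag, rows_rsa, rows_resp = [], [], [], [], []
    for task, modality, lag in CELLS:
        cp = condition_params(p, effects_code(task, modality, lag))
        nominal = np.repeat(grid, reps)
        negative = nominal < 0
        realized = nominal.astype(float).copy()
        if negative.any():
            jitter = rng.normal(0.0, design.rsa_jitter_sd, size=int(negative.sum()))
            realized[negative] = bin_to_frames(
                nominal[negative] + jitter, design.frame_ms
            )
        keep = np.ones(nominal.size, dtype=bool)
        if negative.any():
            keep[negative] = rng.random(int(negative.sum())) < design.negative_rsa_retention
        realized = realized[keep]
        prob = response_probability(detection_probability(realized, cp), p.lapse)
        resp = (rng.random(realized.size) < prob).astype(int)
        k = realized.size
        rows_task += [task] * k
        rows_mod += [modality] * k
        rows_lag += [lag] * k
        rows_rsa.append(realized)
        rows_resp.append(resp)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "task": rows_task,
            "modality": rows_mod,
            "lag": rows_lag,
            "rsa_ms": np.concatenate(rows_rsa),
            "response": np.concatenate(rows_resp),
        }
    )


def generate_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a full cohort and return (trials, ground truth).

    The ground-truth dict holds the generating :class:`GroupParams` and
    every participant's :class:`ParticipantParams` for recovery scoring.
    A single seed drives participant draws and trial simulation, so the
    output is reproducible byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_participants)))
    frames = []
    participants: dict[str, ParticipantParams] = {}
    for i in range(config.n_participants):
        pid = f"p{i + 1:0{width}d}"
        p = config.group.draw(rng)
        participants[pid] = p
        frames.append(simulate_trials(p, config.design, rng, participant_id=pid))
    trials = pd.concat(frames, ignore_index=True)
    truth = {"group": config.group, "participants": participants, "seed": config.seed}
    return trials, truth


def inject_overdispersion(
    table: pd.DataFrame,
    participants: dict[str, ParticipantParams],
    dispersion: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Replace cell counts with beta-binomial draws (extra-binomial noise).

    Each cell's yes-count is redrawn as y ~ Binomial(n, q) with
    q ~ Beta(c p, c (1-p)), c = (1 - dispersion) / dispersion, around the
    observer-model probability p of that cell, so the intra-class
    correlation of responses within a cell is ``dispersion``.  Used as a
    stress input for the overdispersion diagnostic: the binomial model
    cannot absorb this extra variance.
    """
    if not (0.0 < dispersion < 1.0):
        raise ValueError("dispersion must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    c = (1.0 - dispersion) / dispersion
    out = table.copy()
    y_new = np.empty(len(out), dtype=int)
    for pid, sub in out.groupby("participant_id", sort=False):
        p = participants[str(pid)]
        for idx, row in sub.iterrows():
            cp = condition_params(p, effects_code(row.task, row.modality, row.lag))
            prob = response_probability(
                detection_probability(row.rsa_ms, cp), p.lapse
            )
            prob = min(max(prob, 1e-6), 1.0 - 1e-6)
            q = rng.beta(c * prob, c * (1.0 - prob))
            y_new[out.index.get_loc(idx)] = rng.binomial(int(row.n_trials), q)
    out["n_yes"] = y_new
    return out


def truth_to_json(truth: dict) -> str:
    """Serialize ground truth (group vector + internal participant vectors)."""
    return json.dumps(
        {
            "seed": truth["seed"],
            "group": truth["group"].to_vector().tolist(),
            "participants": {
                pid: p.to_internal().tolist()
                for pid, p in truth["participants"].items()
            },
        },
        indent=1,
    )
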