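"""Penalized maximum-likelihood fitting of the multilevel observer model.

The joint objective is the sum over participants of the binomial data
log likelihood and the log group density of their 33 parameters (the
group level acts as an adaptive penalty; the fit is the joint mode of
the multilevel model).  All 33 P + 65 parameters are maximized together
by L-BFGS-B with analytic gradients, using the non-centered
parameterization x_i = mu + sd * e_i for the participant block — the
penalty then has unit curvature in every standardized offset, which
keeps the surface well conditioned even when group sds approach their
floor.  Group log-sds are bounded below at the floor to prevent the
degenerate collapse joint-mode estimation is prone to.

Multiple jittered starting points guard against local maxima; a single
master seed makes the whole search reproducible, and a previous solution
can be passed as a warm start (how the resampling procedures make
hundreds of refits affordable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import (
    CELLS,
    LAPSE_HI,
    LAPSE_LO,
    MS_SCALE,
    NONLAPSE_IDX,
    CellData,
    GroupParams,
    ParticipantParams,
    design_matrix,
)
from .trials import table_to_celldata

__all__ = [
    "FitConfig",
    "FitResult",
    "initial_values",
    "fit",
    "stability_check",
    "effect_table",
    "EFFECT_NAMES",
    "participant_cell_values",
]

log = logging.getLogger(__name__)

_DESIGN = design_matrix()

# Optimization-scale indices of the flank parameters (sigma_L, m and their
# condition coefficients), frozen at group means for data-starved participants.
_FLANK_IDX = np.concatenate([[2, 3], np.arange(19, 33)])


# Default group-sd starting values on the optimization scale, ordered as
# model.PARAM_NAMES: generous enough to let individuals move early on.
_SD0 = np.concatenate(
    [
        [0.5, 0.5, 0.5, 0.3],  # tau_bar/100, log delta_bar, log sigmaL_bar, m_bar
        np.full(7, 0.3),  # beta_tau/100
        np.full(7, 0.3),  # beta_delta
        np.full(7, 0.3),  # beta_sigma
        np.full(7, 0.3),  # beta_m
    ]
)

# Per-coordinate jitter scales (internal scale) for multi-start search.
_JITTER = np.concatenate([[0.4, 0.4, 0.4, 0.25, 0.8], np.full(28, 0.2)])


@dataclass
class FitConfig:
    """Tunables of the multi-start joint fit."""

    n_starts: int = 20
    seed: int = 0
    max_outer: int = 10  # joint-solve restarts until stationary
    outer_tol: float = 1e-3  # absolute joint-loglik improvement to continue
    inner_maxiter: int = 2000
    # group-sd floor on each parameter's optimization scale (10 ms for
    # ms-scale parameters, 0.1 log-units for the multiplicative ones):
    # large enough to actually stop joint-mode collapse from pinning
    # individuals to the group means, small enough to bind only where the
    # data cannot identify the spread
    sd_floor: float = 0.1
    n_starts_validation: int = 50
    # when False, a fit that exhausts its iteration budget without the joint
    # objective going stationary returns its best point instead of raising;
    # used by the budget-capped resampling refits
    require_convergence: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitResult:
    """Best fit over all starts, plus per-start diagnostics."""

    group: GroupParams
    participants: dict[str, ParticipantParams]
    loglik: float
    n_starts: int
    per_start_logliks: list[float]
    converged: list[bool]
    seed: int
    config: FitConfig
    internal: np.ndarray = None  # participants x 33, optimization scale
    participant_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "n_starts": self.n_starts,
            "per_start_logliks": self.per_start_logliks,
            "converged": self.converged,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "group": self.group.to_vector().tolist(),
            "participant_ids": self.participant_ids,
            "internal": self.internal.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        internal = np.asarray(d["internal"], dtype=float)
        pids = list(d["participant_ids"])
        return cls(
            group=GroupParams.from_vector(np.asarray(d["group"])),
            participants={
                pid: ParticipantParams.from_internal(internal[i])
                for i, pid in enumerate(pids)
            },
            loglik=float(d["loglik"]),
            n_starts=int(d["n_starts"]),
            per_start_logliks=[float(v) for v in d["per_start_logliks"]],
            converged=[bool(v) for v in d["converged"]],
            seed=int(d["seed"]),
            config=FitConfig(**d["config"]),
            internal=internal,
            participant_ids=pids,
        )


def initial_values(
    cells: dict[str, CellData], seed: int = 0
) -> tuple[np.ndarray, GroupParams]:
    """Heuristic starting point from the pooled yes-proportions.

    tau starts at the yes-weighted mean RSA, delta at the RSA span where
    the pooled yes-proportion exceeds one half (falling back to half the
    RSA range), sigma_L at a quarter of the RSA span; m and all
    condition coefficients start at zero and lapse at 0.02.
    """
    rsa = np.concatenate([c.rsa for c in cells.values()])
    n = np.concatenate([c.n for c in cells.values()])
    y = np.concatenate([c.y for c in cells.values()])
    lo, hi = float(rsa.min()), float(rsa.max())
    span = max(hi - lo, 1.0)

    total_yes = y.sum()
    degenerate = total_yes == 0 or total_yes == n.sum()
    if degenerate:
        log.warning("degenerate table (all yes or all no); using wide defaults")
        tau0 = (lo + hi) / 2.0
        delta0 = span / 2.0
    else:
        tau0 = float((rsa * y).sum() / total_yes)
        # pool proportions per unique RSA, then span of the > 0.5 region
        order = np.argsort(rsa)
        uniq, inv = np.unique(rsa[order], return_inverse=True)
        ny = np.bincount(inv, weights=n[order])
        yy = np.bincount(inv, weights=y[order])
        high = uniq[yy / ny > 0.5]
        delta0 = float(high.max() - high.min()) if high.size >= 2 else span / 2.0
        delta0 = max(delta0, span / 20.0)
    sigma0 = max(span / 4.0, 1.0)

    base = ParticipantParams(
        tau_bar=tau0, delta_bar=delta0, sigmaL_bar=sigma0, m_bar=0.0, lapse=0.02
    ).to_internal()
    group0 = GroupParams(
        mean=base[NONLAPSE_IDX].copy(), sd=_SD0.copy(), lapse_mean=base[4]
    )
    return base, group0


def _start_points(
    base: np.ndarray,
    group0: GroupParams,
    pids: list[str],
    n_starts: int,
    rng: np.random.Generator,
):
    """Yield (X, group) starts: the heuristic first, jittered copies after."""
    n = len(pids)
    for s in range(n_starts):
        X = np.tile(base, (n, 1))
        group = GroupParams(
            mean=group0.mean.copy(), sd=group0.sd.copy(), lapse_mean=group0.lapse_mean
        )
        if s > 0:
            X += rng.normal(0.0, _JITTER, size=(n, 33))
            shift = rng.normal(0.0, _JITTER[np.r_[0:4, 5:33]] * 0.5)
            group.mean = group.mean + shift[:32]
        yield X, group


class _Stacked:
    """All participants' cells concatenated for one vectorized pass.

    The participant block of the joint objective separates across
    participants, so all of them can be optimized in a single L-BFGS-B
    problem over the stacked (P x 33) parameter matrix; the likelihood
    and its gradient are computed in one numpy pass over every cell,
    with per-participant accumulation via bincount.
    """

    def __init__(self, cells: list[CellData]):
        self.P = len(cells)
        self.rsa = np.concatenate([c.rsa for c in cells])
        self.n = np.concatenate([c.n for c in cells])
        self.y = np.concatenate([c.y for c in cells])
        self.logc = np.concatenate([c.logc for c in cells])
        self.D = np.concatenate([c.D for c in cells])
        self.pidx = np.concatenate(
            [np.full(len(c), i, dtype=np.intp) for i, c in enumerate(cells)]
        )
        # cells are stored participant-contiguous: segment offsets for reduceat
        sizes = np.array([len(c) for c in cells])
        self.starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.intp)
        # reusable buffers: the per-cell parameter gather and the per-cell
        # gradient matrix are the two big allocations on the hot path
        self._pv = np.empty((self.rsa.size, 33))
        self._G = np.empty((self.rsa.size, 33))

    def loglik_grad(self, X: np.ndarray) -> tuple[float, np.ndarray]:
        """Summed data log likelihood and its gradient w.r.t. X (P x 33)."""
        from scipy.special import expit, ndtr

        from .model import LAPSE_HI, LAPSE_LO, MS_SCALE

        pv = np.take(X, self.pidx, axis=0, out=self._pv)  # cells x 33
        D = self.D
        # exponents bounded at 30 (~1e13 ms): keeps line-search probes at
        # absurd parameter values finite without touching the sane region
        tau = MS_SCALE * (pv[:, 0] + np.einsum("ij,ij->i", D, pv[:, 5:12]))
        delta = MS_SCALE * np.exp(
            np.minimum(pv[:, 1] + np.einsum("ij,ij->i", D, pv[:, 12:19]), 30.0)
        )
        sigL = MS_SCALE * np.exp(
            np.minimum(pv[:, 2] + np.einsum("ij,ij->i", D, pv[:, 19:26]), 30.0)
        )
        m = np.minimum(pv[:, 3] + np.einsum("ij,ij->i", D, pv[:, 26:33]), 30.0)
        sigR = np.exp(m) * sigL
        z1 = (self.rsa - tau + delta / 2.0) / sigL
        z2 = (self.rsa - tau - delta / 2.0) / sigR
        pdet_raw = ndtr(z1) - ndtr(z2)
        pdet = np.maximum(pdet_raw, 0.0)
        s_lapse = expit(X[:, 4])
        lapse = (LAPSE_LO + (LAPSE_HI - LAPSE_LO) * s_lapse)[self.pidx]
        p = lapse + (1.0 - 2.0 * lapse) * pdet
        ll = float(np.sum(self.logc + self.y * np.log(p) + (self.n - self.y) * np.log1p(-p)))

        w = self.y / p - (self.n - self.y) / (1.0 - p)
        inv_sqrt2pi = 0.3989422804014327
        z1c = np.clip(z1, -40.0, 40.0)  # pdf is exactly 0 beyond in float64
        z2c = np.clip(z2, -40.0, 40.0)
        phi1 = np.exp(-0.5 * z1c * z1c) * inv_sqrt2pi
        phi2 = np.exp(-0.5 * z2c * z2c) * inv_sqrt2pi
        active = pdet_raw > 0.0
        one_m2l = 1.0 - 2.0 * lapse
        dtau = np.where(active, -phi1 / sigL + phi2 / sigR, 0.0)
        ddelta = np.where(active, 0.5 * (phi1 / sigL + phi2 / sigR), 0.0)
        dsig = np.where(active, (-phi1 * z1c + phi2 * z2c) / sigL, 0.0)
        dm = np.where(active, phi2 * z2c, 0.0)

        # per-cell gradient in its participant's 33 coordinates, then one
        # segment reduction over the participant-contiguous cell blocks
        G = self._G
        G[:, 0] = w * one_m2l * dtau * MS_SCALE
        G[:, 1] = w * one_m2l * ddelta * delta
        G[:, 2] = w * one_m2l * dsig * sigL
        G[:, 3] = w * one_m2l * dm
        G[:, 4] = w * (1.0 - 2.0 * pdet)
        G[:, 5:12] = G[:, 0][:, None] * D
        G[:, 12:19] = G[:, 1][:, None] * D
        G[:, 19:26] = G[:, 2][:, None] * D
        G[:, 26:33] = G[:, 3][:, None] * D
        g = np.add.reduceat(G, self.starts, axis=0)
        g[:, 4] *= (LAPSE_HI - LAPSE_LO) * s_lapse * (1.0 - s_lapse)
        return ll, g

    def penalty_grad(self, X: np.ndarray, group: GroupParams):
        """Summed group log density over participants, and its gradient."""
        import math

        from .model import LAPSE_GROUP_SD

        z = (X[:, NONLAPSE_IDX] - group.mean) / group.sd
        zl = (X[:, 4] - group.lapse_mean) / LAPSE_GROUP_SD
        val = (
            -0.5 * float(np.sum(z * z))
            - self.P * float(np.sum(np.log(group.sd)))
            - 0.5 * float(np.sum(zl * zl))
            - self.P * math.log(LAPSE_GROUP_SD)
            - self.P * 33 * 0.5 * math.log(2.0 * math.pi)
        )
        g = np.zeros_like(X)
        g[:, NONLAPSE_IDX] = -z / group.sd
        g[:, 4] = -zl / LAPSE_GROUP_SD
        return val, g


def _solve_joint(
    X0: np.ndarray,
    group0: GroupParams,
    stacked: _Stacked,
    config: FitConfig,
    frozen_rows: list[int],
) -> tuple[np.ndarray, GroupParams, float, bool]:
    """One L-BFGS-B run over all participant and group parameters.

    The search uses the non-centered parameterization x_i = mu + sd * e_i
    (participants represented by standardized offsets e): the group
    penalty then has unit curvature in every e coordinate regardless of
    how small the group sds get, which removes the stiffness the
    centered parameterization develops near the sd floor.  Group log-sds
    are bounded below at the floor; the flank parameters of
    data-starved participants are pinned to the group means by fixing
    their offsets at zero.  The objective value is the joint log
    likelihood, unchanged by the reparameterization.
    """
    import math

    from .model import LAPSE_GROUP_SD

    P = stacked.P
    nE = P * 33
    nl = NONLAPSE_IDX

    E0 = np.empty((P, 33))
    E0[:, nl] = (X0[:, nl] - group0.mean) / group0.sd
    E0[:, 4] = (X0[:, 4] - group0.lapse_mean) / LAPSE_GROUP_SD

    lb = np.full(nE + 65, -np.inf)
    ub = np.full(nE + 65, np.inf)
    lb[nE + 32 : nE + 64] = np.log(config.sd_floor)
    if frozen_rows:
        lbE = lb[:nE].reshape(P, 33)
        ubE = ub[:nE].reshape(P, 33)
        for i in frozen_rows:
            E0[i, _FLANK_IDX] = 0.0
            lbE[i, _FLANK_IDX] = 0.0
            ubE[i, _FLANK_IDX] = 0.0

    v0 = np.concatenate([E0.ravel(), group0.to_vector()])
    v0[nE + 32 : nE + 64] = np.maximum(v0[nE + 32 : nE + 64], np.log(config.sd_floor))
    const = -P * math.log(LAPSE_GROUP_SD) - P * 33 * 0.5 * math.log(2.0 * math.pi)

    def negobj(v):
        E = v[:nE].reshape(P, 33)
        mu, log_sd, lapse_mean = v[nE : nE + 32], v[nE + 32 : nE + 64], v[-1]
        sd = np.exp(log_sd)
        X = np.empty((P, 33))
        X[:, nl] = mu + sd * E[:, nl]
        X[:, 4] = lapse_mean + LAPSE_GROUP_SD * E[:, 4]
        ll, gX = stacked.loglik_grad(X)
        f = ll - 0.5 * float(np.sum(E * E)) - P * float(np.sum(log_sd)) + const
        g = np.empty_like(v)
        gE = g[:nE].reshape(P, 33)
        gE[:, nl] = gX[:, nl] * sd - E[:, nl]
        gE[:, 4] = gX[:, 4] * LAPSE_GROUP_SD - E[:, 4]
        g[nE : nE + 32] = gX[:, nl].sum(axis=0)
        g[nE + 32 : nE + 64] = sd * np.einsum("ij,ij->j", gX[:, nl], E[:, nl]) - P
        g[-1] = gX[:, 4].sum()
        return -f, -g

    res = minimize(
        negobj,
        v0,
        jac=True,
        method="L-BFGS-B",
        bounds=np.column_stack([lb, ub]),
        options={
            "maxiter": config.inner_maxiter,
            "maxcor": 25,
            "ftol": 1e-11,
            "gtol": 1e-6,
        },
    )
    v = res.x
    E = v[:nE].reshape(P, 33)
    group = GroupParams.from_vector(v[nE:])
    X = np.empty((P, 33))
    X[:, nl] = group.mean + group.sd * E[:, nl]
    X[:, 4] = group.lapse_mean + LAPSE_GROUP_SD * E[:, 4]
    jl = _joint_loglik(X, group, stacked)
    return X, group, jl, bool(np.isfinite(jl))


def _joint_loglik(X: np.ndarray, group: GroupParams, stacked: _Stacked) -> float:
    ll, _ = stacked.loglik_grad(X)
    pl, _ = stacked.penalty_grad(X, group)
    return ll + pl


def _restarted_solve(
    X: np.ndarray,
    group: GroupParams,
    stacked: _Stacked,
    frozen_rows: list[int],
    config: FitConfig,
) -> tuple[np.ndarray, GroupParams, float, bool]:
    """Joint solves repeated until the objective is stationary.

    A single joint L-BFGS run does essentially all the work; the outer
    loop restarts it (curvature memory cleared) until the improvement
    falls below ``outer_tol``, which guards against early inner
    termination on a hard surface.
    """
    prev = -np.inf
    converged = False
    jl = -np.inf
    for _ in range(config.max_outer):
        X, group, jl, ok = _solve_joint(X, group, stacked, config, frozen_rows)
        if not ok:
            break
        if jl - prev <= config.outer_tol:
            converged = True
            break
        prev = jl
    return X, group, jl, converged


def fit(
    table,
    config: FitConfig | None = None,
    init: tuple[np.ndarray, GroupParams] | None = None,
) -> FitResult:
    """Fit the multilevel observer model to an aggregated binomial table.

    ``table`` is the aggregated DataFrame from :func:`recalib.trials.aggregate`
    or a ready ``{participant_id: CellData}`` mapping.  ``init`` warm-starts
    the search from a previous solution (participants x 33 internal matrix
    plus group), in which case only that single start is run — used by the
    resampling procedures, where hundreds of refits of slightly perturbed
    data are needed.
    """
    config = config or FitConfig()
    cells_by_pid = table if isinstance(table, dict) else table_to_celldata(table)
    if not cells_by_pid:
        raise ValueError("empty table: nothing to fit")
    pids = sorted(cells_by_pid)
    cells = [cells_by_pid[p] for p in pids]
    stacked = _Stacked(cells)

    frozen_rows: list[int] = []
    for i, (pid, data) in enumerate(zip(pids, cells)):
        if np.unique(data.rsa).size < 2:
            log.warning(
                "participant %s has < 2 distinct RSAs; flank parameters held at group means",
                pid,
            )
            frozen_rows.append(i)

    rng = np.random.default_rng(config.seed)
    if init is not None:
        X0, group0 = init
        starts = [(np.array(X0, dtype=float, copy=True), group0)]
    else:
        base, group0 = initial_values(cells_by_pid, config.seed)
        starts = list(
            _start_points(base, group0, pids, config.n_starts, rng)
        )

    per_start: list[float] = []
    conv: list[bool] = []
    solutions = []
    for X, group in starts:
        X, group, jl, ok = _restarted_solve(X, group, stacked, frozen_rows, config)
        per_start.append(jl)
        conv.append(ok)
        solutions.append((X, group, jl))
    best_idx = None
    for i, (jl, ok) in enumerate(zip(per_start, conv)):
        if ok and np.isfinite(jl) and (best_idx is None or jl > per_start[best_idx]):
            best_idx = i
    if best_idx is None and not config.require_convergence:
        finite = [i for i, jl in enumerate(per_start) if np.isfinite(jl)]
        if finite:
            best_idx = max(finite, key=lambda i: per_start[i])
    if best_idx is None:
        raise RuntimeError(
            f"no start converged; per-start logliks: {per_start}, flags: {conv}"
        )
    X, group, jl = solutions[best_idx]
    participants = {
        pid: ParticipantParams.from_internal(X[i]) for i, pid in enumerate(pids)
    }
    return FitResult(
        group=group,
        participants=participants,
        loglik=jl,
        n_starts=len(starts),
        per_start_logliks=per_start,
        converged=conv,
        seed=config.seed,
        config=config,
        internal=X,
        participant_ids=pids,
    )


# ---------------------------------------------------------------------------
# effect summaries
# ---------------------------------------------------------------------------

#: Names of the reported effects, in output order: the four simple
#: (per task x modality) adaptation effects, then marginal main effects
#: and interactions.  Interactions are difference-of-differences, so for
#: the additive tau predictor they coincide with the beta coefficients.
EFFECT_NAMES = (
    "grand_mean",
    "adaptation@simultaneity:visual",
    "adaptation@simultaneity:auditory",
    "adaptation@agency:visual",
    "adaptation@agency:auditory",
    "adaptation",
    "task",
    "modality",
    "task:modality",
    "task:adaptation",
    "modality:adaptation",
    "task:modality:adaptation",
)


def participant_cell_values(p: ParticipantParams) -> dict[str, np.ndarray]:
    """tau and delta realized in all 8 cells (ordered as model.CELLS)."""
    D = _DESIGN
    return {
        "tau": p.tau_bar + D @ p.beta_tau,
        "delta": p.delta_bar * np.exp(D @ p.beta_delta),
    }


def _effects_from_cells(v: np.ndarray) -> dict[str, float]:
    """All reported effects from one participant's 8 cell values."""
    cell = {c: v[i] for i, c in enumerate(CELLS)}

    def diff_a(task, mod):
        return cell[(task, mod, "lag150")] - cell[(task, mod, "lag0")]

    simple = {
        f"adaptation@{t}:{s}": diff_a(t, s)
        for t in ("simultaneity", "agency")
        for s in ("visual", "auditory")
    }
    eff = dict(simple)
    eff["grand_mean"] = float(np.mean(v))
    eff["adaptation"] = float(np.mean(list(simple.values())))
    eff["task"] = float(
        np.mean([cell[("agency", s, a)] - cell[("simultaneity", s, a)]
                 for s in MODS for a in LAGS2])
    )
    eff["modality"] = float(
        np.mean([cell[(t, "auditory", a)] - cell[(t, "visual", a)]
                 for t in TASKS2 for a in LAGS2])
    )
    eff["task:modality"] = float(
        np.mean([
            (cell[("agency", "auditory", a)] - cell[("agency", "visual", a)])
            - (cell[("simultaneity", "auditory", a)] - cell[("simultaneity", "visual", a)])
            for a in LAGS2
        ])
    )
    eff["task:adaptation"] = float(
        np.mean([diff_a("agency", s) - diff_a("simultaneity", s) for s in MODS])
    )
    eff["modality:adaptation"] = float(
        np.mean([diff_a(t, "auditory") - diff_a(t, "visual") for t in TASKS2])
    )
    eff["task:modality:adaptation"] = float(
        (diff_a("agency", "auditory") - diff_a("agency", "visual"))
        - (diff_a("simultaneity", "auditory") - diff_a("simultaneity", "visual"))
    )
    return eff


TASKS2 = ("simultaneity", "agency")
MODS = ("visual", "auditory")
LAGS2 = ("lag0", "lag150")


def effect_table(result: FitResult) -> pd.DataFrame:
    """Group-level effect estimates for tau and delta (ms).

    Per participant, tau and delta are realized in all 8 cells; each
    effect is computed per participant and averaged across the group.
    In the balanced design every marginal effect equals the mean of its
    simple effects.
    """
    rows = []
    per_param: dict[str, list[dict[str, float]]] = {"tau": [], "delta": []}
    for pid in result.participant_ids:
        values = participant_cell_values(result.participants[pid])
        for param in ("tau", "delta"):
            per_param[param].append(_effects_from_cells(values[param]))
    for param in ("tau", "delta"):
        effs = per_param[param]
        for name in EFFECT_NAMES:
            rows.append(
                {
                    "parameter": param,
                    "effect": name,
                    "estimate": float(np.mean([e[name] for e in effs])),
                }
            )
    return pd.DataFrame(rows)


def get_effect(result: FitResult, parameter: str, effect: str) -> float:
    """One named effect from :func:`effect_table` (ms)."""
    tab = effect_table(result)
    row = tab[(tab["parameter"] == parameter) & (tab["effect"] == effect)]
    if len(row) != 1:
        raise KeyError(f"unknown statistic ({parameter!r}, {effect!r})")
    return float(row["estimate"].iloc[0])


def stability_check(table, config: FitConfig | None = None, result: FitResult | None = None) -> dict:
    """Probe sensitivity of the fit to local maxima with extra starts.

    Refits from ``config.n_starts_validation`` fresh jittered starts and
    reports the spread of the joint log likelihood and of the headline
    adaptation effects on tau (overall and per task x modality cell, ms)
    across the local optima found.
    """
    config = config or FitConfig()
    if result is None:
        result = fit(table, config)
    val_config = FitConfig(**{**config.to_dict(), "n_starts": config.n_starts_validation,
                              "seed": config.seed + 1})
    refit = fit(table, val_config)

    logliks = np.asarray(result.per_start_logliks + refit.per_start_logliks)
    headline = [
        "adaptation",
        "adaptation@simultaneity:visual",
        "adaptation@simultaneity:auditory",
        "adaptation@agency:visual",
        "adaptation@agency:auditory",
    ]
    eff_a = {name: get_effect(result, "tau", name) for name in headline}
    eff_b = {name: get_effect(refit, "tau", name) for name in headline}
    return {
        "n_starts_total": int(logliks.size),
        "loglik_max": float(np.max(logliks)),
        "loglik_spread": float(np.max(logliks) - np.min(logliks)),
        "headline_effects_ms": {
            name: {"best": eff_a[name], "validation": eff_b[name],
                   "spread": abs(eff_a[name] - eff_b[name])}
            for name in headline
        },
    }
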