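"""Two-criterion observer model for binary timing judgements.

An observer experiences the asynchrony between a keypress and a sensory
stimulus with Gaussian latency noise and reports "yes" (simultaneous /
self-caused) whenever the subjective asynchrony falls between two decision
criteria.  The resulting psychometric function over the realized
response--stimulus asynchrony (RSA, ms) is a difference of two normal CDFs:

    p(yes | dt) = Phi((dt - (tau - delta/2)) / sigma_L)
                - Phi((dt - (tau + delta/2)) / (exp(m) * sigma_L))

where ``tau`` is the midpoint between the criteria (psychometric central
tendency, ms), ``delta`` the criterion separation (width of the "yes"
window, ms), ``sigma_L`` the Gaussian noise on the left flank (ms) and
``m`` the log ratio of right-flank to left-flank noise.  Responses are
additionally mixed with a lapse process: with probability ``2l`` the
observer guesses, giving

    P(yes) = l + p - 2 l p.

Condition structure (task x test-stimulus modality x adaptation lag,
each with two levels) enters through effects-coded linear predictors:
``tau`` and ``m`` are additive in the seven codes (three main effects,
three two-way and one three-way interaction), while ``delta`` and
``sigma_L`` are log-linear, keeping them positive.  Each participant
therefore has 33 free scalars (four grand means, a lapse parameter and
4 x 7 condition coefficients); the group level adds a Gaussian
location/scale pair for every non-lapse parameter (identity scale for
``tau``, ``m`` and the coefficients, log scale for ``delta`` and
``sigma_L``) plus a single group lapse location, 65 scalars in all.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit, ndtr

__all__ = [
    "TASKS",
    "MODALITIES",
    "LAGS",
    "CELLS",
    "BETA_NAMES",
    "PARAM_NAMES",
    "ConditionParams",
    "ParticipantParams",
    "GroupParams",
    "effects_code",
    "cell_index",
    "design_matrix",
    "condition_params",
    "detection_probability",
    "response_probability",
    "participant_loglik",
    "joint_log_likelihood",
    "count_parameters",
]

# Factor levels; the first level of each factor carries code -0.5.
TASKS = ("simultaneity", "agency")
MODALITIES = ("visual", "auditory")
LAGS = ("lag0", "lag150")

#: The 8 condition cells in canonical order.
CELLS = tuple(itertools.product(TASKS, MODALITIES, LAGS))

#: Order of the seven effects-coded predictors.
BETA_NAMES = ("t", "s", "a", "ts", "ta", "sa", "tsa")

# Lapse is constrained to [LAPSE_LO, LAPSE_HI) through a scaled logit so the
# likelihood stays finite; the group-level lapse distribution is a Gaussian
# on that logit scale with fixed spread LAPSE_GROUP_SD.
LAPSE_LO = 1e-4
LAPSE_HI = 0.5
LAPSE_GROUP_SD = 0.5

# ms-scale parameters are divided by MS_SCALE internally so every coordinate
# the optimizer sees is O(1).
MS_SCALE = 100.0

_SQRT2PI = math.sqrt(2.0 * math.pi)


def effects_code(task: str, modality: str, lag: str) -> tuple[float, float, float]:
    """Map factor levels to effects codes ``(t, s, a)``, each +-0.5.

    Convention: simultaneity/visual/lag0 -> -0.5 and
    agency/auditory/lag150 -> +0.5, so every reported effect reads as
    (second level) minus (first level).
    """
    try:
        t = (TASKS.index(task) - 0.5)
        s = (MODALITIES.index(modality) - 0.5)
        a = (LAGS.index(lag) - 0.5)
    except ValueError as exc:
        raise ValueError(
            f"unknown factor level in ({task!r}, {modality!r}, {lag!r})"
        ) from exc
    return (t, s, a)


def cell_index(task: str, modality: str, lag: str) -> int:
    """Index of a condition cell in :data:`CELLS`."""
    try:
        return CELLS.index((task, modality, lag))
    except ValueError as exc:
        raise ValueError(
            f"unknown condition ({task!r}, {modality!r}, {lag!r})"
        ) from exc


def design_matrix() -> np.ndarray:
    """8 x 7 effects-coding matrix, rows ordered as :data:`CELLS`.

    Columns follow :data:`BETA_NAMES`: the three main-effect codes and
    their products, so a two-way coefficient equals the
    difference-of-differences of cell values and the three-way
    coefficient the difference of those.
    """
    rows = []
    for task, modality, lag in CELLS:
        t, s, a = effects_code(task, modality, lag)
        rows.append([t, s, a, t * s, t * a, s * a, t * s * a])
    return np.asarray(rows, dtype=float)


_DESIGN = design_matrix()


@dataclass(frozen=True)
class ConditionParams:
    """Psychometric parameters realized in one condition cell."""

    tau: float  # midpoint between criteria, ms
    delta: float  # criterion separation, ms (> 0)
    sigmaL: float  # left-flank noise, ms (> 0)
    m: float  # log right/left flank-noise ratio


@dataclass
class ParticipantParams:
    """The 33 individual-level free parameters, on natural scales."""

    tau_bar: float
    delta_bar: float
    sigmaL_bar: float
    m_bar: float
    lapse: float
    beta_tau: np.ndarray = field(default_factory=lambda: np.zeros(7))
    beta_delta: np.ndarray = field(default_factory=lambda: np.zeros(7))
    beta_sigma: np.ndarray = field(default_factory=lambda: np.zeros(7))
    beta_m: np.ndarray = field(default_factory=lambda: np.zeros(7))

    def __post_init__(self) -> None:
        for name in ("beta_tau", "beta_delta", "beta_sigma", "beta_m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (7,):
                raise ValueError(f"{name} must have shape (7,), got {arr.shape}")
            setattr(self, name, arr)
        if self.delta_bar <= 0 or self.sigmaL_bar <= 0:
            raise ValueError("delta_bar and sigmaL_bar must be strictly positive")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")

    # -- internal (optimization-scale) vector ----------------------------
    # layout: [tau_bar/S, log(delta_bar/S), log(sigmaL_bar/S), m_bar,
    #          scaled-logit lapse, beta_tau/S (7), beta_delta (7),
    #          beta_sigma (7), beta_m (7)]          with S = MS_SCALE
    def to_internal(self) -> np.ndarray:
        lapse = min(max(self.lapse, LAPSE_LO), LAPSE_HI - 1e-9)
        u = logit((lapse - LAPSE_LO) / (LAPSE_HI - LAPSE_LO))
        return np.concatenate(
            [
                [
                    self.tau_bar / MS_SCALE,
                    math.log(self.delta_bar / MS_SCALE),
                    math.log(self.sigmaL_bar / MS_SCALE),
                    self.m_bar,
                    u,
                ],
                self.beta_tau / MS_SCALE,
                self.beta_delta,
                self.beta_sigma,
                self.beta_m,
            ]
        )

    @classmethod
    def from_internal(cls, x: np.ndarray) -> "ParticipantParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (33,):
            raise ValueError(f"internal vector must have shape (33,), got {x.shape}")
        lapse = LAPSE_LO + (LAPSE_HI - LAPSE_LO) * expit(x[4])
        return cls(
            tau_bar=x[0] * MS_SCALE,
            delta_bar=math.exp(x[1]) * MS_SCALE,
            sigmaL_bar=math.exp(x[2]) * MS_SCALE,
            m_bar=x[3],
            lapse=float(lapse),
            beta_tau=x[5:12] * MS_SCALE,
            beta_delta=x[12:19].copy(),
            beta_sigma=x[19:26].copy(),
            beta_m=x[26:33].copy(),
        )

    @property
    def n_free(self) -> int:
        return self.to_internal().size


#: Indices of the 32 non-lapse coordinates of the internal vector, in the
#: order the group-level location/scale pairs are stored.
NONLAPSE_IDX = np.array([0, 1, 2, 3] + list(range(5, 33)))

#: Names of the 32 group-modelled parameters (optimization scales).
PARAM_NAMES = tuple(
    ["tau_bar", "log_delta_bar", "log_sigmaL_bar", "m_bar"]
    + [f"beta_tau_{b}" for b in BETA_NAMES]
    + [f"beta_delta_{b}" for b in BETA_NAMES]
    + [f"beta_sigma_{b}" for b in BETA_NAMES]
    + [f"beta_m_{b}" for b in BETA_NAMES]
)


@dataclass
class GroupParams:
    """Group-level distributions generating individual parameters.

    ``mean``/``sd`` hold a Gaussian location/scale pair for each of the 32
    non-lapse parameters on its optimization scale (so ``delta_bar`` and
    ``sigmaL_bar`` are lognormal on the natural scale).  ``lapse_mean`` is
    the single free group lapse location on the scaled-logit scale; its
    spread is fixed at :data:`LAPSE_GROUP_SD`, giving 65 free scalars.
    """

    mean: np.ndarray
    sd: np.ndarray
    lapse_mean: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (32,) or self.sd.shape != (32,):
            raise ValueError("mean and sd must have shape (32,)")
        if np.any(self.sd <= 0):
            raise ValueError("all group sds must be strictly positive")

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.mean, np.log(self.sd), [self.lapse_mean]])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "GroupParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (65,):
            raise ValueError(f"group vector must have shape (65,), got {v.shape}")
        return cls(mean=v[:32], sd=np.exp(v[32:64]), lapse_mean=float(v[64]))

    @property
    def n_free(self) -> int:
        return self.to_vector().size

    # -- participant draws and penalties --------------------------------
    def draw_internal(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one participant's internal 33-vector."""
        x = np.empty(33)
        x[NONLAPSE_IDX] = rng.normal(self.mean, self.sd)
        x[4] = rng.normal(self.lapse_mean, LAPSE_GROUP_SD)
        return x

    def draw(self, rng: np.random.Generator) -> ParticipantParams:
        return ParticipantParams.from_internal(self.draw_internal(rng))

    def logpdf(self, x: np.ndarray) -> float:
        """Log density of one participant's internal vector."""
        z = (x[NONLAPSE_IDX] - self.mean) / self.sd
        out = -0.5 * float(z @ z) - float(np.sum(np.log(self.sd)))
        zl = (x[4] - self.lapse_mean) / LAPSE_GROUP_SD
        out += -0.5 * zl * zl - math.log(LAPSE_GROUP_SD)
        out -= 33 * 0.5 * math.log(2.0 * math.pi)
        return out

    def logpdf_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Log density and its gradient with respect to ``x``."""
        g = np.zeros(33)
        z = (x[NONLAPSE_IDX] - self.mean) / self.sd
        g[NONLAPSE_IDX] = -z / self.sd
        zl = (x[4] - self.lapse_mean) / LAPSE_GROUP_SD
        g[4] = -zl / LAPSE_GROUP_SD
        val = (
            -0.5 * float(z @ z)
            - float(np.sum(np.log(self.sd)))
            - 0.5 * zl * zl
            - math.log(LAPSE_GROUP_SD)
            - 33 * 0.5 * math.log(2.0 * math.pi)
        )
        return val, g


def _lapse_from_u(u: float) -> float:
    return float(LAPSE_LO + (LAPSE_HI - LAPSE_LO) * expit(u))


def condition_params(p: ParticipantParams, code: tuple[float, float, float]) -> ConditionParams:
    """Realize the psychometric parameters in one condition cell.

    ``tau`` and ``m`` use additive predictors in the effects codes;
    ``delta`` and ``sigma_L`` multiply their grand means by the
    exponential of the same linear form, keeping them positive.
    """
    t, s, a = code
    d = np.array([t, s, a, t * s, t * a, s * a, t * s * a])
    return ConditionParams(
        tau=float(p.tau_bar + d @ p.beta_tau),
        delta=float(p.delta_bar * math.exp(d @ p.beta_delta)),
        sigmaL=float(p.sigmaL_bar * math.exp(d @ p.beta_sigma)),
        m=float(p.m_bar + d @ p.beta_m),
    )


def detection_probability(rsa, cp: ConditionParams):
    """Probability of a (non-lapse) "yes" at the given RSA (ms).

    Difference of the two criterion CDFs; with unequal flank noise the
    raw difference can dip microscopically below zero in the far tails,
    so it is floored at 0 to stay a valid probability.
    """
    rsa = np.asarray(rsa, dtype=float)
    lo = (rsa - (cp.tau - cp.delta / 2.0)) / cp.sigmaL
    hi = (rsa - (cp.tau + cp.delta / 2.0)) / (math.exp(cp.m) * cp.sigmaL)
    p = ndtr(lo) - ndtr(hi)
    return np.maximum(p, 0.0) if p.ndim else float(max(p, 0.0))


def response_probability(p, lapse):
    """Mix the detection probability with the lapse (guessing) process."""
    p = np.asarray(p, dtype=float)
    out = lapse + p - 2.0 * lapse * p
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# vectorized likelihood core
# ---------------------------------------------------------------------------

class CellData:
    """One participant's binomial cells packed into flat arrays.

    ``cond_idx`` maps each cell to a row of :func:`design_matrix`; the log
    binomial coefficients are precomputed once.
    """

    __slots__ = ("rsa", "n", "y", "cond_idx", "logc", "D")

    def __init__(self, rsa, n, y, cond_idx):
        self.rsa = np.asarray(rsa, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.cond_idx = np.asarray(cond_idx, dtype=np.intp)
        if not (self.rsa.shape == self.n.shape == self.y.shape == self.cond_idx.shape):
            raise ValueError("rsa, n, y, cond_idx must share one shape")
        if np.any(self.y < 0) or np.any(self.y > self.n):
            raise ValueError("need 0 <= n_yes <= n_trials in every cell")
        self.logc = gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1)
        self.D = _DESIGN[self.cond_idx]  # cells x 7

    def __len__(self) -> int:
        return self.rsa.size


def _cell_response_probs(x: np.ndarray, data: CellData):
    """Response probabilities per cell plus intermediates for the gradient."""
    D = data.D
    tau = MS_SCALE * (x[0] + D @ x[5:12])
    delta = MS_SCALE * np.exp(x[1] + D @ x[12:19])
    sigL = MS_SCALE * np.exp(x[2] + D @ x[19:26])
    m = x[3] + D @ x[26:33]
    sigR = np.exp(m) * sigL
    z1 = (data.rsa - tau + delta / 2.0) / sigL
    z2 = (data.rsa - tau - delta / 2.0) / sigR
    pdet_raw = ndtr(z1) - ndtr(z2)
    pdet = np.maximum(pdet_raw, 0.0)
    lapse = _lapse_from_u(x[4])
    p = lapse + (1.0 - 2.0 * lapse) * pdet
    return p, pdet, pdet_raw, z1, z2, sigL, sigR, delta, lapse


def loglik_internal(x: np.ndarray, data: CellData) -> float:
    """Binomial log likelihood of one participant's cells at internal ``x``."""
    p, *_ = _cell_response_probs(x, data)
    return float(
        np.sum(data.logc + data.y * np.log(p) + (data.n - data.y) * np.log1p(-p))
    )


def loglik_grad_internal(x: np.ndarray, data: CellData) -> tuple[float, np.ndarray]:
    """Log likelihood and its analytic 33-gradient (internal scale)."""
    p, pdet, pdet_raw, z1, z2, sigL, sigR, delta, lapse = _cell_response_probs(x, data)
    ll = float(np.sum(data.logc + data.y * np.log(p) + (data.n - data.y) * np.log1p(-p)))

    w = data.y / p - (data.n - data.y) / (1.0 - p)  # dll/dp per cell
    z1c = np.clip(z1, -40.0, 40.0)  # pdf underflows to exactly 0 beyond
    z2c = np.clip(z2, -40.0, 40.0)
    phi1 = np.exp(-0.5 * z1c * z1c) / _SQRT2PI
    phi2 = np.exp(-0.5 * z2c * z2c) / _SQRT2PI
    active = pdet_raw > 0.0  # flooring zeroes the pdet gradient

    one_m2l = 1.0 - 2.0 * lapse
    # dp/d{tau, delta, sigL, m} on ms scale, flowing through the floor
    dtau = np.where(active, -phi1 / sigL + phi2 / sigR, 0.0)
    ddelta = np.where(active, 0.5 * (phi1 / sigL + phi2 / sigR), 0.0)
    dsig = np.where(active, (-phi1 * z1c + phi2 * z2c) / sigL, 0.0)
    dm = np.where(active, phi2 * z2c, 0.0)

    wt_tau = w * one_m2l * dtau * MS_SCALE
    wt_delta = w * one_m2l * ddelta * delta
    wt_sig = w * one_m2l * dsig * sigL
    wt_m = w * one_m2l * dm

    g = np.empty(33)
    D = data.D
    g[0] = wt_tau.sum()
    g[1] = wt_delta.sum()
    g[2] = wt_sig.sum()
    g[3] = wt_m.sum()
    s = expit(x[4])
    g[4] = float(np.sum(w * (1.0 - 2.0 * pdet))) * (LAPSE_HI - LAPSE_LO) * s * (1.0 - s)
    g[5:12] = wt_tau @ D
    g[12:19] = wt_delta @ D
    g[19:26] = wt_sig @ D
    g[26:33] = wt_m @ D
    return ll, g


def participant_loglik(p: ParticipantParams, cells: CellData) -> float:
    """Binomial log likelihood of one participant's aggregated cells.

    Returns ``-inf`` (never raises) when a zero predicted probability
    meets observed successes, which can only happen at ``lapse = 0``.
    """
    D = cells.D
    tau = p.tau_bar + D @ p.beta_tau
    delta = p.delta_bar * np.exp(D @ p.beta_delta)
    sigL = p.sigmaL_bar * np.exp(D @ p.beta_sigma)
    m = p.m_bar + D @ p.beta_m
    z1 = (cells.rsa - tau + delta / 2.0) / sigL
    z2 = (cells.rsa - tau - delta / 2.0) / (np.exp(m) * sigL)
    pdet = np.maximum(ndtr(z1) - ndtr(z2), 0.0)
    prob = response_probability(pdet, p.lapse)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (
            cells.logc
            + np.where(cells.y > 0, cells.y * np.log(prob), 0.0)
            + np.where(cells.n - cells.y > 0, (cells.n - cells.y) * np.log1p(-prob), 0.0)
        )
    if np.any(np.isnan(terms)) or np.any(np.isneginf(terms)):
        return float("-inf")
    return float(np.sum(terms))


def joint_log_likelihood(
    group: GroupParams,
    participants: dict[str, ParticipantParams],
    cells_by_participant: dict[str, CellData],
) -> float:
    """Joint objective: data log likelihood plus group log densities.

    This is the penalized (joint-mode) objective the fitter maximizes:
    the sum over participants of their binomial log likelihood and of the
    log group density of their 33 parameters.
    """
    missing = set(cells_by_participant) - set(participants)
    if missing:
        raise ValueError(f"missing ParticipantParams for {sorted(missing)}")
    total = 0.0
    for pid, cells in cells_by_participant.items():
        p = participants[pid]
        total += participant_loglik(p, cells)
        total += group.logpdf(p.to_internal())
    return total


def count_parameters(n_participants: int) -> tuple[int, int, int]:
    """Count free scalars in the multilevel model for ``n_participants``.

    Counted structurally from the parameter containers: the length of one
    participant's flattened parameter vector times the cohort size, plus
    the length of the flattened group vector.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    template = ParticipantParams(
        tau_bar=0.0, delta_bar=1.0, sigmaL_bar=1.0, m_bar=0.0, lapse=0.02
    )
    per_participant = template.n_free
    group = GroupParams(mean=np.zeros(32), sd=np.ones(32), lapse_mean=0.0).n_free
    individual_total = per_participant * n_participants
    return (individual_total, group, individual_total + group)
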