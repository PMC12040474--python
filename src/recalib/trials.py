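"""Reading, validating and aggregating trial-level judgement data.

The canonical on-disk format is a long-format UTF-8 CSV with header
``participant_id,task,modality,lag,rsa_ms,response``: one row per test
trial, RSA in ms with keypress-leading positive (negative = the stimulus
preceded the keypress), and a binary yes/no response.  Aggregation turns
trials into the binomial tables the observer model consumes: one row per
participant x condition x RSA with ``n_trials`` and ``n_yes`` counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import LAGS, MODALITIES, TASKS, CellData, cell_index

__all__ = [
    "FRAME_MS",
    "TRIAL_COLUMNS",
    "LoadReport",
    "ExclusionReport",
    "load_trials",
    "aggregate",
    "exclusion_filter",
    "table_to_celldata",
    "write_table",
]

log = logging.getLogger(__name__)

#: One frame of a 120 Hz display, the grid stimulus-leading RSAs snap to.
FRAME_MS = 1000.0 / 120.0

TRIAL_COLUMNS = ("participant_id", "task", "modality", "lag", "rsa_ms", "response")

_RESPONSE_MAP = {"yes": 1, "no": 0, "y": 1, "n": 0, "1": 1, "0": 0, "true": 1, "false": 0}


@dataclass
class LoadReport:
    """Row accounting for one CSV load."""

    n_rows: int = 0
    n_kept: int = 0
    errors: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return self.n_rows - self.n_kept


@dataclass
class ExclusionReport:
    """Participant x task removals applied by :func:`exclusion_filter`."""

    threshold: float
    removed: list[dict] = field(default_factory=list)
    yes_fractions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "removed": self.removed,
            "yes_fractions": {f"{k[0]}/{k[1]}": v for k, v in self.yes_fractions.items()},
        }


def _normalize_level(value, allowed: tuple[str, ...], synonyms: dict | None = None):
    s = str(value).strip().lower()
    if synonyms and s in synonyms:
        s = synonyms[s]
    return s if s in allowed else None


def load_trials(
    path,
    level_synonyms: dict | None = None,
    max_reject_fraction: float = 0.5,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a trial CSV, validating every row.

    Factor levels are matched case-insensitively; ``level_synonyms`` maps
    extra spellings (already lowercased) onto canonical levels, e.g.
    ``{"sj": "simultaneity"}``.  Invalid rows are collected with their
    line numbers rather than aborting, unless more than
    ``max_reject_fraction`` of rows fail.

    Returns the kept trials (canonical lowercase levels, ``response`` as
    0/1 int) and a :class:`LoadReport`.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    report = LoadReport(n_rows=len(raw))
    synonyms = dict(_RESPONSE_MAP)
    level_synonyms = level_synonyms or {}

    tasks, modalities, lags, rsas, responses, keep = [], [], [], [], [], []
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # header is line 1
        task = _normalize_level(row.task, TASKS, level_synonyms)
        modality = _normalize_level(row.modality, MODALITIES, level_synonyms)
        lag = _normalize_level(row.lag, LAGS, level_synonyms)
        resp = str(row.response).strip().lower()
        resp_val = synonyms.get(resp)
        try:
            rsa = float(row.rsa_ms)
        except (TypeError, ValueError):
            rsa = np.nan
        problems = []
        if task is None:
            problems.append(f"task {row.task!r}")
        if modality is None:
            problems.append(f"modality {row.modality!r}")
        if lag is None:
            problems.append(f"lag {row.lag!r}")
        if resp_val is None:
            problems.append(f"response {row.response!r}")
        if not np.isfinite(rsa):
            problems.append(f"rsa_ms {row.rsa_ms!r}")
        if problems:
            report.errors.append(f"line {line}: invalid " + ", ".join(problems))
            keep.append(False)
            tasks.append(None); modalities.append(None); lags.append(None)
            rsas.append(np.nan); responses.append(-1)
        else:
            keep.append(True)
            tasks.append(task); modalities.append(modality); lags.append(lag)
            rsas.append(rsa); responses.append(resp_val)

    out = pd.DataFrame(
        {
            "participant_id": raw["participant_id"].astype(str).str.strip(),
            "task": tasks,
            "modality": modalities,
            "lag": lags,
            "rsa_ms": rsas,
            "response": responses,
        }
    )[np.asarray(keep)]
    out = out.reset_index(drop=True)
    report.n_kept = len(out)
    if report.n_rows > 0 and report.n_rejected / report.n_rows > max_reject_fraction:
        raise ValueError(
            f"{path}: {report.n_rejected}/{report.n_rows} rows rejected "
            f"(> {max_reject_fraction:.0%}); first errors: {report.errors[:3]}"
        )
    log.info(
        "loaded %s: %d rows, %d kept, %d rejected",
        path, report.n_rows, report.n_kept, report.n_rejected,
    )
    return out, report


def bin_to_frames(rsa_ms, frame_ms: float = FRAME_MS):
    """Snap RSAs to the nearest display frame: round(rsa/frame)*frame."""
    rsa_ms = np.asarray(rsa_ms, dtype=float)
    return np.round(rsa_ms / frame_ms) * frame_ms


def aggregate(
    trials: pd.DataFrame,
    rsa_binning: str | float = "frame-negative",
    frame_ms: float = FRAME_MS,
) -> pd.DataFrame:
    """Aggregate trials into a binomial table.

    ``rsa_binning`` is one of

    - ``"frame-negative"`` (default): snap stimulus-leading (negative)
      RSAs to the nearest display frame, as the realized asynchronies of
      those trials are only known to frame resolution; keep non-negative
      RSAs exact,
    - ``"frame-all"``: snap every RSA to the frame grid,
    - ``"exact"``: no binning (pre-binned data),
    - a float: grid spacing in ms applied to every RSA.

    Cells that coincide after binning are merged.  Returns a DataFrame
    with columns ``participant_id, task, modality, lag, rsa_ms,
    n_trials, n_yes``.
    """
    if len(trials) == 0:
        raise ValueError("cannot aggregate an empty trial collection")
    df = trials.copy()
    rsa = df["rsa_ms"].to_numpy(dtype=float)
    if isinstance(rsa_binning, str):
        if rsa_binning == "frame-negative":
            rsa = np.where(rsa < 0, bin_to_frames(rsa, frame_ms), rsa)
        elif rsa_binning == "frame-all":
            rsa = bin_to_frames(rsa, frame_ms)
        elif rsa_binning != "exact":
            raise ValueError(f"unknown rsa_binning {rsa_binning!r}")
    else:
        rsa = np.round(rsa / float(rsa_binning)) * float(rsa_binning)
    df["rsa_ms"] = np.round(rsa, 6)  # kill float dust so grouping keys match

    grouped = (
        df.groupby(["participant_id", "task", "modality", "lag", "rsa_ms"], sort=True)["response"]
        .agg(n_trials="count", n_yes="sum")
        .reset_index()
    )
    grouped["n_trials"] = grouped["n_trials"].astype(int)
    grouped["n_yes"] = grouped["n_yes"].astype(int)
    return grouped


def exclusion_filter(
    trials: pd.DataFrame, min_yes_fraction: float = 0.02
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop a participant's task when they almost never respond yes.

    A participant whose fraction of yes responses within one task falls
    below ``min_yes_fraction`` (default 2%) plausibly judged by a
    non-temporal cue there; that task's trials are removed while their
    other task is kept.
    """
    if not (0.0 <= min_yes_fraction <= 1.0):
        raise ValueError("min_yes_fraction must lie in [0, 1]")
    report = ExclusionReport(threshold=min_yes_fraction)
    frac = trials.groupby(["participant_id", "task"])["response"].mean()
    report.yes_fractions = {k: float(v) for k, v in frac.items()}
    bad = frac[frac < min_yes_fraction]
    if len(bad) == 0:
        return trials, report
    mask = pd.Series(True, index=trials.index)
    for (pid, task), value in bad.items():
        mask &= ~((trials["participant_id"] == pid) & (trials["task"] == task))
        report.removed.append(
            {"participant_id": pid, "task": task, "yes_fraction": float(value)}
        )
        log.info("excluding %s/%s (yes fraction %.3f)", pid, task, value)
    return trials[mask].reset_index(drop=True), report


def table_to_celldata(table: pd.DataFrame) -> dict[str, CellData]:
    """Pack an aggregated table into per-participant :class:`CellData`."""
    required = {"participant_id", "task", "modality", "lag", "rsa_ms", "n_trials", "n_yes"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"aggregated table missing columns {sorted(missing)}")
    out: dict[str, CellData] = {}
    for pid, sub in table.groupby("participant_id", sort=True):
        cond = [
            cell_index(t, m, l)
            for t, m, l in zip(sub["task"], sub["modality"], sub["lag"])
        ]
        out[str(pid)] = CellData(
            rsa=sub["rsa_ms"].to_numpy(dtype=float),
            n=sub["n_trials"].to_numpy(dtype=float),
            y=sub["n_yes"].to_numpy(dtype=float),
            cond_idx=cond,
        )
    return out


def write_table(table: pd.DataFrame, path) -> None:
    """Write an aggregated (or trial) table as canonical CSV."""
    table.to_csv(path, index=False)
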