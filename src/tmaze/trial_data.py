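"""Data model and I/O for per-trial T-maze choice logs.

One *trial* is one passage through the T-maze: the animal chooses the left
or the right arm, each arm delivering a solution with a fixed reward value
for the duration of a *session*.  A session ends when the bottles are
swapped, so the side holding the higher-value solution (``high_side``)
alternates across sessions while staying constant within one.

The containers here are deliberately plain: a :class:`Trial` is one choice,
a :class:`MouseRecord` is one animal's ordered choice sequence plus its
session structure, and a :class:`Cohort` is a list of records.  Logs are
plain delimited text (comma by default) so simulated and real cohorts are
interchangeable everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SIDES = ("L", "R")

__all__ = [
    "Trial",
    "Session",
    "MouseRecord",
    "Cohort",
    "SchemaError",
    "ValidationError",
    "OrderingError",
    "read_trial_log",
    "write_trial_log",
    "filter_by_trial_rate",
    "segment_sessions",
]


class SchemaError(ValueError):
    """A required column is missing from a trial log."""


class ValidationError(ValueError):
    """A field value violates its contract."""


class OrderingError(ValueError):
    """Trial indices are not strictly increasing within an animal."""


@dataclass(frozen=True)
class Trial:
    """One T-maze choice.

    ``outcome_label`` is derived: ``"high"`` iff the chosen side is the side
    currently holding the higher-value solution.
    """

    index: int
    session_id: int
    chosen_side: str
    high_side: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"trial index must be >= 1, got {self.index}")
        for name in ("chosen_side", "high_side"):
            v = getattr(self, name)
            if v not in SIDES:
                raise ValidationError(f"{name} must be one of {SIDES}, got {v!r}")

    @property
    def outcome_label(self) -> str:
        return "high" if self.chosen_side == self.high_side else "low"


@dataclass(frozen=True)
class Session:
    """A block of trials with a fixed side-to-solution mapping.

    ``value_high`` is the reward value delivered on ``high_side`` and
    ``value_low`` on the opposite side.  In value sweeps ``high_side`` is the
    *designated* (varying-value) side, so ``value_high - value_low`` may be
    negative.
    """

    session_id: int
    high_side: str
    value_low: float = 1.0
    value_high: float = 3.0
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.high_side not in SIDES:
            raise ValidationError(f"high_side must be one of {SIDES}")
        if self.value_low < 0 or self.value_high < 0:
            raise ValidationError("reward values must be non-negative")
        if self.n_trials < 0:
            raise ValidationError("n_trials must be non-negative")


@dataclass
class MouseRecord:
    """Ordered choice sequence of one animal, with session structure."""

    mouse_id: str
    trials: list[Trial]
    sessions: list[Session]
    days_observed: float = 1.0

    def __post_init__(self) -> None:
        idx = [t.index for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise OrderingError(
                f"mouse {self.mouse_id}: trial indices not strictly increasing"
            )
        known = {s.session_id for s in self.sessions}
        missing = {t.session_id for t in self.trials} - known
        if missing:
            raise ValidationError(
                f"mouse {self.mouse_id}: trials reference unknown sessions {sorted(missing)}"
            )
        counts = {s.session_id: s.n_trials for s in self.sessions}
        actual: dict[int, int] = {}
        for t in self.trials:
            actual[t.session_id] = actual.get(t.session_id, 0) + 1
        for sid, n in actual.items():
            if counts[sid] != n:
                raise ValidationError(
                    f"mouse {self.mouse_id}: session {sid} declares "
                    f"{counts[sid]} trials but has {n}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def trials_per_day(self) -> float:
        return self.n_trials / self.days_observed

    def session_map(self) -> dict[int, Session]:
        return {s.session_id: s for s in self.sessions}

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(chosen, high, session_id) as arrays; sides coded L=0, R=1."""
        chosen = np.fromiter((t.chosen_side == "R" for t in self.trials), dtype=np.int8)
        high = np.fromiter((t.high_side == "R" for t in self.trials), dtype=np.int8)
        sid = np.fromiter((t.session_id for t in self.trials), dtype=np.int64)
        return chosen, high, sid

    def reward_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-trial (chosen, reward, value_on_other_side) under deterministic delivery."""
        chosen, high, sid = self.as_arrays()
        smap = self.session_map()
        vlow = np.array([smap[s].value_low for s in sid], dtype=float)
        vhigh = np.array([smap[s].value_high for s in sid], dtype=float)
        reward = np.where(chosen == high, vhigh, vlow)
        other = np.where(chosen == high, vlow, vhigh)
        return chosen, reward, other

    def mirrored(self) -> "MouseRecord":
        """The same record with every L/R label swapped."""
        flip = {"L": "R", "R": "L"}
        trials = [
            replace(t, chosen_side=flip[t.chosen_side], high_side=flip[t.high_side])
            for t in self.trials
        ]
        sessions = [replace(s, high_side=flip[s.high_side]) for s in self.sessions]
        return MouseRecord(self.mouse_id, trials, sessions, self.days_observed)


@dataclass
class Cohort:
    """A set of mouse records with unique ids."""

    records: list[MouseRecord]
    group_id: str | None = None

    def __post_init__(self) -> None:
        ids = [r.mouse_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("mouse_id must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, mouse_id: str) -> MouseRecord:
        for r in self.records:
            if r.mouse_id == mouse_id:
                return r
        raise KeyError(mouse_id)


_REQUIRED = ("mouse_id", "trial_index", "session_id", "chosen_side", "high_side")


def read_trial_log(path, format_config: Mapping | None = None) -> Cohort:
    """Read a delimited trial log into a :class:`Cohort`.

    ``format_config`` keys: ``delimiter`` (default ``,``; tab accepted),
    ``value_low`` / ``value_high`` defaults used when the file carries no
    per-row value columns (default 1.0 / 3.0, the water/sucrose values).
    """
    cfg = dict(format_config or {})
    delim = cfg.get("delimiter", ",")
    default_low = float(cfg.get("value_low", 1.0))
    default_high = float(cfg.get("value_high", 3.0))

    df = pd.read_csv(path, sep=delim, dtype={"mouse_id": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log is missing column(s): {', '.join(missing)}")

    bad = ~df["chosen_side"].isin(SIDES) | ~df["high_side"].isin(SIDES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValidationError(f"unknown side code at file line {row}")

    has_values = "value_low" in df.columns and "value_high" in df.columns
    records = []
    for mid, sub in df.groupby("mouse_id", sort=False):
        sub = sub.sort_values("trial_index", kind="stable")
        idx = sub["trial_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            raise OrderingError(f"mouse {mid}: duplicate or non-increasing trial_index")
        trials = [
            Trial(int(r.trial_index), int(r.session_id), r.chosen_side, r.high_side)
            for r in sub.itertuples()
        ]
        sessions = []
        for sid, ssub in sub.groupby("session_id", sort=True):
            hs = ssub["high_side"].unique()
            if len(hs) != 1:
                raise ValidationError(
                    f"mouse {mid}: session {sid} has inconsistent high_side"
                )
            vl, vh = default_low, default_high
            if has_values:
                vl = float(ssub["value_low"].iloc[0])
                vh = float(ssub["value_high"].iloc[0])
            sessions.append(Session(int(sid), hs[0], vl, vh, len(ssub)))
        days = float(sub["days_observed"].iloc[0]) if "days_observed" in sub else 1.0
        records.append(MouseRecord(str(mid), trials, sessions, days))
    return Cohort(records)


def write_trial_log(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort as a delimited trial log re-readable by :func:`read_trial_log`."""
    rows = []
    for rec in cohort:
        smap = rec.session_map()
        for t in rec.trials:
            s = smap[t.session_id]
            rows.append(
                {
                    "mouse_id": rec.mouse_id,
                    "trial_index": t.index,
                    "session_id": t.session_id,
                    "chosen_side": t.chosen_side,
                    "high_side": t.high_side,
                    "value_low": s.value_low,
                    "value_high": s.value_high,
                    "days_observed": rec.days_observed,
                }
            )
    cols = [
        "mouse_id",
        "trial_index",
        "session_id",
        "chosen_side",
        "high_side",
        "value_low",
        "value_high",
        "days_observed",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=delimiter, index=False)


def filter_by_trial_rate(cohort: Cohort, min_trials_per_day: float = 5.0) -> Cohort:
    """Keep animals with strictly more than ``min_trials_per_day`` trials/day.

    The inclusion criterion is strict (> not >=): an animal entering the
    maze exactly five times a day over the whole observation window is
    excluded at the default threshold.
    """
    for rec in cohort:
        if rec.days_observed <= 0:
            raise ValidationError(f"mouse {rec.mouse_id}: days_observed must be > 0")
    kept = [r for r in cohort if r.trials_per_day > min_trials_per_day]
    return Cohort(kept, group_id=cohort.group_id)


def segment_sessions(
    trials: Sequence[Trial],
    swap_schedule: Iterable[int] | None = None,
    value_low: float = 1.0,
    value_high: float = 3.0,
) -> list[Session]:
    """Segment a trial sequence into sessions.

    Without a schedule, maximal runs of constant ``high_side`` become
    sessions numbered consecutively from 1.  With ``swap_schedule`` — 1-based
    positions (into the trial sequence) at which a new session starts — the
    declared boundaries are used and a constant ``high_side`` is enforced
    within each declared session.
    """
    trials = list(trials)
    if not trials:
        return []
    if swap_schedule is None:
        boundaries = [0]
        for i in range(1, len(trials)):
            if trials[i].high_side != trials[i - 1].high_side:
                boundaries.append(i)
    else:
        boundaries = sorted({0} | {b - 1 for b in swap_schedule if 1 < b <= len(trials)})
    boundaries.append(len(trials))

    sessions = []
    for sid, (a, b) in enumerate(zip(boundaries, boundaries[1:]), start=1):
        chunk = trials[a:b]
        sides = {t.high_side for t in chunk}
        if len(sides) != 1:
            raise ValidationError(
                f"declared session {sid} mixes high_side values {sorted(sides)}"
            )
        sessions.append(Session(sid, chunk[0].high_side, value_low, value_high, len(chunk)))
    return sessions
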