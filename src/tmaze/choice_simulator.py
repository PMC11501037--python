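"""Generative simulation of T-maze choice sequences.

Agents carry the fitted latent triplet (alpha, beta, chi) of a real or
synthetic animal and replay the task generatively: on every trial the
softmax-with-perseveration policy draws a side, the chosen side delivers its
current solution value deterministically, and the delta rule updates the
chosen side's expected value.  Expected values start at 1 (naive animals
that have only ever known water) and persist across bottle swaps.

On top of the single-animal simulator this module implements the three
counterfactual experiments used to interrogate the fitted parameters:

* :func:`delta_v_sweep` — vary the value difference between sides
  (reference side fixed at 1, the other at 1 + dV) and trace the five choice
  descriptors per profile group;
* :func:`attribution_study` — re-simulate a cohort with its latent
  parameters shuffled across animals (singly or as whole triplets) to ask
  which parameter carries the between-profile differences;
* :func:`cross_context_prediction` — chain a water-vs-sucrose block into a
  saccharin-vs-nicotine block (values 1/3 then 1/0.3) and compare the
  descriptors across blocks.

Replicates use common random numbers across the swept condition (the child
seed depends on the group and replicate index, not on dV), so condition
contrasts are not inflated by simulation noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import DESCRIPTOR_COLUMNS, descriptor_vector
from .random_utils import child_rng
from .rl_model import LatentTriplet
from .trial_data import Cohort, MouseRecord, Session, Trial

__all__ = [
    "SessionSchedule",
    "standard_schedule",
    "SweepResult",
    "AttributionResult",
    "simulate_mouse",
    "simulate_cohort",
    "delta_v_sweep",
    "attribution_study",
    "cross_context_prediction",
    "archetype_separation",
]


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered session plan for a simulation.

    ``sessions`` holds (n_trials, high_side, value_low, value_high) per
    session; ``v0`` is the initial expected value of both sides (1 by
    default: before the task the animals have only ever earned water).
    """

    sessions: tuple[tuple[int, str, float, float], ...]
    v0: float = 1.0

    def __post_init__(self) -> None:
        for i, (n, side, vl, vh) in enumerate(self.sessions, 1):
            if n < 1:
                raise ValueError(f"session {i}: n_trials must be >= 1")
            if side not in ("L", "R"):
                raise ValueError(f"session {i}: high_side must be L or R")
            if vl < 0 or vh < 0:
                raise ValueError(f"session {i}: negative reward value unsupported")

    @property
    def n_trials(self) -> int:
        return sum(s[0] for s in self.sessions)

    def session_objects(self, start_id: int = 1) -> list[Session]:
        return [
            Session(start_id + i, side, vl, vh, n)
            for i, (n, side, vl, vh) in enumerate(self.sessions)
        ]

    def trial_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-trial (high, value_low, value_high, session_id); high coded L=0/R=1."""
        high, vlow, vhigh, sid = [], [], [], []
        for i, (n, side, vl, vh) in enumerate(self.sessions, 1):
            high += [1 if side == "R" else 0] * n
            vlow += [vl] * n
            vhigh += [vh] * n
            sid += [i] * n
        return (
            np.asarray(high, dtype=np.int8),
            np.asarray(vlow, dtype=float),
            np.asarray(vhigh, dtype=float),
            np.asarray(sid, dtype=np.int64),
        )


def standard_schedule(
    n_sessions: int = 6,
    n_trials: int = 50,
    value_low: float = 1.0,
    value_high: float = 3.0,
    start_side: str = "L",
    alternate: bool = True,
    v0: float = 1.0,
) -> SessionSchedule:
    """The default task: sessions of 50 choices, high side alternating."""
    sides = ("L", "R") if start_side == "L" else ("R", "L")
    sess = tuple(
        (n_trials, sides[i % 2] if alternate else sides[0], value_low, value_high)
        for i in range(n_sessions)
    )
    return SessionSchedule(sess, v0=v0)


def _sim_core_py(u, high, vlow, vhigh, alpha, beta, chi, v_l, v_r, prev):
    """Sequential policy rollout; returns (choices, v_l, v_r, prev)."""
    n = u.shape[0]
    choices = np.empty(n, dtype=np.int8)
    for t in range(n):
        z = beta * (v_r - v_l) + chi * prev
        if z >= 0:
            p_r = 1.0 / (1.0 + math.exp(-z))
        else:
            e = math.exp(z)
            p_r = e / (1.0 + e)
        c = 1 if u[t] < p_r else 0
        choices[t] = c
        reward = vhigh[t] if c == high[t] else vlow[t]
        if c == 1:
            v_r = v_r + alpha * (reward - v_r)
            prev = 1.0
        else:
            v_l = v_l + alpha * (reward - v_l)
            prev = -1.0
    return choices, v_l, v_r, prev


try:
    from numba import njit

    _sim_core = njit(cache=False)(_sim_core_py)
    _sim_core(
        np.zeros(1), np.zeros(1, dtype=np.int8), np.ones(1), np.ones(1),
        0.5, 1.0, 0.0, 1.0, 1.0, 0.0,
    )
except Exception:  # pragma: no cover
    _sim_core = _sim_core_py


def simulate_mouse(
    triplet: LatentTriplet,
    schedule: SessionSchedule,
    seed: int | np.random.Generator | None = None,
    mouse_id: str = "sim",
    days_observed: float | None = None,
) -> MouseRecord:
    """Simulate one animal through a session schedule.

    Deterministic given (triplet, schedule, seed).  ``days_observed``
    defaults to 3 days per session (the bottle-swap cadence).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    high, vlow, vhigh, sid = schedule.trial_arrays()
    u = rng.random(len(high))
    choices, *_ = _sim_core(
        u, high, vlow, vhigh,
        float(triplet.alpha), float(triplet.beta), float(triplet.chi),
        float(schedule.v0), float(schedule.v0), 0.0,
    )
    if days_observed is None:
        days_observed = 3.0 * len(schedule.sessions)
    return _record_from_choices(mouse_id, choices, high, sid, schedule, days_observed)


def _record_from_choices(mouse_id, choices, high, sid, schedule, days_observed):
    side = np.array(["L", "R"])
    trials = [
        Trial(t + 1, int(sid[t]), side[choices[t]], side[high[t]])
        for t in range(len(choices))
    ]
    return MouseRecord(mouse_id, trials, schedule.session_objects(), days_observed)


def simulate_cohort(
    triplets: Sequence[LatentTriplet],
    schedule: SessionSchedule,
    seed: int | None = None,
    mouse_ids: Sequence[str] | None = None,
    group_id: str | None = None,
) -> Cohort:
    """Simulate one animal per triplet; child seeds spawn from the master seed."""
    if len(triplets) == 0:
        raise ValueError("triplets must be non-empty")
    if mouse_ids is None:
        mouse_ids = [f"sim_{i + 1:03d}" for i in range(len(triplets))]
    records = [
        simulate_mouse(tr, schedule, seed=child_rng(seed, i), mouse_id=mid)
        for i, (tr, mid) in enumerate(zip(triplets, mouse_ids))
    ]
    return Cohort(records, group_id=group_id)


@dataclass
class SweepResult:
    """Descriptor statistics per (group, dV) from a value sweep."""

    table: pd.DataFrame  # columns: group, dv, descriptor, mean, sd
    dv_grid: tuple[float, ...]
    n_replicates: int
    seed: int | None

    def mean(self, group: str, dv: float, descriptor: str) -> float:
        t = self.table
        row = t[(t.group == group) & (t.dv == dv) & (t.descriptor == descriptor)]
        return float(row["mean"].iloc[0])


def delta_v_sweep(
    triplets_by_group: Mapping[str, Sequence[LatentTriplet]],
    dv_grid: Sequence[float] = (-1.0, 0.0, 1.0, 2.0, 3.0),
    n_sessions: int = 6,
    n_trials: int = 50,
    n_replicates: int = 200,
    seed: int | None = None,
) -> SweepResult:
    """Sweep the value difference between sides and trace the descriptors.

    The reference side is fixed at value 1; the designated (alternating)
    side delivers ``1 + dV``, so the descriptor ``pref`` measures choice of
    the varying-value side.  Replicate r of group g uses the child seed
    ``(g_index, r)`` for every dV (common random numbers), and draws its
    triplet round-robin from the group's list.
    """
    for dv in dv_grid:
        if 1.0 + dv < 0:
            raise ValueError(f"dV = {dv} implies a negative reward value")
    rows = []
    for gi, (group, triplets) in enumerate(triplets_by_group.items()):
        if len(triplets) == 0:
            raise ValueError(f"group {group!r} has no triplets")
        for dv in dv_grid:
            vals = {c: [] for c in DESCRIPTOR_COLUMNS}
            for r in range(n_replicates):
                tr = triplets[r % len(triplets)]
                sched = standard_schedule(
                    n_sessions, n_trials, value_low=1.0, value_high=1.0 + dv
                )
                rec = simulate_mouse(tr, sched, seed=child_rng(seed, gi, r))
                for c, v in descriptor_vector(rec).items():
                    vals[c].append(v)
            for c in DESCRIPTOR_COLUMNS:
                arr = np.asarray(vals[c], dtype=float)
                rows.append(
                    {
                        "group": group,
                        "dv": float(dv),
                        "descriptor": c,
                        "mean": float(np.nanmean(arr)),
                        "sd": float(np.nanstd(arr, ddof=1)),
                    }
                )
    return SweepResult(pd.DataFrame(rows), tuple(float(d) for d in dv_grid),
                       n_replicates, seed)


ATTRIBUTION_MODES = (
    "own",
    "random_triplet",
    "shuffle_alpha",
    "shuffle_beta",
    "shuffle_chi",
    "random_triplet_empirical_trials",
)


@dataclass
class AttributionResult:
    """Descriptors of a re-simulated cohort under one attribution mode."""

    per_animal: pd.DataFrame  # mouse_id, label, the five descriptors
    summary: pd.DataFrame  # label x descriptor means
    mode: str
    seed: int | None


def attribution_study(
    cohort_fits: pd.DataFrame,
    mode: str,
    n_sessions: int = 6,
    n_trials: int = 50,
    seed: int | None = None,
) -> AttributionResult:
    """Re-simulate a fitted cohort with latent parameters reassigned.

    ``cohort_fits`` needs columns ``mouse_id, alpha, beta, chi, label``
    (and ``trials_per_day`` for the empirical-trials mode).  Modes: ``own``
    keeps each animal's triplet; ``random_triplet`` permutes whole triplets
    across animals; ``shuffle_alpha``/``shuffle_beta``/``shuffle_chi``
    permute a single parameter, keeping the other two; and
    ``random_triplet_empirical_trials`` additionally sets each animal's
    session length to round(3 x its trials/day).  Summaries are always
    grouped by the animal's *original* archetype label.  Shuffles are
    permutations (sampling without replacement), so parameter marginals are
    preserved exactly.
    """
    if mode not in ATTRIBUTION_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {ATTRIBUTION_MODES}")
    df = cohort_fits.reset_index() if "mouse_id" not in cohort_fits.columns else cohort_fits
    df = df.copy()
    rng = child_rng(seed, 999)  # shuffling stream, separate from simulation streams
    n = len(df)
    if mode in ("random_triplet", "random_triplet_empirical_trials"):
        perm = rng.permutation(n)
        df[["alpha", "beta", "chi"]] = df[["alpha", "beta", "chi"]].to_numpy()[perm]
    elif mode.startswith("shuffle_"):
        col = mode.removeprefix("shuffle_")
        df[col] = df[col].to_numpy()[rng.permutation(n)]

    rows = []
    for i, r in enumerate(df.itertuples()):
        if mode == "random_triplet_empirical_trials":
            nt = max(1, round(float(r.trials_per_day) * 3.0))
        else:
            nt = n_trials
        sched = standard_schedule(n_sessions, nt)
        tr = LatentTriplet(float(r.alpha), float(r.beta), float(r.chi))
        rec = simulate_mouse(tr, sched, seed=child_rng(seed, i), mouse_id=str(r.mouse_id))
        rows.append({"mouse_id": r.mouse_id, "label": r.label, **descriptor_vector(rec)})
    per_animal = pd.DataFrame(rows)
    summary = per_animal.groupby("label")[list(DESCRIPTOR_COLUMNS)].mean()
    return AttributionResult(per_animal, summary, mode, seed)


def archetype_separation(per_animal: pd.DataFrame) -> float:
    """Mean absolute between-group gap of descriptor means.

    Averages |mean_g1 - mean_g2| over every unordered group pair and every
    descriptor — the scalar used to quantify how strongly a (re)simulated
    cohort separates the archetype groups.
    """
    means = per_animal.groupby("label")[list(DESCRIPTOR_COLUMNS)].mean()
    groups = list(means.index)
    gaps = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gaps.append(np.abs(means.loc[groups[i]] - means.loc[groups[j]]).to_numpy())
    return float(np.mean(gaps))


def cross_context_prediction(
    triplets: Sequence[LatentTriplet],
    labels: Sequence[str] | None = None,
    n_sessions_per_block: int = 6,
    n_trials: int = 50,
    values_block1: tuple[float, float] = (1.0, 3.0),
    values_block2: tuple[float, float] = (1.0, 0.3),
    carry_values: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Predict behavior across a change of reward context.

    One continuous simulation of 2 x ``n_sessions_per_block`` sessions: the
    first block pits water (1) against sucrose (3), the second saccharin (1)
    against nicotine+saccharin (0.3), with the designated side alternating
    throughout.  Learned values carry over at the block boundary by default
    (``carry_values=False`` resets them to v0 for sensitivity analysis).
    Returns one row per animal per block with the five descriptors; ``pref``
    is measured toward the varying-value side (sucrose, then nicotine).
    """
    if len(triplets) == 0:
        raise ValueError("triplets must be non-empty")
    if labels is not None and len(labels) != len(triplets):
        raise ValueError("labels must match triplets in length")

    vl1, vh1 = values_block1
    vl2, vh2 = values_block2
    sched1 = standard_schedule(n_sessions_per_block, n_trials, vl1, vh1, start_side="L")
    side2 = "L" if n_sessions_per_block % 2 == 0 else "R"
    sched2 = standard_schedule(n_sessions_per_block, n_trials, vl2, vh2, start_side=side2)

    rows = []
    for i, tr in enumerate(triplets):
        rng = child_rng(seed, i)
        h1, l1, v1, s1 = sched1.trial_arrays()
        u1 = rng.random(len(h1))
        c1, vl, vr, prev = _sim_core(
            u1, h1, l1, v1, tr.alpha, tr.beta, tr.chi, sched1.v0, sched1.v0, 0.0
        )
        if not carry_values:
            vl = vr = sched2.v0
        h2, l2, v2, s2 = sched2.trial_arrays()
        u2 = rng.random(len(h2))
        c2, *_ = _sim_core(u2, h2, l2, v2, tr.alpha, tr.beta, tr.chi, vl, vr, prev)

        rec1 = _record_from_choices(f"sim_{i + 1:03d}", c1, h1, s1, sched1, 3.0 * n_sessions_per_block)
        rec2 = _record_from_choices(f"sim_{i + 1:03d}", c2, h2, s2, sched2, 3.0 * n_sessions_per_block)
        for block, rec in (("WS", rec1), ("SaN", rec2)):
            row = {"mouse_id": rec.mouse_id, "block": block, **descriptor_vector(rec)}
            if labels is not None:
                row["label"] = labels[i]
            rows.append(row)
    return pd.DataFrame(rows)
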