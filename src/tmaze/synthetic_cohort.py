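"""Fully synthetic cohorts with a ground-truth manifest.

Each animal is drawn from one of three latent behavioral profiles and
leaves two traces, mirroring what the live setup records:

* a T-maze choice log, produced by the generative policy of
  :mod:`tmaze.choice_simulator` from a latent triplet drawn uniformly from
  the profile's prior range — Trackers learn fast but choose softly (high
  learning rate, low inverse temperature), Explorers sit in an intermediate
  regime, and Non-Switchers barely learn but choose near-deterministically
  (very low learning rate, high inverse temperature), which glues them to
  one side; and
* a home-cage RFID event stream from a continuous-time Markov chain over
  the five compartments with profile-specific transition structure and
  dwell scales: Trackers transit most and head for the stair, Explorers
  favour the nest/food side of the hub, Non-Switchers sit long in the nest.
  Transition rates triple in the dark phase, and nest dwells in the light
  phase mix in a multi-hour resting component, reproducing the circadian
  activity pattern and the bimodal nest-dwell distribution of real streams.

Everything is reproducible from one master seed; the manifest records each
animal's profile, true triplet and trial rate for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .choice_simulator import SessionSchedule, simulate_mouse, standard_schedule
from .random_utils import child_rng
from .rl_model import LatentTriplet
from .tracking_metrics import COMPARTMENTS
from .trial_data import Cohort

PROFILES = ("Tracker", "Explorer", "NonSwitcher")
_SHORT = {"Tracker": "Tr", "Explorer": "Ex", "NonSwitcher": "NS"}

__all__ = [
    "PROFILES",
    "ProfilePrior",
    "default_profile_priors",
    "generate_cohort",
    "generate_tracking",
]


@dataclass(frozen=True)
class ProfilePrior:
    """Uniform prior box for one behavioral profile, plus its home-cage chain.

    ``transition_matrix`` is the embedded jump chain over (N, F, C, S, T)
    with zero diagonal; ``dwell_scale`` gives the mean dwell (seconds) per
    compartment in the light phase.  ``night_multiplier`` scales transition
    rates in the dark phase; ``nest_rest`` = (probability, mean seconds) of
    a long resting dwell when entering the nest during the light phase.
    """

    profile: str
    alpha_range: tuple[float, float]
    beta_range: tuple[float, float]
    chi_range: tuple[float, float] = (-1.0, 1.0)
    trials_per_day_range: tuple[float, float] = (5.0, 25.0)
    transition_matrix: np.ndarray | None = None
    dwell_scale: Mapping[str, float] | None = None
    night_multiplier: float = 3.0
    nest_rest: tuple[float, float] = (0.3, 10800.0)

    def __post_init__(self) -> None:
        if not (0 < self.alpha_range[0] <= self.alpha_range[1] <= 1):
            raise ValueError(f"{self.profile}: alpha range outside (0, 1]")
        if not (0 < self.beta_range[0] <= self.beta_range[1] <= 20):
            raise ValueError(f"{self.profile}: beta range outside (0, 20]")
        if not (-2 <= self.chi_range[0] <= self.chi_range[1] <= 2):
            raise ValueError(f"{self.profile}: chi range outside [-2, 2]")
        if self.transition_matrix is not None:
            P = np.asarray(self.transition_matrix, dtype=float)
            if P.shape != (5, 5) or np.any(P < 0) or np.any(np.diag(P) != 0):
                raise ValueError(f"{self.profile}: invalid jump matrix")
            if not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError(f"{self.profile}: jump matrix rows must sum to 1")

    def draw_triplet(self, rng: np.random.Generator) -> LatentTriplet:
        return LatentTriplet(
            alpha=float(rng.uniform(*self.alpha_range)),
            beta=float(rng.uniform(*self.beta_range)),
            chi=float(rng.uniform(*self.chi_range)),
        )


def _jump_matrix(c_row: Mapping[str, float], s_to_t: float) -> np.ndarray:
    """Hub-topology jump chain: N,F touch only C; S touches C and T; T only S."""
    idx = {c: i for i, c in enumerate(COMPARTMENTS)}
    P = np.zeros((5, 5))
    P[idx["N"], idx["C"]] = 1.0
    P[idx["F"], idx["C"]] = 1.0
    P[idx["T"], idx["S"]] = 1.0
    for dest, p in c_row.items():
        P[idx["C"], idx[dest]] = p
    P[idx["S"], idx["T"]] = s_to_t
    P[idx["S"], idx["C"]] = 1.0 - s_to_t
    return P


def default_profile_priors() -> list[ProfilePrior]:
    """The declared defaults for the three profiles.

    Latent-parameter boxes encode the profile signatures (Tracker high
    learning rate / low inverse temperature; Explorer intermediate;
    Non-Switcher the reverse) and the home-cage chains encode the observed
    sign structure: Trackers transit most and route the hub toward the
    stair, Explorers toward nest and food, Non-Switchers rest in the nest.
    """
    return [
        ProfilePrior(
            profile="Tracker",
            alpha_range=(0.5, 0.95),
            beta_range=(0.5, 2.5),
            trials_per_day_range=(15.0, 25.0),
            transition_matrix=_jump_matrix({"N": 0.25, "F": 0.15, "S": 0.60}, s_to_t=0.60),
            dwell_scale={"N": 900.0, "F": 180.0, "C": 40.0, "S": 60.0, "T": 180.0},
            nest_rest=(0.25, 9000.0),
        ),
        ProfilePrior(
            profile="Explorer",
            alpha_range=(0.1, 0.35),
            beta_range=(0.2, 0.7),
            trials_per_day_range=(10.0, 18.0),
            transition_matrix=_jump_matrix({"N": 0.40, "F": 0.35, "S": 0.25}, s_to_t=0.75),
            dwell_scale={"N": 1200.0, "F": 300.0, "C": 60.0, "S": 90.0, "T": 150.0},
            nest_rest=(0.3, 10800.0),
        ),
        ProfilePrior(
            profile="NonSwitcher",
            alpha_range=(0.01, 0.05),
            beta_range=(3.0, 10.0),
            trials_per_day_range=(5.0, 10.0),
            transition_matrix=_jump_matrix({"N": 0.55, "F": 0.30, "S": 0.15}, s_to_t=0.30),
            dwell_scale={"N": 2400.0, "F": 300.0, "C": 80.0, "S": 120.0, "T": 200.0},
            nest_rest=(0.5, 12600.0),
        ),
    ]


def generate_tracking(
    profile_prior: ProfilePrior,
    days: float,
    seed: int | np.random.Generator | None = None,
    mouse_id: str = "sim",
    day_length: float = 86400.0,
) -> pd.DataFrame:
    """Simulate a home-cage RFID event stream for one animal.

    Continuous-time Markov chain over the five compartments: dwell times
    are exponential with the prior's per-compartment scale, divided by
    ``night_multiplier`` in the dark phase (the second half of each day;
    time 0 is lights-on), and nest entries in the light phase draw a long
    resting dwell with the prior's ``nest_rest`` probability.  One event is
    emitted per compartment entry.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if profile_prior.transition_matrix is None or profile_prior.dwell_scale is None:
        raise ValueError(f"{profile_prior.profile}: prior lacks tracking parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = np.asarray(profile_prior.transition_matrix, dtype=float)
    scales = np.array([profile_prior.dwell_scale[c] for c in COMPARTMENTS])
    idx = {c: i for i, c in enumerate(COMPARTMENTS)}

    t = 0.0
    loc = idx["N"]
    end = days * day_length
    times, locs = [0.0], ["N"]
    p_rest, rest_scale = profile_prior.nest_rest
    while True:
        is_light = (t % day_length) < day_length / 2.0
        scale = scales[loc]
        if loc == idx["N"] and is_light and rng.random() < p_rest:
            scale = rest_scale
        if not is_light:
            scale = scale / profile_prior.night_multiplier
        t = t + rng.exponential(scale)
        if t >= end:
            break
        loc = int(rng.choice(5, p=P[loc]))
        times.append(t)
        locs.append(COMPARTMENTS[loc])
    return pd.DataFrame({"mouse_id": mouse_id, "time_s": times, "location": locs})


def generate_cohort(
    n_per_profile: int | Mapping[str, int] = 20,
    schedule: SessionSchedule | None = None,
    seed: int | None = None,
    priors: Sequence[ProfilePrior] | None = None,
    tracking_days: float = 10.0,
    n_sessions: int = 6,
) -> tuple[Cohort, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns ``(choice_cohort, event_log, manifest)``.  With no explicit
    ``schedule``, each animal runs ``n_sessions`` alternating sessions of
    ``round(3 x trials/day)`` choices at water/sucrose values (1, 3) — three
    days between bottle swaps — with its trial rate drawn from the profile
    prior.  The manifest holds one row per animal: profile, true triplet,
    trials/day.
    """
    priors = list(priors) if priors is not None else default_profile_priors()
    if isinstance(n_per_profile, int):
        counts = {p.profile: n_per_profile for p in priors}
    else:
        counts = dict(n_per_profile)
    for p in priors:
        if counts.get(p.profile, 0) < 1:
            raise ValueError(f"n_per_profile must be >= 1 for {p.profile}")

    records, events, manifest = [], [], []
    for pi, prior in enumerate(priors):
        for ai in range(counts[prior.profile]):
            mid = f"{_SHORT.get(prior.profile, prior.profile)}_{ai + 1:02d}"
            rng_draw = child_rng(seed, pi, ai, 0)
            triplet = prior.draw_triplet(rng_draw)
            tpd = float(rng_draw.uniform(*prior.trials_per_day_range))
            if schedule is None:
                sched = standard_schedule(n_sessions, max(1, round(tpd * 3.0)))
                days = 3.0 * n_sessions
            else:
                sched = schedule
                days = 3.0 * len(schedule.sessions)
            rec = simulate_mouse(
                triplet, sched, seed=child_rng(seed, pi, ai, 1),
                mouse_id=mid, days_observed=days,
            )
            records.append(rec)
            events.append(
                generate_tracking(prior, tracking_days,
                                  seed=child_rng(seed, pi, ai, 2), mouse_id=mid)
            )
            manifest.append({
                "mouse_id": mid, "profile": prior.profile,
                "alpha": triplet.alpha, "beta": triplet.beta, "chi": triplet.chi,
                "trials_per_day": tpd,
            })
    return (
        Cohort(records),
        pd.concat(events, ignore_index=True),
        pd.DataFrame(manifest),
    )
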