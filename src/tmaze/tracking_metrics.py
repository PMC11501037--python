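"""Home-cage RFID analytics.

The living environment is a square cage of four social compartments — nest
(N), food (F), a central hub (C) and a stair (S) — plus the T-maze test
zone (T) reached through the stair.  RFID antennae log each animal's
position as a time-stamped event stream; this module turns those streams
into per-animal metrics:

* residency episodes (maximal dwells in one compartment),
* occupancy fractions and their Shannon entropy (EnA, nats),
* daily detection counts (NbD, compartment transitions per day) and a
  24-hour circadian histogram,
* conditional transition probabilities, first order (direct moves) and
  second order (hub-mediated: from a non-hub compartment to the next
  non-hub compartment reached, however many hub visits intervene),
* a fluid-consumption estimator from daily bottle weight changes, and
* correlation / regression of any metric against archetypal composition.

Event logs are delimited text with columns ``mouse_id, time_s, location``.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

COMPARTMENTS = ("N", "F", "C", "S", "T")
#: Hub-mediated (second-order) transition pairs reported in the metrics table.
SECOND_ORDER_PAIRS = (("N", "F"), ("N", "S"), ("F", "N"), ("F", "S"), ("S", "N"), ("S", "F"))
DAY_SECONDS = 86400.0

__all__ = [
    "COMPARTMENTS",
    "read_event_log",
    "write_event_log",
    "residency_episodes",
    "occupancy_fractions",
    "transition_probabilities",
    "activity_summary",
    "metrics_table",
    "estimate_consumption",
    "correlate_with_composition",
]


def read_event_log(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype={"mouse_id": str, "location": str})
    for col in ("mouse_id", "time_s", "location"):
        if col not in df.columns:
            raise ValueError(f"event log is missing column {col!r}")
    return df


def write_event_log(events: pd.DataFrame, path, delimiter: str = ",") -> None:
    events[["mouse_id", "time_s", "location"]].to_csv(path, sep=delimiter, index=False)


def _check_events(events: pd.DataFrame) -> pd.DataFrame:
    bad = set(events["location"]) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown location code(s): {sorted(bad)}")
    for mid, sub in events.groupby("mouse_id", sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError(f"mouse {mid}: timestamps decrease")
    return events


def residency_episodes(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse each animal's event stream into residency episodes.

    Maximal runs of the same location become one episode with
    ``duration = next run start - run start``; the final episode is closed
    at the animal's last event time and flagged ``open``.
    """
    _check_events(events)
    rows = []
    for mid, sub in events.groupby("mouse_id", sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        loc = sub["location"].to_numpy()
        if len(t) == 0:
            continue
        starts = [0] + [i for i in range(1, len(loc)) if loc[i] != loc[i - 1]]
        for a, b in zip(starts, starts[1:] + [None]):
            if b is None:
                rows.append({"mouse_id": mid, "location": loc[a], "start": t[a],
                             "duration": t[-1] - t[a], "open": True})
            else:
                rows.append({"mouse_id": mid, "location": loc[a], "start": t[a],
                             "duration": t[b] - t[a], "open": False})
    return pd.DataFrame(rows, columns=["mouse_id", "location", "start", "duration", "open"])


def occupancy_fractions(events: pd.DataFrame) -> pd.DataFrame:
    """Per-animal fraction of observed time in each compartment (rows sum to 1)."""
    ep = residency_episodes(events)
    out = {}
    for mid, sub in ep.groupby("mouse_id", sort=False):
        tot = sub["duration"].sum()
        occ = {}
        for comp in COMPARTMENTS:
            d = sub.loc[sub["location"] == comp, "duration"].sum()
            occ[comp] = d / tot if tot > 0 else math.nan
        out[mid] = occ
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "mouse_id"
    return df[list(COMPARTMENTS)]


def _location_runs(sub: pd.DataFrame) -> np.ndarray:
    loc = sub["location"].to_numpy()
    if len(loc) == 0:
        return loc
    keep = np.ones(len(loc), dtype=bool)
    keep[1:] = loc[1:] != loc[:-1]
    return loc[keep]


def transition_probabilities(events: pd.DataFrame, order: int = 1) -> pd.DataFrame:
    """Conditional transition probabilities P(destination | source) per animal.

    ``order=1`` counts direct moves between consecutive distinct locations.
    ``order=2`` counts hub-mediated moves: from each visit to a non-hub
    source, the next non-hub compartment reached (skipping any number of
    consecutive hub (C) visits).  Sources never left are absent from the
    table.  Returns tidy rows ``mouse_id, source, dest, prob, n``.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    _check_events(events)
    rows = []
    for mid, sub in events.groupby("mouse_id", sort=False):
        runs = _location_runs(sub)
        counts: dict[tuple[str, str], int] = {}
        if order == 1:
            for a, b in zip(runs, runs[1:]):
                counts[(a, b)] = counts.get((a, b), 0) + 1
        else:
            for i, src in enumerate(runs):
                if src == "C":
                    continue
                j = i + 1
                while j < len(runs) and runs[j] == "C":
                    j += 1
                if j < len(runs):
                    counts[(src, runs[j])] = counts.get((src, runs[j]), 0) + 1
        totals: dict[str, int] = {}
        for (src, _), n in counts.items():
            totals[src] = totals.get(src, 0) + n
        for (src, dst), n in sorted(counts.items()):
            rows.append({"mouse_id": mid, "source": src, "dest": dst,
                         "prob": n / totals[src], "n": n})
    return pd.DataFrame(rows, columns=["mouse_id", "source", "dest", "prob", "n"])


def activity_summary(
    events: pd.DataFrame, day_length: float = DAY_SECONDS
) -> pd.DataFrame:
    """Per-animal activity metrics: NbD, circadian histogram, EnA.

    NbD is the number of compartment transitions per day averaged over the
    observed span; the circadian histogram gives mean transitions per hourly
    bin per day (columns ``h00..h23``); EnA is the Shannon entropy (nats) of
    the occupancy-time distribution over the five compartments, between 0
    (single compartment) and ln 5 (uniform).
    """
    _check_events(events)
    occ = occupancy_fractions(events)
    rows = {}
    for mid, sub in events.groupby("mouse_id", sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        runs_mask = np.ones(len(sub), dtype=bool)
        loc = sub["location"].to_numpy()
        runs_mask[1:] = loc[1:] != loc[:-1]
        trans_times = t[runs_mask][1:]  # each run start after the first is a transition
        span = t[-1] - t[0] if len(t) > 1 else 0.0
        days = span / day_length
        if days < 1.0:
            warnings.warn(f"mouse {mid}: observation span below one day; "
                          "metrics computed over the actual span")
            days = max(days, 1e-9)
        hour = ((trans_times % day_length) / day_length * 24).astype(int)
        hist = np.bincount(hour, minlength=24)[:24] / days
        p = occ.loc[mid].to_numpy(dtype=float)
        p = p[np.isfinite(p) & (p > 0)]
        ena = float(-(p * np.log(p)).sum()) if len(p) else math.nan
        row = {"nbd": len(trans_times) / days, "ena": ena}
        row.update({f"h{h:02d}": hist[h] for h in range(24)})
        rows[mid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "mouse_id"
    return df


def metrics_table(events: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-animal home-cage metrics table.

    Columns: ``nbd``, ``ena``, occupancy ``occ_N..occ_T``, first-order
    transition probabilities out of the hub and stair (``CtoN, CtoF, CtoS,
    StoC, StoT``) and the hub-mediated second-order probabilities
    (``NtoF, NtoS, FtoN, FtoS, StoN, StoF``).  Unobserved transitions are NaN.
    """
    act = activity_summary(events)[["nbd", "ena"]]
    occ = occupancy_fractions(events).rename(columns=lambda c: f"occ_{c}")
    t1 = transition_probabilities(events, order=1)
    t2 = transition_probabilities(events, order=2)

    def pick(t, src, dst):
        sel = t[(t.source == src) & (t.dest == dst)].set_index("mouse_id")["prob"]
        return sel

    cols = {}
    for src, dst in (("C", "N"), ("C", "F"), ("C", "S"), ("S", "C"), ("S", "T")):
        cols[f"{src}to{dst}"] = pick(t1, src, dst)
    for src, dst in SECOND_ORDER_PAIRS:
        cols[f"{src}to{dst}"] = pick(t2, src, dst)
    trans = pd.DataFrame(cols)
    out = act.join(occ, how="outer").join(trans, how="outer")
    out.index.name = "mouse_id"
    return out


def estimate_consumption(daily_bottle_deltas: pd.DataFrame) -> float:
    """Daily fluid consumption (ml/day) from bottle weight changes.

    Each row is one day with the measured fluid change on the chosen side
    (``chosen``) and the non-chosen side (``non_chosen``); the latter
    estimates evaporation and handling loss and is subtracted.  Days with a
    missing measurement are excluded; negative changes beyond 0.1 ml are
    flagged (a bottle was refilled or misweighed) but not clipped.
    """
    df = daily_bottle_deltas
    for col in ("chosen", "non_chosen"):
        if col not in df.columns:
            raise ValueError(f"daily deltas need a {col!r} column")
    ok = df["chosen"].notna() & df["non_chosen"].notna()
    sub = df[ok]
    if (sub[["chosen", "non_chosen"]].to_numpy() < -0.1).any():
        warnings.warn("negative bottle delta beyond tolerance; day kept, check the log")
    if len(sub) == 0:
        return math.nan
    return float((sub["chosen"] - sub["non_chosen"]).mean())


def correlate_with_composition(
    metrics: pd.DataFrame,
    composition: pd.DataFrame,
    regression_pairs: Iterable[tuple[str, str]] | None = None,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate home-cage metrics with archetypal composition.

    Joins the two tables on ``mouse_id`` and returns

    * a tidy correlation table (Pearson r, two-sided p, n) for every
      metric x composition column pair with at least ``min_pairs`` complete
      observations (others are NaN), and
    * an ordinary-least-squares table (slope, adjusted R², slope p) for the
      requested ``regression_pairs`` (default: all pairs).
    """
    comp_cols = [c for c in composition.columns if c.startswith("alpha_")]
    if not comp_cols:
        comp_cols = [c for c in composition.columns
                     if np.issubdtype(composition[c].dtype, np.number)]
    joined = metrics.join(composition[comp_cols], how="inner")
    metric_cols = [c for c in metrics.columns
                   if np.issubdtype(metrics[c].dtype, np.number)]

    corr_rows = []
    for mcol in metric_cols:
        for ccol in comp_cols:
            sub = joined[[mcol, ccol]].dropna()
            if len(sub) < min_pairs or sub[mcol].nunique() < 2 or sub[ccol].nunique() < 2:
                r, p = math.nan, math.nan
            else:
                r, p = stats.pearsonr(sub[mcol], sub[ccol])
            corr_rows.append({"metric": mcol, "composition": ccol,
                              "r": float(r), "p": float(p), "n": len(sub)})
    corr = pd.DataFrame(corr_rows)

    pairs = list(regression_pairs) if regression_pairs is not None else [
        (m, c) for m in metric_cols for c in comp_cols
    ]
    reg_rows = []
    for mcol, ccol in pairs:
        sub = joined[[mcol, ccol]].dropna()
        if len(sub) < min_pairs or sub[ccol].nunique() < 2:
            reg_rows.append({"metric": mcol, "composition": ccol, "slope": math.nan,
                             "adj_r2": math.nan, "slope_p": math.nan, "n": len(sub)})
            continue
        X = sm.add_constant(sub[ccol].to_numpy())
        fit = sm.OLS(sub[mcol].to_numpy(), X).fit()
        reg_rows.append({
            "metric": mcol, "composition": ccol,
            "slope": float(fit.params[1]),
            "adj_r2": float(fit.rsquared_adj),
            "slope_p": float(fit.pvalues[1]),
            "n": len(sub),
        })
    return corr, pd.DataFrame(reg_rows)
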