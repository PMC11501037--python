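"""The five per-animal choice descriptors and the descriptor matrix.

For each animal the choice sequence is summarised by five statistics, all
fractions in [0, 1]:

``switch``
    Global side balance, ``1 - |p_L - p_R|`` over all trials pooled: 0 for an
    animal that visits a single side, 1 for an exactly even split.
``sw_low`` / ``sw_high``
    Probability of changing side after a low-value (water) or high-value
    (sucrose) outcome, over consecutive within-session trial pairs.
``pref``
    Mean over sessions of the fraction of choices on the designated
    higher-value side (sucrose preference when values are 1 vs 3).
``side_bias``
    ``|2 m - 1|`` where m is the mean over sessions of the left-choice
    fraction.  Because the high-value side alternates across sessions, the
    per-session mean cancels reward tracking and isolates a fixed side
    preference.

Undefined statistics (no qualifying trials/pairs) are returned as NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import Cohort, MouseRecord

DESCRIPTOR_COLUMNS = ("switch", "sw_low", "sw_high", "pref", "side_bias")

__all__ = [
    "DESCRIPTOR_COLUMNS",
    "DescriptorMatrix",
    "switch_index",
    "conditional_switch",
    "preference",
    "side_bias",
    "descriptor_vector",
    "descriptor_matrix",
    "classify_nonswitcher_origin",
]


def switch_index(record: MouseRecord) -> float:
    """Global switching level: 1 - |p_L - p_R| over all trials pooled."""
    if record.n_trials == 0:
        return math.nan
    chosen, _, _ = record.as_arrays()
    p_r = float(chosen.mean())
    return 1.0 - abs((1.0 - p_r) - p_r)


def conditional_switch(record: MouseRecord, outcome_class: str) -> float:
    """P(side change at t+1 | outcome at t), within-session pairs only.

    ``outcome_class`` is ``"low"`` or ``"high"``: the value class of the
    solution received at trial t.  NaN when no qualifying pair exists.
    """
    if outcome_class not in ("low", "high"):
        raise ValueError(f"outcome_class must be 'low' or 'high', got {outcome_class!r}")
    chosen, high, sid = record.as_arrays()
    if len(chosen) < 2:
        return math.nan
    same_session = sid[1:] == sid[:-1]
    got_high = chosen[:-1] == high[:-1]
    qualifies = same_session & (got_high if outcome_class == "high" else ~got_high)
    if not qualifies.any():
        return math.nan
    switched = chosen[1:] != chosen[:-1]
    return float(switched[qualifies].mean())


def preference(record: MouseRecord) -> float:
    """Mean over sessions of the fraction of choices on the high-value side."""
    fracs = _per_session_fractions(record, target="high")
    return float(np.mean(fracs)) if fracs else math.nan


def side_bias(record: MouseRecord) -> float:
    """Folded per-session left-choice mean: |2m - 1|, 0 = unbiased, 1 = one side only."""
    fracs = _per_session_fractions(record, target="L")
    if not fracs:
        return math.nan
    m = float(np.mean(fracs))
    return abs(2.0 * m - 1.0)


def _per_session_fractions(record: MouseRecord, target: str) -> list[float]:
    chosen, high, sid = record.as_arrays()
    out = []
    for s in sorted({int(x) for x in sid}):
        mask = sid == s
        if not mask.any():
            continue
        if target == "high":
            out.append(float((chosen[mask] == high[mask]).mean()))
        else:  # left
            out.append(float((chosen[mask] == 0).mean()))
    return out


def descriptor_vector(record: MouseRecord) -> dict[str, float]:
    """All five descriptors for one animal, keyed by DESCRIPTOR_COLUMNS."""
    return {
        "switch": switch_index(record),
        "sw_low": conditional_switch(record, "low"),
        "sw_high": conditional_switch(record, "high"),
        "pref": preference(record),
        "side_bias": side_bias(record),
    }


@dataclass
class DescriptorMatrix:
    """n x 5 descriptor table with its scaling record.

    ``values`` holds the (possibly scaled) matrix in the fixed column order
    of :data:`DESCRIPTOR_COLUMNS`; ``column_mins``/``column_maxs`` record the
    raw per-column extrema so scaled coordinates can be mapped back to raw
    descriptor units.
    """

    mouse_ids: list[str]
    values: np.ndarray
    scaling: str
    column_mins: np.ndarray
    column_maxs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.mouse_ids, name="mouse_id"),
            columns=list(DESCRIPTOR_COLUMNS),
        )

    def unscale(self, scaled: np.ndarray) -> np.ndarray:
        """Map minmax-scaled coordinates back to raw descriptor units."""
        if self.scaling == "raw":
            return np.asarray(scaled, dtype=float)
        span = self.column_maxs - self.column_mins
        return np.asarray(scaled, dtype=float) * span + self.column_mins


def descriptor_matrix(cohort: Cohort, scaling: str = "minmax") -> DescriptorMatrix:
    """Assemble the cohort descriptor matrix.

    ``scaling="minmax"`` maps each column onto [0, 1] (the convention used
    before archetypal analysis); constant columns map to zero with a
    warning.  Animals with any undefined descriptor are rejected by name.
    """
    if scaling not in ("raw", "minmax"):
        raise ValueError(f"scaling must be 'raw' or 'minmax', got {scaling!r}")
    ids, rows, bad = [], [], []
    for rec in cohort:
        vec = descriptor_vector(rec)
        row = [vec[c] for c in DESCRIPTOR_COLUMNS]
        if any(math.isnan(v) for v in row):
            bad.append(rec.mouse_id)
        else:
            ids.append(rec.mouse_id)
            rows.append(row)
    if bad:
        raise ValueError(
            "undefined descriptor(s) for animal(s): " + ", ".join(bad)
        )
    X = np.asarray(rows, dtype=float)
    mins = X.min(axis=0) if len(X) else np.zeros(5)
    maxs = X.max(axis=0) if len(X) else np.zeros(5)
    if scaling == "minmax":
        span = maxs - mins
        const = span == 0
        if const.any():
            names = [c for c, f in zip(DESCRIPTOR_COLUMNS, const) if f]
            warnings.warn(f"constant descriptor column(s) mapped to 0: {names}")
        safe = np.where(const, 1.0, span)
        X = (X - mins) / safe
        X[:, const] = 0.0
    if len(X) < 4:
        warnings.warn(
            f"only {len(X)} animals: fewer than k+1 = 4 needed for 3-archetype analysis"
        )
    return DescriptorMatrix(ids, X, scaling, mins, maxs)


def classify_nonswitcher_origin(ws_record: MouseRecord, ww_record: MouseRecord) -> str:
    """Relate a Non-Switcher's preferred side to its history.

    Compares the animal's majority side during the water-vs-sucrose (WS)
    period with (i) the side where it first encountered sucrose and (ii) its
    majority side during the preceding water-vs-water (WW) period.  Returns
    one of ``"first-sucrose & same-WW"``, ``"first-sucrose & opposite-WW"``,
    ``"opposite-first-sucrose & same-WW"``,
    ``"opposite-first-sucrose & opposite-WW"``; NaN-like cases (no sucrose
    encounter, exact 50/50 majority) raise ValueError.
    """
    pref_side = _majority_side(ws_record)
    ww_side = _majority_side(ww_record)
    first = next((t for t in ws_record.trials if t.outcome_label == "high"), None)
    if first is None:
        raise ValueError("no high-value outcome in the WS record")
    a = "first-sucrose" if pref_side == first.high_side else "opposite-first-sucrose"
    b = "same-WW" if pref_side == ww_side else "opposite-WW"
    return f"{a} & {b}"


def _majority_side(record: MouseRecord) -> str:
    chosen, _, _ = record.as_arrays()
    if len(chosen) == 0:
        raise ValueError(f"mouse {record.mouse_id}: empty record")
    p_r = chosen.mean()
    if p_r == 0.5:
        raise ValueError(f"mouse {record.mouse_id}: exact 50/50 side split")
    return "R" if p_r > 0.5 else "L"
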