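import numpy as np
import pytest

from tmaze.trial_data import Cohort, MouseRecord, Session, Trial


def make_record(
    choices: str,
    high_sides: str | None = None,
    session_breaks: tuple[int, ...] = (),
    mouse_id: str = "m1",
    days_observed: float = 1.0,
    value_low: float = 1.0,
    value_high: float = 3.0,
) -> MouseRecord:
    """Build a MouseRecord from compact strings.

    ``choices`` like "LLRR"; ``high_sides`` a same-length string (defaults to
    all "R"); ``session_breaks`` are 0-based positions where a new session
    starts (position 0 implicit).
    """
    n = len(choices)
    high_sides = high_sides or "R" * n
    assert len(high_sides) == n
    breaks = sorted({0, *session_breaks, n})
    trials, sessions = [], []
    for sid, (a, b) in enumerate(zip(breaks, breaks[1:]), start=1):
        hs = set(high_sides[a:b])
        assert len(hs) == 1, "high side must be constant within a declared session"
        sessions.append(Session(sid, high_sides[a], value_low, value_high, b - a))
        for t in range(a, b):
            trials.append(Trial(t + 1, sid, choices[t], high_sides[t]))
    return MouseRecord(mouse_id, trials, sessions, days_observed)


@pytest.fixture
def alternating_record():
    """Two 6-trial sessions; high side L then R; mixed choices."""
    return make_record(
        "LLRLRRLRRRLL", high_sides="LLLLLLRRRRRR", session_breaks=(6,)
    )


@pytest.fixture
def small_cohort():
    recs = [
        make_record("LLRR", mouse_id="a", days_observed=2.0),
        make_record("RRRL", mouse_id="b", days_observed=1.0),
    ]
    return Cohort(recs)
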