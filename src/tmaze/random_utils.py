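"""Seed derivation for reproducible nested simulations.

All stochastic stages derive per-unit generators from one master seed via
``numpy.random.SeedSequence`` spawn keys, so any sub-simulation (one animal,
one sweep replicate) can be re-created in isolation from the master seed and
its key.
"""

from __future__ import annotations

import numpy as np


def child_rng(master_seed: int | None, *key: int) -> np.random.Generator:
    """Generator for the child stream identified by ``key`` under ``master_seed``."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
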