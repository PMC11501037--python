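import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from tmaze.choice_simulator import (
    SessionSchedule,
    _sim_core_py,
    archetype_separation,
    attribution_study,
    cross_context_prediction,
    delta_v_sweep,
    simulate_cohort,
    simulate_mouse,
    standard_schedule,
)
from tmaze.descriptors import descriptor_vector
from tmaze.random_utils import child_rng
from tmaze.rl_model import LatentTriplet, sequence_nll


class TestSimulateMouse:
    def test_uniform_policy_side_fraction(self):
        # beta = chi = 0 (numerical floor for beta): every trial is a coin flip
        rec = simulate_mouse(
            LatentTriplet(0.5, 1e-6, 0.0), standard_schedule(), seed=99
        )
        chosen, _, _ = rec.as_arrays()
        n_r = int(chosen.sum())
        ci = binomtest(n_r, rec.n_trials, 0.5).proportion_ci(confidence_level=0.99)
        assert ci.low <= 0.5 <= ci.high

    def test_greedy_agent_locks_onto_high_side(self):
        # beta = 20, alpha = 1: once the high side is sampled the value gap is 2
        # and P(high) = 1/(1+e^-40); count deviations after the first high choice
        rec = simulate_mouse(
            LatentTriplet(1.0, 20.0, 0.0), standard_schedule(1, 50), seed=7
        )
        chosen, high, _ = rec.as_arrays()
        hits = np.flatnonzero(chosen == high)
        assert len(hits) > 0
        after = chosen[hits[0] :]
        assert np.all(after == high[hits[0] :])

    def test_determinism(self):
        tr = LatentTriplet(0.4, 2.0, 0.3)
        r1 = simulate_mouse(tr, standard_schedule(), seed=5)
        r2 = simulate_mouse(tr, standard_schedule(), seed=5)
        assert r1.trials == r2.trials

    def test_mirror_symmetry_of_the_core(self):
        # flipping the uniform draws (u -> 1-u) and the schedule sides mirrors
        # every choice
        rng = np.random.default_rng(3)
        u = rng.random(100)
        high = np.array([0] * 50 + [1] * 50, dtype=np.int8)
        vlow = np.full(100, 1.0)
        vhigh = np.full(100, 3.0)
        c, *_ = _sim_core_py(u, high, vlow, vhigh, 0.6, 2.0, 0.4, 1.0, 1.0, 0.0)
        cm, *_ = _sim_core_py(1 - u, 1 - high, vlow, vhigh, 0.6, 2.0, 0.4, 1.0, 1.0, 0.0)
        assert np.all(c == 1 - cm)

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            SessionSchedule(((10, "L", 1.0, -0.5),))


class TestSimulateCohort:
    def test_size_and_reproducibility(self):
        trips = [LatentTriplet(0.5, 1.0, 0.0)] * 4
        c1 = simulate_cohort(trips, standard_schedule(2, 20), seed=11)
        c2 = simulate_cohort(trips, standard_schedule(2, 20), seed=11)
        assert len(c1) == 4
        for a, b in zip(c1, c2):
            assert a.trials == b.trials

    def test_child_seed_isolation(self):
        # animal i of the cohort is exactly the stand-alone simulation
        # under child stream (seed, i)
        trips = [LatentTriplet(0.5, 1.0, 0.0), LatentTriplet(0.9, 3.0, 0.5)]
        cohort = simulate_cohort(trips, standard_schedule(2, 20), seed=21)
        solo = simulate_mouse(
            trips[1], standard_schedule(2, 20), seed=child_rng(21, 1)
        )
        assert cohort.records[1].trials == solo.trials

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort([], standard_schedule(), seed=0)

    def test_uniform_policy_descriptor_expectations(self):
        # a large near-uniform cohort: switch -> high, pref -> 0.5
        trips = [LatentTriplet(0.2, 1e-6, 0.0)] * 40
        cohort = simulate_cohort(trips, standard_schedule(), seed=31)
        descs = pd.DataFrame([descriptor_vector(r) for r in cohort])
        assert descs["pref"].mean() == pytest.approx(0.5, abs=0.02)
        assert descs["sw_low"].mean() == pytest.approx(0.5, abs=0.03)
        assert descs["side_bias"].mean() < 0.1


def test_simulator_and_likelihood_agree():
    """The generating triplet fits its own data better than a perturbed one."""
    true = LatentTriplet(0.5, 2.0, 0.0)
    shifted = LatentTriplet(0.8, 2.0, 0.0)
    wins = 0
    for s in range(50):
        rec = simulate_mouse(true, standard_schedule(), seed=1000 + s)
        if sequence_nll(rec, true, v0=1.0) < sequence_nll(rec, shifted, v0=1.0):
            wins += 1
    assert wins / 50 > 0.5


@pytest.fixture(scope="module")
def groups():
    return {
        "Tracker": [LatentTriplet(0.8, 1.5, 0.0), LatentTriplet(0.7, 2.0, 0.2)],
        "Explorer": [LatentTriplet(0.2, 0.4, 0.0), LatentTriplet(0.3, 0.5, -0.2)],
    }


class TestDeltaVSweep:
    def test_symmetric_at_zero(self, groups):
        sw = delta_v_sweep(groups, dv_grid=(0.0,), n_replicates=200, seed=1)
        for g in groups:
            assert sw.mean(g, 0.0, "pref") == pytest.approx(0.5, abs=0.02)

    def test_dv2_is_plain_ws_simulation(self, groups):
        sw = delta_v_sweep(groups, dv_grid=(2.0,), n_replicates=3, seed=2)
        # replicate r of group 0 under common random numbers == stand-alone WS run
        vals = []
        for r in range(3):
            tr = groups["Tracker"][r % 2]
            rec = simulate_mouse(tr, standard_schedule(), seed=child_rng(2, 0, r))
            vals.append(descriptor_vector(rec)["pref"])
        assert sw.mean("Tracker", 2.0, "pref") == pytest.approx(np.mean(vals), abs=1e-12)

    def test_tracker_monotone_explorer_flat(self, groups):
        sw = delta_v_sweep(groups, n_replicates=60, seed=3)
        tr = [sw.mean("Tracker", dv, "pref") for dv in sw.dv_grid]
        ex = [sw.mean("Explorer", dv, "pref") for dv in sw.dv_grid]
        assert all(b >= a - 1e-9 for a, b in zip(tr, tr[1:]))
        assert max(ex) - min(ex) < max(tr) - min(tr)

    def test_negative_value_rejected(self, groups):
        with pytest.raises(ValueError):
            delta_v_sweep(groups, dv_grid=(-1.5,), n_replicates=1, seed=0)


@pytest.fixture(scope="module")
def fits():
    rng = np.random.default_rng(8)
    rows = []
    specs = {
        "Tracker": ((0.5, 0.95), (0.5, 2.5)),
        "Explorer": ((0.1, 0.35), (0.2, 0.7)),
        "NonSwitcher": ((0.01, 0.05), (3.0, 10.0)),
    }
    i = 0
    for label, (ar, br) in specs.items():
        for _ in range(8):
            rows.append(
                {
                    "mouse_id": f"m{i}",
                    "label": label,
                    "alpha": rng.uniform(*ar),
                    "beta": rng.uniform(*br),
                    "chi": rng.uniform(-1, 1),
                    "trials_per_day": rng.uniform(5, 25),
                }
            )
            i += 1
    return pd.DataFrame(rows)


class TestAttribution:
    def test_own_mode_is_identity_with_cohort_simulation(self, fits):
        res = attribution_study(fits, "own", seed=13)
        trips = [LatentTriplet(r.alpha, r.beta, r.chi) for r in fits.itertuples()]
        cohort = simulate_cohort(trips, standard_schedule(), seed=13)
        for rec, (_, row) in zip(cohort, res.per_animal.iterrows()):
            expect = descriptor_vector(rec)
            for k, v in expect.items():
                assert row[k] == pytest.approx(v, nan_ok=True)

    def test_shuffle_chi_preserves_separation(self, fits):
        own = archetype_separation(attribution_study(fits, "own", seed=13).per_animal)
        shuf = archetype_separation(
            attribution_study(fits, "shuffle_chi", seed=13).per_animal
        )
        assert shuf >= 0.8 * own

    def test_random_triplet_collapses_separation(self, fits):
        own = archetype_separation(attribution_study(fits, "own", seed=13).per_animal)
        rand = archetype_separation(
            attribution_study(fits, "random_triplet", seed=13).per_animal
        )
        assert rand < own

    def test_empirical_trials_mode_uses_trial_rate(self, fits):
        res = attribution_study(fits, "random_triplet_empirical_trials", seed=13)
        assert len(res.per_animal) == len(fits)

    def test_unknown_mode_rejected(self, fits):
        with pytest.raises(ValueError):
            attribution_study(fits, "shuffle_everything", seed=0)


class TestCrossContext:
    def test_block1_is_plain_ws_prefix(self):
        trips = [LatentTriplet(0.7, 2.0, 0.1)]
        cc = cross_context_prediction(trips, seed=17)
        ws = cc[(cc.block == "WS")].iloc[0]
        rec = simulate_mouse(trips[0], standard_schedule(), seed=child_rng(17, 0))
        expect = descriptor_vector(rec)
        for k, v in expect.items():
            assert ws[k] == pytest.approx(v)

    def test_tracker_avoids_nicotine_side(self):
        trips = [LatentTriplet(0.8, 2.0, 0.0)] * 20
        cc = cross_context_prediction(trips, seed=18)
        san_pref = cc[cc.block == "SaN"]["pref"].mean()
        assert san_pref <= 0.5

    def test_explorer_changes_less_than_tracker(self):
        trackers = [LatentTriplet(0.8, 2.0, 0.0)] * 15
        explorers = [LatentTriplet(0.2, 0.4, 0.0)] * 15
        cc = cross_context_prediction(
            trackers + explorers,
            labels=["Tracker"] * 15 + ["Explorer"] * 15,
            seed=19,
        )
        pv = cc.pivot_table(index="label", columns="block", values="pref")
        delta = (pv["SaN"] - pv["WS"]).abs()
        assert delta["Explorer"] < delta["Tracker"]
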