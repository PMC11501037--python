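"""Tests of the delta-rule/softmax model against independent oracles.

The brute-force oracle chains the per-trial probabilities by hand (plain
Python floats, product of probabilities) and shares no code with the
package's likelihood path.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record
from tmaze.choice_simulator import simulate_mouse, standard_schedule
from tmaze.rl_model import (
    FitConfig,
    LatentTriplet,
    ValueState,
    choice_probability,
    compare_models,
    fit_mouse,
    fit_reduced,
    sequence_nll,
    update_value,
)


def oracle_nll(record, alpha, beta, chi, v0=0.0):
    """Independent forward-chaining likelihood: product of softmax probs."""
    values = {"L": v0, "R": v0}
    smap = record.session_map()
    prev = None
    prob_product = 1.0
    for trial in record.trials:
        drive = beta * (values["R"] - values["L"])
        if prev == "R":
            drive += chi
        elif prev == "L":
            drive -= chi
        p_right = 1.0 / (1.0 + math.exp(-drive))
        p = p_right if trial.chosen_side == "R" else 1.0 - p_right
        prob_product *= max(p, 1e-12)  # the model's defined probability floor
        sess = smap[trial.session_id]
        reward = sess.value_high if trial.chosen_side == trial.high_side else sess.value_low
        values[trial.chosen_side] += alpha * (reward - values[trial.chosen_side])
        prev = trial.chosen_side
    return -math.log(prob_product)


class TestUpdateValue:
    @pytest.mark.parametrize(
        "v, reward, alpha, expected",
        [
            (0.7, 3.0, 1.0, 3.0),  # full update replaces the value
            (0.7, 3.0, 0.0, 0.7),  # no learning
            (0.0, 3.0, 0.5, 1.5),  # half the prediction error
        ],
    )
    def test_identities(self, v, reward, alpha, expected):
        assert update_value(v, reward, alpha) == expected

    def test_contraction(self):
        v, r, a = 0.2, 3.0, 0.3
        assert abs(update_value(v, r, a) - r) == pytest.approx((1 - a) * abs(v - r))

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            update_value(0.0, 1.0, 1.5)


class TestChoiceProbability:
    def test_equal_values_no_perseveration(self):
        assert choice_probability(ValueState(1.0, 1.0), beta=5.0, chi=0.0) == 0.5

    def test_zero_beta_ignores_values(self):
        assert choice_probability(ValueState(0.0, 100.0), beta=0.0, chi=0.0) == 0.5

    def test_logistic_value(self):
        p = choice_probability(ValueState(0.0, 1.0), beta=2.0, chi=0.0)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), abs=1e-12)

    def test_first_trial_has_no_perseveration(self):
        assert choice_probability(ValueState(0.0, 0.0, "none"), 1.0, 2.0) == 0.5

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        vl=st.floats(0, 4),
        vr=st.floats(0, 4),
        beta=st.floats(0, 20),
        chi=st.floats(-2, 2),
        prev=st.sampled_from(["L", "R", "none"]),
    )
    def test_mirror_symmetry(self, vl, vr, beta, chi, prev):
        mirror_prev = {"L": "R", "R": "L", "none": "none"}[prev]
        p = choice_probability(ValueState(vl, vr, prev), beta, chi)
        q = choice_probability(ValueState(vr, vl, mirror_prev), beta, chi)
        assert p + q == pytest.approx(1.0, abs=1e-12)


class TestSequenceNll:
    def test_single_symmetric_trial(self):
        rec = make_record("R")
        assert sequence_nll(rec, (0.5, 3.0, 1.0), v0=0.0) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_uniform_policy_is_n_log_2(self):
        rec = make_record("LRLRRRLL")
        nll = sequence_nll(rec, (0.5, 1e-6, 0.0), v0=0.0)
        # beta at its numerical floor with v0 = 0: drive stays ~0
        assert nll == pytest.approx(8 * math.log(2), rel=1e-6)

    def test_three_trial_hand_chain(self):
        # choices R,R,L; sucrose (3) on R, water (1) on L; alpha=.5 beta=1 chi=.5 v0=0
        rec = make_record("RRL", high_sides="RRR")
        # hand forward chaining:
        # t1: v=(0,0), prev none -> P_R = 0.5; reward 3 -> v_R = 1.5
        # t2: drive = 1*1.5 + .5*1 = 2 -> P_R = 1/(1+e^-2); v_R = 2.25
        # t3: drive = 2.25 + .5 = 2.75 -> P_L = 1 - 1/(1+e^-2.75)
        p1 = 0.5
        p2 = 1 / (1 + math.exp(-2.0))
        p3 = 1 - 1 / (1 + math.exp(-2.75))
        expected = -(math.log(p1) + math.log(p2) + math.log(p3))
        assert sequence_nll(rec, (0.5, 1.0, 0.5), v0=0.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_oracle_on_random_records(self):
        rng = np.random.default_rng(2024)
        sides = np.array(["L", "R"])
        for _ in range(200):
            n = 10
            choices = "".join(sides[rng.integers(0, 2, n)])
            highs = "".join(sides[rng.integers(0, 2, 1)]) * n
            breaks = (5,) if rng.random() < 0.5 else ()
            rec = make_record(choices, high_sides=highs, session_breaks=breaks)
            a = rng.uniform(0.01, 1.0)
            b = rng.uniform(0.0, 20.0)
            c = rng.uniform(-2.0, 2.0)
            assert sequence_nll(rec, (a, b, c), v0=0.0) == pytest.approx(
                oracle_nll(rec, a, b, c), abs=1e-12
            )

    def test_empty_record_rejected(self):
        from tmaze.trial_data import MouseRecord

        rec = MouseRecord("e", [], [])
        with pytest.raises(ValueError):
            sequence_nll(rec, (0.5, 1.0, 0.0))


class TestTripletBounds:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0, "beta": 1.0},
            {"alpha": 1.2, "beta": 1.0},
            {"alpha": 0.5, "beta": 0.0},
            {"alpha": 0.5, "beta": 25.0},
            {"alpha": 0.5, "beta": 1.0, "chi": 2.5},
        ],
    )
    def test_out_of_bounds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LatentTriplet(**kwargs)


@pytest.fixture(scope="module")
def simulated_record():
    return simulate_mouse(LatentTriplet(0.8, 5.0, 0.0), standard_schedule(), seed=123)


class TestFitting:
    def test_mle_dominates_truth(self, simulated_record):
        fit = fit_mouse(simulated_record, FitConfig(seed=0))
        true_nll = sequence_nll(simulated_record, LatentTriplet(0.8, 5.0, 0.0))
        assert fit.nll <= true_nll + 1e-6

    def test_constant_side_beats_chance(self):
        rec = make_record("L" * 40)
        fit = fit_mouse(rec, FitConfig(seed=1))
        assert fit.nll <= 40 * math.log(2)

    def test_too_few_trials_refused(self):
        rec = make_record("LRLRL")
        with pytest.raises(ValueError, match="too few"):
            fit_mouse(rec, FitConfig(seed=0))

    def test_reduced_never_beats_full(self, simulated_record):
        full = fit_mouse(simulated_record, FitConfig(seed=2))
        red = fit_reduced(simulated_record, FitConfig(seed=2))
        assert red.nll >= full.nll - 1e-6
        assert red.triplet.chi == 0.0

    def test_bic_formulas(self, simulated_record):
        full = fit_mouse(simulated_record, FitConfig(seed=3))
        red = fit_reduced(simulated_record, FitConfig(seed=3))
        n = simulated_record.n_trials
        assert full.bic == pytest.approx(2 * full.nll + 3 * math.log(n))
        assert red.bic == pytest.approx(2 * red.nll + 2 * math.log(n))

    def test_reproducible_given_seed(self, simulated_record):
        f1 = fit_mouse(simulated_record, FitConfig(seed=4))
        f2 = fit_mouse(simulated_record, FitConfig(seed=4))
        assert f1.triplet == f2.triplet
        assert f1.nll == f2.nll


class TestCompareModels:
    def _fit(self, nll, n=100, p=3):
        from tmaze.rl_model import FitResult

        return FitResult(
            triplet=LatentTriplet(0.5, 1.0, 0.0), nll=nll, n_trials=n,
            bic=2 * nll + p * math.log(n), n_params=p, converged=True,
            n_starts_used=1, best_start=0,
        )

    def test_identical_nll(self):
        out = compare_models(self._fit(50.0), self._fit(50.0, p=2))
        assert out["lrt_statistic"] == 0.0
        assert out["lrt_p"] == 1.0

    def test_three_nat_difference(self):
        out = compare_models(self._fit(47.0), self._fit(50.0, p=2))
        assert out["lrt_statistic"] == pytest.approx(6.0)
        assert out["lrt_p"] == pytest.approx(0.01431, abs=5e-6)

    def test_negative_statistic_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = compare_models(self._fit(50.0), self._fit(49.9, p=2))
        assert out["lrt_statistic"] == 0.0

    def test_mismatched_records_rejected(self):
        with pytest.raises(ValueError):
            compare_models(self._fit(50.0), self._fit(50.0, n=99, p=2))
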