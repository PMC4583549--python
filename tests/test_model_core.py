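"""Unit and property tests for the betasort core operations."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from betasort import (
    BetaMemory,
    BetasortParams,
    Trial,
    apply_feedback,
    beta_density,
    betasort_trial,
    choose,
    estimate_position,
    relax,
    run_session,
)
from betasort.task import SessionSchedule, ScheduledTrial


def always_rewarded(pair, choice):
    return 1


class TestBetaDensity:
    @pytest.mark.parametrize(
        "x,u,l,expected",
        [
            (0.5, 1.0, 1.0, 1.0),  # uniform case
            (0.5, 2.0, 2.0, 1.5),  # 6 * 0.5 * 0.5
            (0.25, 2.0, 1.0, 0.5),  # density 2x at x = 0.25
        ],
    )
    def test_closed_form_values(self, x, u, l, expected):
        assert beta_density(x, u, l) == pytest.approx(expected, rel=1e-12)

    def test_integrates_to_one(self):
        val, _ = integrate.quad(lambda x: beta_density(x, 2.5, 1.3), 0, 1)
        assert val == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "x,u,l", [(-0.1, 1, 1), (1.5, 1, 1), (np.nan, 1, 1), (0.5, 0, 1), (0.5, 1, -2)]
    )
    def test_invalid_arguments_rejected(self, x, u, l):
        with pytest.raises(ValueError):
            beta_density(x, u, l)


class TestEstimatePosition:
    def test_zero_evidence_is_midspan(self):
        assert estimate_position(0, 0) == 0.5

    def test_symmetry_and_arithmetic(self):
        assert estimate_position(3, 3) == 0.5
        assert estimate_position(20, 10) == pytest.approx(2 / 3, abs=1e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_position(-1, 2)

    def test_vectorised(self):
        v = estimate_position(np.array([0.0, 1.0]), np.array([0.0, 3.0]))
        assert np.allclose(v, [0.5, 0.25])


class TestRelax:
    def test_perfect_reward_history_scales_by_recall_only(self):
        mem = BetaMemory(
            U=np.array([20.0, 0.0]), L=np.array([10.0, 0.0]),
            R=np.array([10.0, 0.0]), N=np.array([0.0, 0.0]),
        )
        out = relax(mem, 0.9)
        assert out.U[0] == pytest.approx(18.0)
        assert out.L[0] == pytest.approx(9.0)

    def test_reward_rate_half_adds_extra_decay(self):
        # rate 0.5 -> factor (0.5/1.5) + 0.5 = 5/6; U = 12 * 5/6 * 0.9 = 9
        mem = BetaMemory(
            U=np.array([12.0, 0.0]), L=np.array([0.0, 0.0]),
            R=np.array([4.0, 0.0]), N=np.array([4.0, 0.0]),
        )
        assert relax(mem, 0.9).U[0] == pytest.approx(9.0)

    def test_input_memory_untouched(self):
        mem = BetaMemory.zeros(3)
        mem.U[0] = 2.0
        relax(mem, 0.5)
        assert mem.U[0] == 2.0

    @given(
        u=st.floats(0, 1e6), l=st.floats(0, 1e6),
        r=st.floats(0, 1e4), n=st.floats(0, 1e4),
        xi=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_relaxation_preserves_position_and_never_grows(self, u, l, r, n, xi):
        mem = BetaMemory(
            U=np.array([u, 1.0]), L=np.array([l, 1.0]),
            R=np.array([r, 0.0]), N=np.array([n, 0.0]),
        )
        out = relax(mem, xi)
        assert np.all(out.U <= mem.U + 1e-12)
        assert np.all(out.L <= mem.L + 1e-12)
        assert np.all(out.R <= mem.R + 1e-12)
        assert np.all(out.N <= mem.N + 1e-12)
        if out.U[0] + out.L[0] > 0:  # scaled evidence not lost to underflow
            assert out.positions[0] == pytest.approx(mem.positions[0], abs=1e-9)


class TestApplyFeedback:
    @staticmethod
    def ordered_memory():
        # A well-learned 7-item list with descending position estimates.
        u = np.array([12.0, 10.0, 8.0, 6.0, 4.0, 2.0, 1.0])
        l = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        return BetaMemory(U=u, L=l, R=np.zeros(7), N=np.zeros(7))

    def test_reward_consolidates_everything_without_moving_positions(self):
        mem = self.ordered_memory()
        v_before = mem.positions.copy()
        trial = Trial(left=1, right=2, choice=1, reward=1, phase="adjacent")
        out = apply_feedback(mem, trial)
        assert np.allclose(out.positions, v_before)
        assert np.allclose(out.U + out.L, mem.U + mem.L + 1.0)
        # reward tally only for the present pair
        assert np.array_equal(out.R, [0, 1, 1, 0, 0, 0, 0])

    def test_reward_consolidation_arithmetic(self):
        # U=4, L=2 (V=2/3) -> (4.6667, 2.3333), position exactly preserved
        mem = BetaMemory(
            U=np.array([4.0, 1.0]), L=np.array([2.0, 1.0]),
            R=np.zeros(2), N=np.zeros(2),
        )
        out = apply_feedback(mem, Trial(left=0, right=1, choice=0, reward=1))
        assert out.U[0] == pytest.approx(4.6667, abs=1e-4)
        assert out.L[0] == pytest.approx(2.3333, abs=1e-4)
        assert out.positions[0] == pytest.approx(2 / 3, rel=1e-12)

    def test_error_trial_worked_example(self):
        # Pair CE with E (the later item) chosen: no reward.
        mem = self.ordered_memory()
        v = mem.positions
        trial = Trial(left=2, right=4, choice=4, reward=0, phase="all_pairs")
        out = apply_feedback(mem, trial)
        # explicit feedback: chosen E pushed down, unchosen C pushed up
        assert out.L[4] == mem.L[4] + 1
        assert out.U[2] == mem.U[2] + 1
        # D lies between C and E: consolidated, position unchanged
        assert out.U[3] == pytest.approx(mem.U[3] + v[3])
        assert out.positions[3] == pytest.approx(v[3])
        # A and B lie above C: pushed upward by one
        assert out.U[0] == mem.U[0] + 1 and out.U[1] == mem.U[1] + 1
        assert out.L[0] == mem.L[0] and out.L[1] == mem.L[1]
        # F and G lie below E: pushed downward by one
        assert out.L[5] == mem.L[5] + 1 and out.L[6] == mem.L[6] + 1
        # non-reward tally for the present pair only
        assert np.array_equal(out.N, [0, 0, 1, 0, 1, 0, 0])

    def test_invalid_reward_rejected(self):
        with pytest.raises(ValueError):
            Trial(left=0, right=1, choice=0, reward=2)

    @given(
        u=st.floats(0.01, 1e5), l=st.floats(0.01, 1e5),
    )
    @settings(max_examples=200, deadline=None)
    def test_consolidation_preserves_position_exactly(self, u, l):
        v = u / (u + l)
        u2, l2 = u + v, l + (1 - v)
        assert u2 / (u2 + l2) == pytest.approx(v, rel=1e-12)
        # unit mass gain, up to cancellation at large tallies
        assert abs((u2 + l2) - (u + l) - 1.0) < 1e-9 * (u + l + 1.0)


class TestBetasortTrial:
    def test_single_rewarded_trial_from_zero_state(self, rng):
        mem = BetaMemory.zeros(7)
        _, reward, out = betasort_trial(
            mem, (0, 1), BetasortParams(tau=0.0, xi=0.9), always_rewarded, rng
        )
        assert reward == 1
        assert np.allclose(out.U, 0.5) and np.allclose(out.L, 0.5)

    def test_memory_stays_nonnegative_over_random_trials(self, rng):
        from betasort import reward_rule

        mem = BetaMemory.zeros(7)
        params = BetasortParams(tau=0.2, xi=0.8)
        for _ in range(300):
            pair = tuple(rng.choice(7, size=2, replace=False))
            _, _, mem = betasort_trial(mem, pair, params, reward_rule, rng)
            for arr in (mem.U, mem.L, mem.R, mem.N):
                assert np.all(arr >= 0)


class TestChoose:
    def test_full_noise_is_uniform(self, rng):
        mem = BetaMemory(
            U=np.array([100.0, 0.0]), L=np.array([0.0, 100.0]),
            R=np.zeros(2), N=np.zeros(2),
        )
        picks = np.array([choose(mem, (0, 1), 1.0, rng) for _ in range(4000)])
        assert abs(np.mean(picks == 0) - 0.5) < 0.03

    def test_extreme_memory_dominates_at_zero_noise(self, rng):
        mem = BetaMemory(
            U=np.array([100.0, 0.0]), L=np.array([0.0, 100.0]),
            R=np.zeros(2), N=np.zeros(2),
        )
        n = 100_000
        picks = np.array([choose(mem, (0, 1), 0.0, rng) for _ in range(n)])
        assert np.mean(picks == 0) >= 0.999

    def test_identical_memories_choose_each_half_the_time(self, rng):
        mem = BetaMemory(
            U=np.array([5.0, 5.0]), L=np.array([3.0, 3.0]),
            R=np.zeros(2), N=np.zeros(2),
        )
        picks = np.array([choose(mem, (0, 1), 0.0, rng) for _ in range(20_000)])
        assert abs(np.mean(picks == 0) - 0.5) < 0.02

    def test_degenerate_generator_ties_broken_uniformly(self):
        class ConstantRng:
            """Returns equal draws, forcing the tie-break path."""

            def __init__(self):
                self._real = np.random.default_rng(5)

            def random(self, size=None):
                return 0.9 if size is None else np.full(size, 0.5)

            def beta(self, a, b):
                return np.full(np.broadcast(a, b).shape, 0.5)

            def choice(self, x):
                return self._real.choice(x)

        mem = BetaMemory.zeros(2)
        fake = ConstantRng()
        picks = [choose(mem, (0, 1), 0.0, fake) for _ in range(200)]
        assert set(picks) == {0, 1}

    def test_errors(self, rng):
        mem = BetaMemory.zeros(3)
        with pytest.raises(ValueError):
            choose(mem, (0,), 0.0, rng)
        with pytest.raises(ValueError):
            choose(mem, (0, 1), 1.5, rng)


def test_runtime_grows_gently_with_list_size():
    """Per-trial cost is linear in list size, so a 16x larger list must
    stay far below the quadratic 256x runtime blow-up."""
    params = BetasortParams(tau=0.05, xi=0.95)

    def timed(n_stimuli):
        trials = [
            ScheduledTrial(i % (n_stimuli - 1), i % (n_stimuli - 1) + 1, "adjacent")
            for i in range(500)
        ]
        schedule = SessionSchedule(n_stimuli, trials, [0])
        best = np.inf
        for rep in range(3):
            t0 = time.perf_counter()
            run_session("betasort", params, schedule, rep)
            best = min(best, time.perf_counter() - t0)
        return best

    assert timed(160) / timed(10) < 40.0
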