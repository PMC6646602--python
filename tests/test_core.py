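"""Unit tests of the per-agent update rules."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from secondsim import (
    AgentParams,
    AgentState,
    Behavior,
    ConcernPair,
    DriveDirection,
    Memory,
    Realization,
    choose_behavior,
    choose_emotion,
    concern_realization,
    initial_state,
    joint_outcome,
    step_agent,
    update_concerns,
    update_memory,
)

SELF = Behavior.SELF_DIRECTED
OTHER = Behavior.OTHER_DIRECTED


def params(**overrides) -> AgentParams:
    base = dict(
        a1=0.0, a2=0.0, a3=0.0, a4=0.0, a5=0.0, a6=0.0, a7=0.0, a8=0.0,
        a9=0.0, baseline=0.0, c_other_initial=0.5, noise_sd=0.0,
    )
    base.update(overrides)
    return AgentParams(**base)


def realization(score=0.0, direction=DriveDirection.NONE, magnitude=0.0):
    return Realization(score, direction, magnitude)


class TestJointOutcome:
    @pytest.mark.parametrize(
        "child, parent, expected",
        [(OTHER, OTHER, 1), (SELF, OTHER, 0), (OTHER, SELF, 0), (SELF, SELF, 0)],
    )
    def test_and_of_directions(self, child, parent, expected):
        assert joint_outcome(child, parent) == expected


class TestMemory:
    @pytest.mark.parametrize(
        "before, z, after",
        [((0, 0), 1, (1, 1)), ((5, 10), 0, (5, 11)), ((5, 10), 1, (6, 11))],
    )
    def test_accumulation(self, before, z, after):
        assert update_memory(Memory(*before), z) == Memory(*after)

    def test_rejects_non_binary_outcome(self):
        with pytest.raises(ValueError):
            update_memory(Memory(0, 0), 2)

    def test_count_never_exceeds_steps(self):
        with pytest.raises(ValueError):
            Memory(joint_play_count=3, steps_elapsed=2)

    def test_final_count_equals_resummed_z_series(self, rng):
        """Accumulated memory equals brute-force re-summation of the z series."""
        z = rng.integers(0, 2, size=500)
        memory = Memory(0, 0)
        for zi in z:
            memory = update_memory(memory, int(zi))
        assert memory.joint_play_count == int(z.sum())
        assert memory.steps_elapsed == len(z)


class TestConcernRealization:
    def test_perfect_match_means_no_drive(self, rng):
        p = params(a3=1.0)
        concerns = ConcernPair.from_other(0.5)
        real = concern_realization(concerns, Memory(5, 10), p, rng)
        assert real.score == 0.0
        assert real.drive_direction is DriveDirection.NONE
        assert real.drive_magnitude == 0.0

    def test_unmet_relatedness_drives_toward_other(self, rng):
        p = params(a3=1.0)
        concerns = ConcernPair.from_other(0.5)
        real = concern_realization(concerns, Memory(1, 10), p, rng)
        assert real.score == pytest.approx(-0.4)
        assert real.drive_direction is DriveDirection.TOWARD_OTHER
        assert real.drive_magnitude == pytest.approx(0.4)

    def test_surplus_relatedness_drives_toward_self(self, rng):
        p = params(a3=0.5)
        concerns = ConcernPair.from_other(0.2)
        real = concern_realization(concerns, Memory(8, 10), p, rng)
        assert real.drive_direction is DriveDirection.TOWARD_SELF
        assert real.drive_magnitude == pytest.approx(0.5 * 0.6)

    def test_drive_is_linear_in_sensitivity(self, rng):
        """Halving a3 halves the drive magnitude for any discrepancy."""
        concerns = ConcernPair.from_other(0.7)
        for count in range(0, 11):
            memory = Memory(count, 10)
            full = concern_realization(concerns, memory, params(a3=0.8), rng)
            half = concern_realization(concerns, memory, params(a3=0.4), rng)
            assert half.drive_magnitude == pytest.approx(full.drive_magnitude / 2)

    def test_session_start_has_no_drive(self, rng):
        real = concern_realization(
            ConcernPair.from_other(0.9), Memory(0, 0), params(a3=1.0), rng
        )
        assert real.drive_direction is DriveDirection.NONE

    def test_satiation_pair_scales_surplus_side(self, rng):
        """The drive while a concern is in surplus uses that concern's sensitivity."""
        p = params()
        deficit = concern_realization(  # relatedness deficit -> autonomy side
            ConcernPair.from_other(0.8), Memory(2, 10), p, rng, a3_pair=(0.1, 0.9)
        )
        surplus = concern_realization(  # relatedness surplus
            ConcernPair.from_other(0.2), Memory(8, 10), p, rng, a3_pair=(0.1, 0.9)
        )
        assert deficit.drive_magnitude == pytest.approx(0.9 * 0.6)
        assert surplus.drive_magnitude == pytest.approx(0.1 * 0.6)


class TestUpdateConcerns:
    def test_neutral_emotions_leave_concerns_unchanged(self):
        p = params(a1=0.5, a2=0.5)
        concerns = ConcernPair.from_other(0.37)
        assert update_concerns(concerns, OTHER, 0, 0, p) == concerns

    def test_positive_own_emotion_reinforces_current_behavior(self):
        p = params(a1=0.01, a2=0.0)
        out = update_concerns(ConcernPair.from_other(0.50), OTHER, 1, 0, p)
        assert out.c_other == pytest.approx(0.51)
        assert out.c_self == pytest.approx(0.49)

    def test_zero_reinforcement_freezes_concerns(self, rng):
        p = params(a1=0.0, a2=0.0)
        concerns = ConcernPair.from_other(0.6)
        for _ in range(100):
            behavior = OTHER if rng.random() < 0.5 else SELF
            emotions = rng.integers(-1, 2, size=2)
            concerns = update_concerns(
                concerns, behavior, int(emotions[0]), int(emotions[1]), p
            )
        assert concerns.c_other == pytest.approx(0.6)

    def test_clipped_at_boundary(self):
        p = params(a1=0.5)
        out = update_concerns(ConcernPair.from_other(0.9), OTHER, 1, 0, p)
        assert out.c_other == pytest.approx(1.0)
        assert out.c_self == pytest.approx(0.0)


class TestChooseBehavior:
    def test_pure_continuity_repeats_own_behavior(self, rng):
        p = params(a5=1.0)
        real = realization()
        for prev in (SELF, OTHER):
            out = choose_behavior(real, prev, OTHER, ConcernPair.from_other(0.5), p, rng)
            assert out is prev

    def test_pure_symmetry_imitates_partner(self, rng):
        p = params(a6=1.0)
        real = realization()
        for partner in (SELF, OTHER):
            out = choose_behavior(real, SELF, partner, ConcernPair.from_other(0.5), p, rng)
            assert out is partner

    def test_frozen_weights_keep_previous_behavior(self, rng):
        out = choose_behavior(
            realization(), SELF, OTHER, ConcernPair.from_other(0.9), params(), rng
        )
        assert out is SELF

    def test_long_run_frequency_matches_propensity(self, rng):
        """Monte-Carlo check of the Bernoulli draw against a fixed propensity."""
        p = params(baseline=1.0)
        concerns = ConcernPair.from_other(0.7)  # pi = 0.7 exactly
        n = 10_000
        draws = sum(
            choose_behavior(realization(), SELF, SELF, concerns, p, rng) is OTHER
            for _ in range(n)
        )
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(draws / n - 0.7) < 3 * se

    def test_a6_override_replaces_symmetry_weight(self, rng):
        p = params(a6=1.0)
        out = choose_behavior(
            realization(), SELF, OTHER, ConcernPair.from_other(0.5), p, rng, a6=0.0
        )
        assert out is SELF  # zero active weight: previous behavior persists


class TestChooseEmotion:
    def test_zero_affect_is_neutral(self, rng):
        assert choose_emotion(realization(), 0, 0, params(), rng) == 0

    def test_emotional_contagion(self, rng):
        p = params(a9=1.0)
        assert choose_emotion(realization(), 0, 1, p, rng) == 1
        assert choose_emotion(realization(), 0, -1, p, rng) == -1

    def test_expression_independent_of_score_when_a7_zero(self, rng):
        """Chi-squared independence of expression and appraisal at a7 = 0."""
        p = params(a7=0.0, a8=0.0, a9=0.0, noise_sd=0.4)
        tables = []
        for score in (-0.9, 0.0):
            real = realization(score=score)
            draws = [choose_emotion(real, 0, 0, p, rng) for _ in range(2000)]
            tables.append([draws.count(v) for v in (-1, 0, 1)])
        _, pvalue, _, _ = stats.chi2_contingency(np.array(tables))
        assert pvalue > 0.01

    def test_score_shifts_expression_when_a7_positive(self, rng):
        p = params(a7=1.0)
        real = realization(score=-0.8, direction=DriveDirection.TOWARD_OTHER,
                           magnitude=0.8)
        assert choose_emotion(real, 0, 0, p, rng) == -1


class TestStepAgent:
    def test_frozen_agents_are_a_fixed_point(self, rng):
        """With all weights zero the state distribution is preserved exactly."""
        p = params()
        state = initial_state(p, rng)
        partner = initial_state(p, rng)
        stepped = step_agent(state, partner, 0, p, rng)
        assert stepped.behavior is state.behavior
        assert stepped.emotion == state.emotion
        assert stepped.concerns == state.concerns

    def test_memory_advances_once_per_call(self, rng):
        p = params()
        state = initial_state(p, rng)
        partner = initial_state(p, rng)
        for expected_steps in range(1, 6):
            state = step_agent(state, partner, 1, p, rng)
            assert state.memory.steps_elapsed == expected_steps
            assert state.memory.joint_play_count == expected_steps

    def test_partner_hidden_states_never_enter_the_update(self):
        """Perturbing the partner's private state leaves the trajectory bit-identical.

        Only the partner's behavior and emotion are observable; concerns,
        realization and memory are private.  The agent is advanced against two
        partners that differ arbitrarily in private state but agree on
        observables, under the same seed.
        """
        p = params(
            a1=0.01, a2=0.02, a3=0.6, a4=0.3, a5=0.4, a6=0.3, a7=0.5,
            a8=0.3, a9=0.2, baseline=0.3, noise_sd=0.05,
        )
        obs_rng = np.random.default_rng(7)
        script = [
            (Behavior(int(obs_rng.integers(0, 2))), int(obs_rng.integers(-1, 2)))
            for _ in range(50)
        ]

        def run(partner_private_seed: int) -> list[AgentState]:
            rng = np.random.default_rng(99)
            private = np.random.default_rng(partner_private_seed)
            state = initial_state(p, rng)
            out = []
            for behavior, emotion in script:
                partner = AgentState(
                    concerns=ConcernPair.from_other(float(private.random())),
                    realization=Realization(
                        float(-private.random()),
                        DriveDirection.TOWARD_OTHER,
                        float(private.random()),
                    ),
                    behavior=behavior,
                    emotion=emotion,
                    memory=Memory(0, int(private.integers(0, 100))),
                )
                state = step_agent(state, partner, 0, p, rng)
                out.append(state)
            return out

        assert run(1) == run(2)
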