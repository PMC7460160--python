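import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hradapt.engine import (
    GEN_RATE_CAP,
    RateInterpretation,
    Scenario1Mode,
    Scenario1State,
    Scenario2Event,
    Scenario2State,
    Scenario3State,
    TestScenarioState,
    Thresholds,
    make_cis_controller,
    make_uas_controller,
    step_scenario1,
    step_scenario2,
    step_scenario3,
    step_test_scenario,
)


class TestScenario1:
    def test_distance_accrues_below_goal_and_threshold(self):
        s = Scenario1State(d=3, deltaD=5, vh=10)
        out = step_scenario1(s, avg_hr=90, w=0.5)
        assert out.d == 4 and out.deltaD == 5 and out.vh == 10

    def test_goal_reached_low_hr_intent_mode_speeds_up(self):
        s = Scenario1State(d=6, deltaD=5, vh=10, mode=Scenario1Mode.INTENT)
        out = step_scenario1(s, avg_hr=90, w=0.5)
        # deltaD stretches first (5 -> 7.5), then speed moves by new deltaD * w
        assert out.d == 0
        assert out.deltaD == pytest.approx(7.5)
        assert out.vh == pytest.approx(13.75)

    def test_goal_reached_low_hr_literal_mode_reproduces_printed_sign(self):
        s = Scenario1State(d=6, deltaD=5, vh=10, mode=Scenario1Mode.LITERAL)
        out = step_scenario1(s, avg_hr=90, w=0.5)
        assert out.deltaD == pytest.approx(7.5)
        assert out.vh == pytest.approx(10 - 7.5 * 0.5)

    def test_high_exertion_eases_both_quantities(self):
        s = Scenario1State(d=6, deltaD=5, vh=10)
        out = step_scenario1(s, avg_hr=100, w=0.5)
        assert out.d == 0
        assert out.deltaD == pytest.approx(2.5)
        assert out.vh == pytest.approx(5.0)

    def test_zero_weight_changes_nothing_but_distance(self):
        for hr in (90, 100):
            s = Scenario1State(d=6, deltaD=5, vh=10)
            out = step_scenario1(s, avg_hr=hr, w=0.0)
            assert out.d == 0 and out.deltaD == 5 and out.vh == 10

    def test_threshold_tie_takes_easing_branch(self):
        s = Scenario1State(d=3, deltaD=5, vh=10)
        out = step_scenario1(s, avg_hr=95.0, w=0.5)
        assert out.d == 0 and out.vh == pytest.approx(5.0)

    def test_hysteresis_dead_band_holds_difficulty(self):
        th = Thresholds(hysteresis_enabled=True)
        s = Scenario1State(d=6, deltaD=5, vh=10)
        out = step_scenario1(s, avg_hr=100.0, w=0.5, thresholds=th)  # inside [95, 105]
        assert out.deltaD == 5 and out.vh == 10

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            step_scenario1(Scenario1State(), avg_hr=90, w=1.5)


class TestScenario2:
    def test_press_below_threshold_tightens(self):
        s = Scenario2State(allotted=10, timer=10)
        out, ev = step_scenario2(s, button_pressed=True, avg_hr=90)
        assert ev is Scenario2Event.PRESS
        assert out.points == 1 and out.allotted == 9 and out.timer == 9

    def test_floor_at_five_seconds(self):
        s = Scenario2State(allotted=5, timer=5)
        out, _ = step_scenario2(s, button_pressed=True, avg_hr=90)
        assert out.allotted == 5

    def test_timeout_relaxes_and_deducts(self):
        s = Scenario2State(allotted=10, timer=1)
        out, ev = step_scenario2(s, button_pressed=False, avg_hr=90)
        assert ev is Scenario2Event.TIMEOUT
        assert out.points == -1 and out.allotted == 11 and out.timer == 11

    def test_cap_at_fifteen_seconds(self):
        s = Scenario2State(allotted=15, timer=1)
        out, _ = step_scenario2(s, button_pressed=False, avg_hr=90)
        assert out.allotted == 15

    def test_press_at_or_above_threshold_relaxes(self):
        s = Scenario2State(allotted=10, timer=10)
        out, _ = step_scenario2(s, button_pressed=True, avg_hr=95.0)
        assert out.points == 1 and out.allotted == 11

    def test_midround_tick_only_runs_timer(self):
        s = Scenario2State(allotted=10, timer=10)
        out, ev = step_scenario2(s, button_pressed=False, avg_hr=90)
        assert ev is Scenario2Event.NONE
        assert out.timer == 9 and out.points == 0 and out.allotted == 10

    def test_exhaustive_allotted_enumeration_stays_bounded(self):
        """Every reachable (allotted, branch, HR side) transition stays in [5, 15]."""
        for allotted in range(5, 16):
            for hr in (90.0, 95.0, 100.0):
                for pressed, timer in ((True, float(allotted)), (False, 1.0)):
                    s = Scenario2State(allotted=float(allotted), timer=timer)
                    out, _ = step_scenario2(s, button_pressed=pressed, avg_hr=hr)
                    assert 5.0 <= out.allotted <= 15.0


class TestScenario3:
    def test_press_below_threshold_raises_rate(self):
        s = Scenario3State(gen_rate=0.366)
        out = step_scenario3(s, s_pressed=True, s_onscreen=True, avg_hr=90)
        assert out.points == 1 and out.gen_rate == pytest.approx(0.466)

    def test_rate_capped_at_five_times_initial(self):
        s = Scenario3State(gen_rate=GEN_RATE_CAP)
        out = step_scenario3(s, s_pressed=True, s_onscreen=True, avg_hr=90)
        assert out.gen_rate == pytest.approx(GEN_RATE_CAP)

    def test_missed_block_deducts_without_rate_change(self):
        s = Scenario3State(gen_rate=0.8)
        out = step_scenario3(s, s_pressed=False, s_onscreen=False, avg_hr=90)
        assert out.points == -1 and out.gen_rate == pytest.approx(0.8)

    def test_rate_floor_holds_under_high_exertion(self):
        s = Scenario3State(gen_rate=0.1)
        out = step_scenario3(s, s_pressed=True, s_onscreen=True, avg_hr=100)
        assert out.gen_rate == pytest.approx(0.1)

    def test_block_still_falling_is_noop(self):
        s = Scenario3State(gen_rate=0.5)
        out = step_scenario3(s, s_pressed=False, s_onscreen=True, avg_hr=90)
        assert out == s

    def test_period_interpretation_reverses_signs(self):
        s = Scenario3State(gen_rate=0.366, interpretation=RateInterpretation.PERIOD)
        harder = step_scenario3(s, s_pressed=True, s_onscreen=True, avg_hr=90)
        assert harder.gen_rate == pytest.approx(0.266)  # shorter interval = harder
        easier = step_scenario3(s, s_pressed=True, s_onscreen=True, avg_hr=100)
        assert easier.gen_rate == pytest.approx(0.466)


class TestTestScenario:
    @pytest.mark.parametrize(
        "speed,hr,dt,expected",
        [
            (3.0, 75.0, 20.0, 4.0),  # below 80 bpm: +1 per 20 s
            (3.0, 85.0, 20.0, 2.0),  # at/above: -1
            (3.0, 75.0, 10.0, 3.0),  # cadence not reached
        ],
    )
    def test_cadence_rule(self, speed, hr, dt, expected):
        s = TestScenarioState(speed=speed)
        assert step_test_scenario(s, last_hr=hr, dt=dt).speed == expected

    def test_speed_clamped_at_floor(self):
        s = TestScenarioState(speed=0.0, speed_floor=0.0)
        assert step_test_scenario(s, last_hr=90.0, dt=20.0).speed == 0.0

    def test_elapsed_accumulates_across_ticks(self):
        s = TestScenarioState(speed=3.0)
        for _ in range(20):
            s = step_test_scenario(s, last_hr=70.0, dt=1.0)
        assert s.speed == 4.0 and s.elapsed == pytest.approx(0.0)


class TestControllers:
    def test_cis_scenario2_difficulty_frozen_over_100_rounds(self):
        ctrl = make_cis_controller(2)
        for _ in range(100):
            ctrl.step(button_pressed=True, avg_hr=90.0, dt=1.0)
        assert ctrl.state.allotted == 10.0

    def test_cis_scenario3_rate_frozen(self):
        ctrl = make_cis_controller(3)
        for hr in (90.0, 100.0) * 50:
            ctrl.step(s_pressed=True, s_onscreen=True, avg_hr=hr)
        assert ctrl.state.gen_rate == pytest.approx(0.366)

    def test_cis_scoring_matches_uas_with_adaptation_off(self):
        """Identical press/timeout sequences score the same in both arms."""
        uas = make_uas_controller(2)
        uas.adaptive = False
        cis = make_cis_controller(2)
        seq = [True, False, False, True, True] * 20
        for pressed in seq:
            uas.step(button_pressed=pressed, avg_hr=88.0, dt=1.0)
            cis.step(button_pressed=pressed, avg_hr=88.0, dt=1.0)
        assert uas.state.points == cis.state.points

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            make_cis_controller(7)


hr_values = st.floats(40, 220)
weights = st.floats(0, 1)


class TestInvariants:
    @given(st.lists(st.tuples(hr_values, weights), min_size=1, max_size=200))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_scenario1_stays_within_clamps(self, seq):
        s = Scenario1State(deltaD=5.0)
        for hr, w in seq:
            s = step_scenario1(s, hr, w)
            assert s.vh_min <= s.vh <= s.vh_max
            assert s.deltaD_min <= s.deltaD <= s.deltaD_max
            assert s.d >= 0

    @given(st.lists(st.tuples(st.booleans(), hr_values), min_size=1, max_size=200))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_scenario2_allotted_never_escapes_bounds(self, seq):
        s = Scenario2State()
        for pressed, hr in seq:
            s, _ = step_scenario2(s, pressed, hr)
            assert 5.0 <= s.allotted <= 15.0
            assert s.timer <= s.allotted

    @given(st.lists(st.tuples(st.booleans(), st.booleans(), hr_values), min_size=1, max_size=200))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_scenario3_rate_never_escapes_bounds(self, seq):
        s = Scenario3State()
        for pressed, onscreen, hr in seq:
            s = step_scenario3(s, pressed, onscreen, hr)
            assert s.rate_floor <= s.gen_rate <= s.rate_cap + 1e-12

    @given(hr=hr_values, w=weights)
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_steps_are_pure(self, hr, w):
        s1 = Scenario1State(d=6, deltaD=5, vh=10)
        assert step_scenario1(s1, hr, w) == step_scenario1(s1, hr, w)
        s2 = Scenario2State()
        assert step_scenario2(s2, True, hr) == step_scenario2(s2, True, hr)

    @given(hr=hr_values)
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_exactly_one_branch_fires(self, hr):
        """The three printed scenario-1 branches partition the input space."""
        s = Scenario1State(d=6, deltaD=5, vh=10)
        out = step_scenario1(s, hr, 0.5)
        th = Thresholds()
        branch_a = out.d == s.d + 1
        branch_b = out.d == 0 and out.deltaD > s.deltaD
        branch_c = out.d == 0 and out.deltaD < s.deltaD
        assert branch_a + branch_b + branch_c == 1
        assert branch_c == (hr >= th.hr_threshold)

    def test_high_exertion_monotonically_eases_until_clamped(self):
        """At/above threshold: speed and rate fall, allotted rises, tick over tick."""
        s1 = Scenario1State(d=6, deltaD=5, vh=50)
        s2 = Scenario2State(allotted=10, timer=10)
        s3 = Scenario3State(gen_rate=1.0)
        for _ in range(10):
            n1 = step_scenario1(s1, 100.0, 0.3)
            assert n1.vh < s1.vh or n1.vh == s1.vh_min
            s1 = Scenario1State(d=6, deltaD=max(n1.deltaD, s1.deltaD_min), vh=n1.vh)
            n2, _ = step_scenario2(s2, True, 100.0)
            assert n2.allotted > s2.allotted or n2.allotted == 15.0
            s2 = Scenario2State(allotted=n2.allotted, timer=n2.allotted)
            n3 = step_scenario3(s3, True, True, 100.0)
            assert n3.gen_rate < s3.gen_rate or n3.gen_rate == s3.rate_floor
            s3 = Scenario3State(gen_rate=n3.gen_rate)
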