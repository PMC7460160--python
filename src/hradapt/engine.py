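"""HR-driven difficulty controllers, as pure state-transition functions.

Three game scenarios adapt their difficulty each tick from the running
average heart rate ``avgHR`` (bpm) against a 95 bpm exertion threshold, plus
a simpler architecture-test controller driven by the last raw reading
against 80 bpm:

* Scenario 1 (horizontally flying character): the character speed ``vh`` and
  the goal distance ``deltaD`` move by a fraction ``w`` — the mean of the
  last 20 scaled HR readings — whenever a goal is reached (below threshold)
  or exertion is high (at/above threshold).
* Scenario 2 (bathtub countdown task): the allotted per-round time adapts by
  ±1 s within [5, 15] s on round completion or timeout.
* Scenario 3 (falling blocks): the block generation rate adapts by ±0.1
  blocks/s within [0.1, 5 x 0.366] on each resolved block.

All step functions are pure: they return a new state and never mutate their
input. A ``make_cis_controller``/``make_uas_controller`` pair wraps them into
stateful controllers; the CIS (conventional, non-adaptive) variant keeps
scoring and timing identical but freezes every difficulty quantity at its
initial value.

Two published ambiguities are carried as explicit options rather than
resolved silently:

* ``mode`` on scenario 1 — the published prose says the speed is *increased*
  on goal completion under low HR, while the published pseudocode subtracts.
  ``intent`` (default) follows the prose; ``literal`` reproduces the
  pseudocode sign-for-sign.
* ``interpretation`` on scenario 3 — the initial quantity is printed as
  "0.366 s" (a period) while the adaptation prose says +0.1 makes blocks
  *more* frequent (a rate). ``rate`` (default) treats the quantity as
  blocks/s with a global clamp [0.1, 1.83]; ``period`` treats it as the
  spawn interval in seconds with the same numeric bounds and reversed signs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable

__all__ = [
    "Thresholds",
    "Scenario1Mode",
    "RateInterpretation",
    "Scenario1State",
    "Scenario2State",
    "Scenario3State",
    "TestScenarioState",
    "Scenario2Event",
    "step_scenario1",
    "step_scenario2",
    "step_scenario3",
    "step_test_scenario",
    "ScenarioController",
    "make_uas_controller",
    "make_cis_controller",
    "GEN_RATE_INITIAL",
    "GEN_RATE_STEP",
    "GEN_RATE_CAP",
]

GEN_RATE_INITIAL = 0.366
GEN_RATE_STEP = 0.1
GEN_RATE_CAP = 5 * 0.366  # 1.83


class Scenario1Mode(str, Enum):
    INTENT = "intent"  # speed up on goal completion below threshold
    LITERAL = "literal"  # reproduce the published pseudocode sign


class RateInterpretation(str, Enum):
    RATE = "rate"  # blocks per second
    PERIOD = "period"  # seconds between blocks


@dataclass(frozen=True)
class Thresholds:
    """HR boundaries steering every controller.

    ``hr_threshold`` (95 bpm) separates the harden/ease branches; equality is
    treated as high exertion (the published branches use strict inequalities,
    leaving the tie undefined — easing is the safe default). ``hr_upper``
    (105 bpm) enables an optional hysteresis band: with it on, difficulty
    hardens only below ``hr_threshold`` and eases only above ``hr_upper``.
    """

    hr_threshold: float = 95.0
    hr_upper: float = 105.0
    hysteresis_enabled: bool = False

    def __post_init__(self) -> None:
        if not self.hr_threshold <= self.hr_upper:
            raise ValueError("hr_threshold must be <= hr_upper")

    def exertion_high(self, avg_hr: float) -> bool | None:
        """True -> ease difficulty, False -> harden, None -> hold (dead band)."""
        if self.hysteresis_enabled:
            if avg_hr < self.hr_threshold:
                return False
            if avg_hr > self.hr_upper:
                return True
            return None
        return avg_hr >= self.hr_threshold


@dataclass(frozen=True)
class Scenario1State:
    """Flying-character controller: distance accrual and speed adaptation."""

    d: float = 0.0  # traveled distance since last goal
    deltaD: float = 100.0  # current goal distance
    vh: float = 10.0  # horizontal displacement speed
    mode: Scenario1Mode = Scenario1Mode.INTENT
    vh_min: float = 1.0
    vh_max: float = 100.0
    deltaD_min: float = 1.0
    deltaD_max: float = 10000.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be non-negative")
        if self.deltaD <= 0 or self.vh <= 0:
            raise ValueError("deltaD and vh must be positive")


@dataclass(frozen=True)
class Scenario2State:
    """Bathtub countdown controller.

    The published countdown variable is split into the per-round ``timer``
    (runs down within a round) and the persistent ``allotted`` time (the
    adapted quantity, held in [5, 15] s); the published timeout branch — add
    one second starting from zero — is only coherent for the allotted time.
    """

    allotted: float = 10.0
    timer: float = 10.0
    points: int = 0
    round_distance_m: float = 6.0  # metadata: round-trip distance per round

    ALLOTTED_MIN = 5.0
    ALLOTTED_MAX = 15.0

    def __post_init__(self) -> None:
        if not self.ALLOTTED_MIN <= self.allotted <= self.ALLOTTED_MAX:
            raise ValueError(f"allotted {self.allotted} outside [5, 15]")
        if self.timer > self.allotted:
            raise ValueError("timer cannot exceed allotted")


class Scenario2Event(str, Enum):
    NONE = "none"  # round still running
    PRESS = "press"  # completed in time
    TIMEOUT = "timeout"  # timer expired


@dataclass(frozen=True)
class Scenario3State:
    """Falling-blocks controller (generation-rate adaptation)."""

    gen_rate: float = GEN_RATE_INITIAL
    step: float = GEN_RATE_STEP
    rate_cap: float = GEN_RATE_CAP
    rate_floor: float = 0.1
    points: int = 0
    interpretation: RateInterpretation = RateInterpretation.RATE

    def __post_init__(self) -> None:
        if not self.rate_floor <= self.gen_rate <= self.rate_cap:
            raise ValueError(
                f"gen_rate {self.gen_rate} outside [{self.rate_floor}, {self.rate_cap}]"
            )


@dataclass(frozen=True)
class TestScenarioState:
    """Architecture-test controller: ±1 speed unit every 20 s on the 80 bpm cut."""

    __test__ = False  # "Test" here means the architecture-test scenario

    speed: float = 1.0
    cadence_s: float = 20.0
    hr_cut: float = 80.0
    elapsed: float = 0.0
    speed_floor: float = 0.0


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(hi, max(lo, x))


def step_scenario1(
    state: Scenario1State,
    avg_hr: float,
    w: float,
    thresholds: Thresholds | None = None,
    adapt: bool = True,
) -> Scenario1State:
    """One 1 Hz tick of the flying-character rule.

    Branch A (goal not yet reached, low exertion): distance accrues by one
    unit. Branch B (goal reached, low exertion): distance resets, the goal
    stretches by ``deltaD*w`` and the speed moves by ``deltaD*w`` (sign per
    ``state.mode``, with ``deltaD`` already updated — the published
    statements execute in order). Branch C (high exertion): distance resets
    and both quantities shrink by their own value times ``w``. With the
    hysteresis dead band active, the hold region accrues distance only.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must lie in [0, 1], got {w}")
    th = thresholds or Thresholds()
    high = th.exertion_high(avg_hr)
    if high is None or (high is False and state.d < state.deltaD):
        return replace(state, d=state.d + 1)
    if not adapt:
        return replace(state, d=0.0)
    if high is False:  # goal reached under low exertion: harden
        new_dd = _clamp(state.deltaD + state.deltaD * w, state.deltaD_min, state.deltaD_max)
        sign = 1.0 if state.mode is Scenario1Mode.INTENT else -1.0
        new_vh = _clamp(state.vh + sign * new_dd * w, state.vh_min, state.vh_max)
    else:  # high exertion: ease
        new_dd = _clamp(state.deltaD - state.deltaD * w, state.deltaD_min, state.deltaD_max)
        new_vh = _clamp(state.vh - state.vh * w, state.vh_min, state.vh_max)
    return replace(state, d=0.0, deltaD=new_dd, vh=new_vh)


def step_scenario2(
    state: Scenario2State,
    button_pressed: bool,
    avg_hr: float,
    dt: float = 1.0,
    thresholds: Thresholds | None = None,
    adapt: bool = True,
) -> tuple[Scenario2State, Scenario2Event]:
    """One tick of the bathtub countdown rule.

    The timer runs down by *dt*. A press with time remaining scores +1 and —
    below threshold — tightens the allotted time by 1 s (floor 5 s), at/above
    threshold relaxes it by 1 s (cap 15 s). A timeout scores −1 and relaxes
    by 1 s. Either terminal event starts a new round with the timer refilled
    to the (possibly adapted) allotted time. Returns the new state and which
    terminal event, if any, occurred.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    th = thresholds or Thresholds()
    timer = state.timer - dt
    if button_pressed and timer > 0:
        allotted = state.allotted
        if adapt:
            high = th.exertion_high(avg_hr)
            if high is False:
                allotted = max(state.ALLOTTED_MIN, allotted - 1)
            elif high is True:
                allotted = min(state.ALLOTTED_MAX, allotted + 1)
        new = replace(state, allotted=allotted, timer=allotted, points=state.points + 1)
        return new, Scenario2Event.PRESS
    if timer <= 0:
        allotted = state.allotted
        if adapt:
            allotted = min(state.ALLOTTED_MAX, allotted + 1)
        new = replace(state, allotted=allotted, timer=allotted, points=state.points - 1)
        return new, Scenario2Event.TIMEOUT
    return replace(state, timer=timer), Scenario2Event.NONE


def step_scenario3(
    state: Scenario3State,
    s_pressed: bool,
    s_onscreen: bool,
    avg_hr: float,
    thresholds: Thresholds | None = None,
    adapt: bool = True,
) -> Scenario3State:
    """Resolve one block of the falling-blocks rule.

    A correct press while the block is on screen scores +1 and moves the
    generation quantity one step toward harder (below threshold) or easier
    (at/above threshold); a block that leaves the screen unpressed scores −1
    and leaves the rate alone. A press with no block on screen, or a block
    still falling, is a no-op.
    """
    th = thresholds or Thresholds()
    if s_pressed and s_onscreen:
        rate = state.gen_rate
        if adapt:
            high = th.exertion_high(avg_hr)
            harder = state.step if state.interpretation is RateInterpretation.RATE else -state.step
            if high is False:
                rate = _clamp(rate + harder, state.rate_floor, state.rate_cap)
            elif high is True:
                rate = _clamp(rate - harder, state.rate_floor, state.rate_cap)
        return replace(state, gen_rate=rate, points=state.points + 1)
    if not s_onscreen:
        return replace(state, points=state.points - 1)
    return state


def step_test_scenario(
    state: TestScenarioState,
    last_hr: float,
    dt: float = 1.0,
    adapt: bool = True,
) -> TestScenarioState:
    """Architecture-test rule: ±1 speed unit per full 20 s, keyed on 80 bpm."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    elapsed = state.elapsed + dt
    speed = state.speed
    while elapsed >= state.cadence_s:
        elapsed -= state.cadence_s
        if adapt:
            if last_hr < state.hr_cut:
                speed += 1.0
            else:
                speed = max(state.speed_floor, speed - 1.0)
    return replace(state, speed=speed, elapsed=elapsed)


_STEP_FUNCS: dict[object, Callable] = {
    1: step_scenario1,
    2: step_scenario2,
    3: step_scenario3,
    "test": step_test_scenario,
}

_INITIAL_STATES = {
    1: Scenario1State,
    2: Scenario2State,
    3: Scenario3State,
    "test": TestScenarioState,
}


@dataclass
class ScenarioController:
    """Stateful wrapper pairing a scenario's step function with its state.

    ``adaptive=False`` yields the CIS behaviour: scoring and timers operate
    normally but difficulty quantities stay frozen at their initial values.
    """

    scenario: object
    state: object
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)
    adaptive: bool = True

    def step(self, **inputs):
        """Advance one tick/event; returns any auxiliary event marker."""
        fn = _STEP_FUNCS[self.scenario]
        if self.scenario == "test":
            out = fn(self.state, adapt=self.adaptive, **inputs)
        else:
            out = fn(self.state, thresholds=self.thresholds, adapt=self.adaptive, **inputs)
        if isinstance(out, tuple):
            self.state, event = out
            return event
        self.state = out
        return None


def make_uas_controller(
    scenario: object,
    initial_state: object | None = None,
    thresholds: Thresholds | None = None,
) -> ScenarioController:
    """Adaptive (UAS) controller for scenario 1, 2, 3 or "test"."""
    if scenario not in _STEP_FUNCS:
        raise ValueError(f"unknown scenario {scenario!r}; expected 1, 2, 3 or 'test'")
    state = initial_state if initial_state is not None else _INITIAL_STATES[scenario]()
    return ScenarioController(scenario, state, thresholds or Thresholds(), adaptive=True)


def make_cis_controller(
    scenario: object,
    initial_state: object | None = None,
    thresholds: Thresholds | None = None,
) -> ScenarioController:
    """Non-adaptive (CIS) controller: identical scoring, frozen difficulty."""
    ctrl = make_uas_controller(scenario, initial_state, thresholds)
    ctrl.adaptive = False
    return ctrl
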