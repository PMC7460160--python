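"""Synthetic child physiology and closed-loop session simulation.

No public dataset accompanies the adaptation engine, so the simulator
provides the study conditions: children aged 5-7 with resting heart rates in
the 70-90 bpm band, age-capped maxima (220 − age), a first-order exertion
response, and a press-success model that degrades smoothly with game
difficulty. Each participant plays both arms of a crossover — the adaptive
system (UAS) and the conventional system (CIS, identical rules with frozen
difficulty) — for 10 minutes each, separated by rest, with telemetry at 1 Hz.

Heart rate follows a first-order relaxation toward a demand-dependent target

    target = resting + demand * effort_gain * (hr_max − resting)
    hr    += (target − hr) * dt / tau + N(0, noise_sd^2 * dt)

clamped to [40, hr_max]. Demand in [0, 1] is read off each controller's own
difficulty quantity normalised by its clamp range, so the loop
game demand -> HR -> adaptation -> demand is closed. Energy expenditure uses
a linear heart-rate-reserve surrogate (the wearable's proprietary calorie
algorithm is unpublished): kcal/s = max(0, c0 + c1 * (hr − resting)), sized
so a ~200 s scenario accumulates single-digit kilocalories.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Sequence

import numpy as np

from .engine import (
    RateInterpretation,
    Scenario1State,
    Scenario2Event,
    Scenario2State,
    Scenario3State,
    ScenarioController,
    TestScenarioState,
    Thresholds,
    make_cis_controller,
    make_uas_controller,
)
from .session import (
    EventKind,
    GameEvent,
    SessionLog,
    SessionRow,
)
from .signal_ingest import ScaledWindow, ScaleConfig, avg_hr, push_sample, window_weight, HRSample, Device

__all__ = [
    "SimParticipant",
    "ProtocolConfig",
    "DEFAULT_SCENARIOS",
    "hr_step",
    "kcal_step",
    "press_behavior",
    "demand_of",
    "sample_participant",
    "simulate_session",
    "simulate_cohort",
    "state_to_dict",
    "encode_tick",
]

DEFAULT_SCENARIOS: tuple = (1, 2, 3)

HR_FLOOR = 40.0  # physiological clamp, bpm

# calorie surrogate defaults (kcal/s and kcal/s per bpm of HR reserve):
# ~0.04 kcal/s at moderate play, i.e. ~8 kcal per ~200 s scenario segment
KCAL_C0 = 0.02
KCAL_C1 = 0.0013


@dataclass(frozen=True)
class SimParticipant:
    """Physiological and behavioural parameters of one synthetic child."""

    age: float = 6.0  # years, in [5, 7]
    resting_hr: float = 80.0  # bpm, sampled from [70, 90]
    tau: float = 30.0  # s, HR response time constant
    effort_gain: float = 0.6  # fraction of HR reserve reachable at full demand
    noise_sd: float = 2.0  # bpm, per-sqrt-second
    skill: float = 0.85  # press-success probability at zero difficulty
    difficulty_penalty: float = 0.5  # success probability lost at full difficulty
    distraction_p: float = 0.0  # probability a press attempt is abandoned
    kcal_c0: float = KCAL_C0
    kcal_c1: float = KCAL_C1
    seed: int = 0

    @property
    def hr_max(self) -> float:
        return 220.0 - self.age

    def __post_init__(self) -> None:
        if not self.resting_hr < self.hr_max:
            raise ValueError("resting_hr must be below hr_max")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.effort_gain <= 1:
            raise ValueError("effort_gain must lie in (0, 1]")


@dataclass(frozen=True)
class ProtocolConfig:
    """Crossover session protocol: 10 min play, 10 min rest, 1 Hz sampling."""

    play_duration_s: float = 600.0
    rest_duration_s: float = 600.0
    sampling_hz: float = 1.0
    warmup_samples: int = 5  # controllers hold until the window has this many

    def __post_init__(self) -> None:
        if self.play_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")


def hr_step(
    hr: float,
    demand: float,
    p: SimParticipant,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
) -> float:
    """One Euler step of the first-order exertion response."""
    if not 0.0 <= demand <= 1.0:
        raise ValueError(f"demand must lie in [0, 1], got {demand}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    target = p.resting_hr + demand * p.effort_gain * (p.hr_max - p.resting_hr)
    nxt = hr + (target - hr) * dt / p.tau
    if rng is not None and p.noise_sd > 0:
        nxt += rng.normal(0.0, p.noise_sd * math.sqrt(dt))
    return min(p.hr_max, max(HR_FLOOR, nxt))


def kcal_step(hr: float, p: SimParticipant, dt: float = 1.0) -> float:
    """Energy increment (kcal) for *dt* seconds at heart rate *hr*."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return max(0.0, p.kcal_c0 + p.kcal_c1 * (hr - p.resting_hr)) * dt


def demand_of(state: Any) -> float:
    """Normalise a controller state's difficulty quantity onto [0, 1]."""
    if isinstance(state, Scenario1State):
        return (state.vh - state.vh_min) / (state.vh_max - state.vh_min)
    if isinstance(state, Scenario2State):
        return (Scenario2State.ALLOTTED_MAX - state.allotted) / (
            Scenario2State.ALLOTTED_MAX - Scenario2State.ALLOTTED_MIN
        )
    if isinstance(state, Scenario3State):
        frac = (state.gen_rate - state.rate_floor) / (state.rate_cap - state.rate_floor)
        if state.interpretation is RateInterpretation.PERIOD:
            frac = 1.0 - frac  # shorter interval = harder
        return min(1.0, max(0.0, frac))
    if isinstance(state, TestScenarioState):
        return min(1.0, max(0.0, state.speed / 20.0))
    raise TypeError(f"no demand model for {type(state).__name__}")


def press_behavior(
    state: Any,
    p: SimParticipant,
    rng: np.random.Generator,
) -> tuple[bool, float]:
    """Simulate one press attempt at the state's current difficulty.

    Returns ``(success, latency_fraction)``; the latency fraction is the
    share of the available time the participant needs (scenario 2 uses it to
    place the press within the round). Success probability is
    ``skill * (1 − difficulty_penalty * demand)``, optionally zeroed by a
    distraction draw.
    """
    difficulty = demand_of(state)
    p_success = p.skill * (1.0 - p.difficulty_penalty * difficulty)
    if p.distraction_p > 0 and rng.random() < p.distraction_p:
        p_success = 0.0
    success = bool(rng.random() < p_success)
    latency = float(rng.uniform(0.3, 0.9))
    return success, latency


def state_to_dict(state: Any) -> dict:
    d = dataclasses.asdict(state)
    return {k: (v.value if isinstance(v, Enum) else v) for k, v in d.items()}


def encode_tick(state: Any, inputs: dict) -> str:
    """Canonical JSON snapshot of (post-step state, tick inputs) for replay."""
    return json.dumps({"state": state_to_dict(state), "inputs": inputs}, sort_keys=True)


def sample_participant(pid: int, rng: np.random.Generator, **overrides) -> SimParticipant:
    """Draw one synthetic child (age 5-7, resting HR 70-90 bpm)."""
    params = dict(
        age=float(rng.uniform(5.0, 7.0)),
        resting_hr=float(rng.uniform(70.0, 90.0)),
        tau=float(rng.uniform(25.0, 35.0)),
        effort_gain=float(rng.uniform(0.5, 0.7)),
        skill=float(rng.uniform(0.75, 0.95)),
        seed=pid,
    )
    params.update(overrides)
    return SimParticipant(**params)


class _ScenarioRunner:
    """Drives one scenario segment tick by tick, recording replayable inputs."""

    def __init__(self, scenario, ctrl: ScenarioController, p: SimParticipant, rng):
        self.scenario = scenario
        self.ctrl = ctrl
        self.p = p
        self.rng = rng
        if scenario == 2:
            self._plan_round()
        if scenario == 3:
            self._block_acc = 0.0

    def _plan_round(self) -> None:
        success, latency = press_behavior(self.ctrl.state, self.p, self.rng)
        self._press_at = latency * self.ctrl.state.allotted if success else math.inf
        self._round_elapsed = 0.0

    def tick(self, avg_hr_val: float | None, w_val: float | None, warmed: bool) -> dict:
        """Advance one second; returns the inputs dict for the replay trace."""
        ctrl = self.ctrl
        adaptive = ctrl.adaptive
        ctrl.adaptive = adaptive and warmed
        try:
            if self.scenario == 1:
                if warmed:
                    ctrl.step(avg_hr=avg_hr_val, w=w_val)
                    return {"stepped": True}
                return {"stepped": False}
            if self.scenario == 2:
                self._round_elapsed += 1.0
                pressed = self._round_elapsed >= self._press_at
                event = ctrl.step(
                    button_pressed=pressed,
                    avg_hr=avg_hr_val if avg_hr_val is not None else 0.0,
                    dt=1.0,
                )
                if event is not Scenario2Event.NONE:
                    self._plan_round()
                return {"pressed": bool(pressed)}
            if self.scenario == 3:
                rate = ctrl.state.gen_rate
                if ctrl.state.interpretation is RateInterpretation.PERIOD:
                    rate = 1.0 / rate
                self._block_acc += rate
                blocks = []
                while self._block_acc >= 1.0:
                    self._block_acc -= 1.0
                    success, _ = press_behavior(ctrl.state, self.p, self.rng)
                    ctrl.step(
                        s_pressed=success,
                        s_onscreen=success,
                        avg_hr=avg_hr_val if avg_hr_val is not None else 0.0,
                    )
                    blocks.append(bool(success))
                return {"blocks": blocks}
            if self.scenario == "test":
                last = avg_hr_val if avg_hr_val is not None else 0.0
                ctrl.step(last_hr=last, dt=1.0)
                return {"stepped": True}
            raise ValueError(f"unknown scenario {self.scenario!r}")
        finally:
            ctrl.adaptive = adaptive


def simulate_session(
    p: SimParticipant,
    arm: str,
    scenarios: Sequence = DEFAULT_SCENARIOS,
    protocol: ProtocolConfig | None = None,
    thresholds: Thresholds | None = None,
    scale: ScaleConfig | None = None,
    initial_states: dict | None = None,
    seed: int | None = None,
    hr_offset_bpm: float = 0.0,
    adaptive: bool | None = None,
) -> SessionLog:
    """Simulate one participant-arm play session at 1 Hz.

    The play duration is split equally across *scenarios*. ``arm`` selects
    adaptive (``"UAS"``) or frozen (``"CIS"``) controllers unless *adaptive*
    overrides it (used for arm-effect experiments where both arms must share
    rules). ``hr_offset_bpm`` is added to every measured sample — a known,
    built-in arm effect for parameter-recovery studies. Deterministic given
    (participant, seed).
    """
    if arm not in ("UAS", "CIS"):
        raise ValueError(f"arm must be 'UAS' or 'CIS', got {arm!r}")
    protocol = protocol or ProtocolConfig()
    thresholds = thresholds or Thresholds()
    scale = scale or ScaleConfig()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    use_adaptive = (arm == "UAS") if adaptive is None else adaptive
    make = make_uas_controller if use_adaptive else make_cis_controller

    dt = 1.0 / protocol.sampling_hz
    seg_ticks = int(round(protocol.play_duration_s / dt / len(scenarios)))
    log = SessionLog(participant=f"p{p.seed:03d}", arm=arm)
    window = ScaledWindow()
    hr = p.resting_hr
    t = 0.0
    log.events.append(GameEvent(EventKind.SIGNAL_ACTIVATION, t, None, {"source": "simulated"}))

    for scenario in scenarios:
        init = (initial_states or {}).get(scenario)
        ctrl = make(scenario, initial_state=init, thresholds=thresholds)
        runner = _ScenarioRunner(scenario, ctrl, p, rng)
        kcal = 0.0  # per-scenario cumulative, reset at activityStarted
        log.events.append(GameEvent(EventKind.ACTIVITY_STARTED, t, scenario))
        for _ in range(seg_ticks):
            t += dt
            demand = demand_of(ctrl.state)
            hr = hr_step(hr, demand, p, dt, rng)
            measured = min(p.hr_max, max(HR_FLOOR, hr + hr_offset_bpm))
            sample = HRSample(t, measured, Device.SIMULATED)
            push_sample(window, sample, scale)
            warmed = len(window) >= protocol.warmup_samples
            a = avg_hr(window)
            w = window_weight(window)
            inputs = runner.tick(a, w, warmed)
            kcal += kcal_step(measured, p, dt)
            points = getattr(ctrl.state, "points", 0)
            log.rows.append(
                SessionRow(
                    t=t,
                    hr_raw=measured,
                    hr_cal=measured,  # simulated streams bypass calibration
                    avg_hr=a,
                    w=w,
                    scenario=scenario,
                    state_json=encode_tick(ctrl.state, inputs),
                    points=int(points),
                    kcal=kcal,
                )
            )
        log.events.append(
            GameEvent(EventKind.ACTIVITY_FINISHED, t, scenario, {"completed": True})
        )
        log.events.append(
            GameEvent(
                EventKind.SCORE_OBTAINED,
                t,
                scenario,
                {"score": int(getattr(ctrl.state, "points", 0))},
            )
        )
    return log


def simulate_cohort(
    n: int,
    protocol: ProtocolConfig | None = None,
    scenarios: Sequence = DEFAULT_SCENARIOS,
    thresholds: Thresholds | None = None,
    master_seed: int = 0,
    arm_effect_bpm: float = 0.0,
    adaptive_uas: bool = True,
    participant_overrides: dict | None = None,
    initial_states: dict | None = None,
) -> list[tuple[SessionLog, SessionLog]]:
    """Simulate *n* participants, each playing both arms (UAS, CIS).

    Both arms share the participant's physiological parameters; each arm
    gets an independent noise stream derived reproducibly from
    *master_seed*. With ``adaptive_uas=False`` the UAS arm also runs frozen
    controllers so that ``arm_effect_bpm`` is the only systematic arm
    difference (a known truth for recovery experiments).

    Returns a list of ``(uas_log, cis_log)`` pairs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    pairs = []
    for pid, child_ss in enumerate(ss.spawn(n)):
        param_seed, uas_seed, cis_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in child_ss.spawn(3)
        ]
        p = sample_participant(
            pid, np.random.default_rng(param_seed), **(participant_overrides or {})
        )
        uas = simulate_session(
            p,
            "UAS",
            scenarios,
            protocol,
            thresholds,
            initial_states=initial_states,
            seed=uas_seed,
            hr_offset_bpm=arm_effect_bpm,
            adaptive=True if adaptive_uas else False,
        )
        cis = simulate_session(
            p, "CIS", scenarios, protocol, thresholds,
            initial_states=initial_states, seed=cis_seed,
        )
        pairs.append((uas, cis))
    return pairs
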