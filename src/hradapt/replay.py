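"""Deterministic re-execution of recorded sessions (regression harness).

Every telemetry row carries the controller state *after* its tick together
with the inputs that produced it (press flags, resolved blocks). Replaying a
session therefore needs no random numbers: starting from the configured
initial states, the engine is stepped with the recorded inputs and the
recorded ``avgHR``/``w`` values, and each resulting state must match the
recorded snapshot bit for bit. Any divergence — e.g. replaying a log under
the other scenario-1 sign mode — is reported at the first differing tick.

Configuration-identity fields (``mode``, ``interpretation``) are excluded
from the comparison so that a frozen-difficulty (CIS) log replays cleanly
under either mode; a genuine behavioural difference always shows up in the
numeric state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

from .engine import (
    RateInterpretation,
    Scenario1Mode,
    ScenarioController,
    Thresholds,
    make_cis_controller,
    make_uas_controller,
)
from .session import SessionLog
from .simulate import encode_tick, state_to_dict

__all__ = ["ReplayDivergence", "ReplayResult", "replay_session"]

_CONFIG_KEYS = {"mode", "interpretation"}


@dataclass(frozen=True)
class ReplayDivergence:
    tick: int  # row index within the log
    t: float
    scenario: object
    recorded: dict
    replayed: dict


@dataclass(frozen=True)
class ReplayResult:
    ok: bool
    n_ticks: int
    divergence: ReplayDivergence | None = None


def _dynamic(d: dict) -> dict:
    return {k: v for k, v in d.items() if k not in _CONFIG_KEYS}


def replay_session(
    log: SessionLog,
    thresholds: Thresholds | None = None,
    initial_states: dict | None = None,
    warmup_samples: int = 5,
    mode: Scenario1Mode | None = None,
    interpretation: RateInterpretation | None = None,
) -> ReplayResult:
    """Re-run the engine over a recorded session and compare state traces.

    *mode* / *interpretation* override the scenario-1 sign convention and
    the scenario-3 unit reading, to probe what a different engine build
    would have done with the same inputs.
    """
    thresholds = thresholds or Thresholds()
    make = make_uas_controller if log.arm == "UAS" else make_cis_controller
    ctrl: ScenarioController | None = None
    current_scenario: object = object()
    for i, row in enumerate(log.rows):
        if row.scenario != current_scenario:
            current_scenario = row.scenario
            init = (initial_states or {}).get(row.scenario)
            ctrl = make(row.scenario, initial_state=init, thresholds=thresholds)
            if row.scenario == 1 and mode is not None:
                ctrl.state = replace(ctrl.state, mode=mode)
            if row.scenario == 3 and interpretation is not None:
                ctrl.state = replace(ctrl.state, interpretation=interpretation)
        recorded = json.loads(row.state_json)
        inputs = recorded.get("inputs", {})
        warmed = (i + 1) >= warmup_samples
        adaptive = ctrl.adaptive
        ctrl.adaptive = adaptive and warmed
        try:
            if row.scenario == 1:
                if inputs.get("stepped", True):
                    ctrl.step(avg_hr=row.avg_hr, w=row.w)
            elif row.scenario == 2:
                ctrl.step(
                    button_pressed=bool(inputs.get("pressed", False)),
                    avg_hr=row.avg_hr if row.avg_hr is not None else 0.0,
                    dt=1.0,
                )
            elif row.scenario == 3:
                for success in inputs.get("blocks", []):
                    ctrl.step(
                        s_pressed=bool(success),
                        s_onscreen=bool(success),
                        avg_hr=row.avg_hr if row.avg_hr is not None else 0.0,
                    )
            elif row.scenario == "test":
                ctrl.step(
                    last_hr=row.avg_hr if row.avg_hr is not None else 0.0, dt=1.0
                )
            else:
                raise ValueError(f"row {i}: unknown scenario {row.scenario!r}")
        finally:
            ctrl.adaptive = adaptive
        replayed = state_to_dict(ctrl.state)
        if _dynamic(replayed) != _dynamic(recorded.get("state", {})):
            return ReplayResult(
                False,
                len(log.rows),
                ReplayDivergence(i, row.t, row.scenario, recorded.get("state", {}), replayed),
            )
    return ReplayResult(True, len(log.rows))
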