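"""Run configuration: YAML schema, defaults and validation.

One :class:`RunConfig` aggregates every tunable constant of the pipeline —
signal scaling and calibration, controller thresholds and per-scenario
parameters, simulation protocol and cohort size. All defaults are the
deployed system's constants: 95/105 bpm boundaries, 9.13 bpm band offset,
initial countdown 10 s within [5, 15], initial generation rate 0.366 with
±0.1 steps capped at 5 x 0.366, the 80 bpm / 20 s test-scenario rule, and
1 Hz sampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .engine import (
    RateInterpretation,
    Scenario1Mode,
    Scenario1State,
    Scenario2State,
    Scenario3State,
    TestScenarioState,
    Thresholds,
)
from .signal_ingest import CalibrationConfig, ScaleConfig
from .simulate import ProtocolConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """A configuration value failed validation; the message names the key."""


@dataclass
class RunConfig:
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    scenario1: Scenario1State = field(default_factory=Scenario1State)
    scenario2: Scenario2State = field(default_factory=Scenario2State)
    scenario3: Scenario3State = field(default_factory=Scenario3State)
    test_scenario: TestScenarioState = field(default_factory=TestScenarioState)
    warmup_samples: int = 5
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    n_participants: int = 30
    master_seed: int = 0
    conf_level: float = 0.95

    def initial_states(self) -> dict:
        return {
            1: self.scenario1,
            2: self.scenario2,
            3: self.scenario3,
            "test": self.test_scenario,
        }

    def to_dict(self) -> dict:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (Scenario1Mode, RateInterpretation)):
                return obj.value
            return obj

        return {
            "signal": {"scale": enc(self.scale), "calibration": enc(self.calibration)},
            "engine": {
                "thresholds": enc(self.thresholds),
                "scenario1": enc(self.scenario1),
                "scenario2": enc(self.scenario2),
                "scenario3": enc(self.scenario3),
                "test_scenario": enc(self.test_scenario),
                "warmup_samples": self.warmup_samples,
            },
            "sim": {
                "protocol": enc(self.protocol),
                "n_participants": self.n_participants,
                "master_seed": self.master_seed,
            },
            "eval": {"conf_level": self.conf_level},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(factory, data: dict | None, path: str, coerce: dict | None = None):
            data = dict(data or {})
            for key, enum_cls in (coerce or {}).items():
                if key in data:
                    data[key] = enum_cls(data[key])
            try:
                return factory(**data)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{path}: {exc}") from exc

        signal = d.get("signal") or {}
        engine = d.get("engine") or {}
        sim = d.get("sim") or {}
        ev = d.get("eval") or {}
        cfg = cls(
            scale=build(ScaleConfig, signal.get("scale"), "signal.scale"),
            calibration=build(CalibrationConfig, signal.get("calibration"), "signal.calibration"),
            thresholds=build(Thresholds, engine.get("thresholds"), "engine.thresholds"),
            scenario1=build(
                Scenario1State, engine.get("scenario1"), "engine.scenario1",
                {"mode": Scenario1Mode},
            ),
            scenario2=build(Scenario2State, engine.get("scenario2"), "engine.scenario2"),
            scenario3=build(
                Scenario3State, engine.get("scenario3"), "engine.scenario3",
                {"interpretation": RateInterpretation},
            ),
            test_scenario=build(
                TestScenarioState, engine.get("test_scenario"), "engine.test_scenario"
            ),
            warmup_samples=int(engine.get("warmup_samples", 5)),
            protocol=build(ProtocolConfig, sim.get("protocol"), "sim.protocol"),
            n_participants=int(sim.get("n_participants", 30)),
            master_seed=int(sim.get("master_seed", 0)),
            conf_level=float(ev.get("conf_level", 0.95)),
        )
        if cfg.warmup_samples < 0:
            raise ConfigError("engine.warmup_samples: must be non-negative")
        if cfg.n_participants < 1:
            raise ConfigError("sim.n_participants: must be >= 1")
        if not 0 < cfg.conf_level < 1:
            raise ConfigError("eval.conf_level: must lie in (0, 1)")
        return cfg


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; a missing path yields all defaults."""
    if path is None:
        return RunConfig()
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(data)


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return path
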