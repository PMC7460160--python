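"""Wearable heart-rate stream ingestion.

Turns raw 1 Hz wrist-band readings into the calibrated, cleaned and scaled
quantities the difficulty controllers consume: the rolling-window weight ``w``
(mean of the last 20 scaled readings, each in [0, 1]) and ``avgHR`` (mean of
the corresponding raw readings in bpm).

Two physical bands were used interchangeably in the original deployment; the
second band reads systematically higher than the first, so a fixed offset
(9.13 bpm by default, established in a stair-stepping calibration test) is
subtracted from its readings. Simulated streams bypass calibration.
"""

from __future__ import annotations

import csv
import json
import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Device",
    "HRSample",
    "CalibrationConfig",
    "ScaleConfig",
    "ScaledWindow",
    "CleanReport",
    "SignalQualityError",
    "InsufficientSignalError",
    "apply_calibration",
    "clean_stream",
    "scale_hr",
    "push_sample",
    "window_weight",
    "avg_hr",
    "read_hr_stream",
]

WINDOW_CAPACITY = 20  # controllers smooth over the last 20 readings


class Device(str, Enum):
    """Origin of a heart-rate reading."""

    BAND1 = "band1"
    BAND2 = "band2"
    SIMULATED = "simulated"


class SignalQualityError(ValueError):
    """Raised when a reading or stream is unusable (non-finite, empty)."""


class InsufficientSignalError(SignalQualityError):
    """Raised when a window holds no samples to average."""


@dataclass(frozen=True)
class HRSample:
    """One heart-rate reading: seconds since session start, bpm, source device."""

    t: float
    bpm: float
    device: Device = Device.SIMULATED

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"timestamp must be non-negative, got {self.t}")


@dataclass(frozen=True)
class CalibrationConfig:
    """Inter-device offset and physiological plausibility bounds.

    ``band2_offset_bpm`` is subtracted from every band-2 reading so that both
    bands report on the band-1 scale. Readings outside
    ``[outlier_floor_bpm, outlier_ceiling_bpm]`` are suppressed as outliers.
    """

    band2_offset_bpm: float = 9.13
    outlier_floor_bpm: float = 40.0
    outlier_ceiling_bpm: float = 220.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.band2_offset_bpm):
            raise ValueError("band2_offset_bpm must be finite")
        if not self.outlier_floor_bpm < self.outlier_ceiling_bpm:
            raise ValueError(
                f"outlier floor ({self.outlier_floor_bpm}) must be below "
                f"ceiling ({self.outlier_ceiling_bpm})"
            )


@dataclass(frozen=True)
class ScaleConfig:
    """Linear bpm -> [0,1] map over ``[hr_lo, hr_hi]``, clamped.

    Defaults span the child resting-to-maximal range (60-200 bpm).
    """

    hr_lo: float = 60.0
    hr_hi: float = 200.0

    def __post_init__(self) -> None:
        if not self.hr_lo < self.hr_hi:
            raise ValueError(f"hr_lo ({self.hr_lo}) must be below hr_hi ({self.hr_hi})")


@dataclass
class ScaledWindow:
    """Ring buffer of the last ``capacity`` readings, raw and scaled in lockstep."""

    capacity: int = WINDOW_CAPACITY
    values: deque = field(default_factory=deque)  # scaled, in [0,1]
    raw_values: deque = field(default_factory=deque)  # bpm

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.values = deque(self.values, maxlen=self.capacity)
        self.raw_values = deque(self.raw_values, maxlen=self.capacity)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CleanReport:
    """Bookkeeping for :func:`clean_stream`."""

    n_in: int
    n_out: int
    n_missing: int
    n_outliers: int


def apply_calibration(sample: HRSample, cfg: CalibrationConfig | None = None) -> HRSample:
    """Return *sample* on the band-1 bpm scale.

    Band-2 readings have the configured offset subtracted; band-1 and
    simulated readings pass through unchanged.
    """
    cfg = cfg or CalibrationConfig()
    if not math.isfinite(sample.bpm):
        raise SignalQualityError(f"non-finite bpm at t={sample.t}")
    if sample.device is Device.BAND2:
        return HRSample(sample.t, sample.bpm - cfg.band2_offset_bpm, sample.device)
    return sample


def clean_stream(
    samples: Sequence[HRSample],
    cfg: CalibrationConfig | None = None,
) -> tuple[list[HRSample], CleanReport]:
    """Drop empty records and suppress outliers, preserving order.

    Missing readings (NaN bpm) and readings outside the configured
    physiological bounds are removed. Raises
    :class:`SignalQualityError` if nothing usable remains.
    """
    cfg = cfg or CalibrationConfig()
    kept: list[HRSample] = []
    n_missing = 0
    n_outliers = 0
    for s in samples:
        if s.bpm is None or not math.isfinite(s.bpm):
            n_missing += 1
            continue
        if not cfg.outlier_floor_bpm <= s.bpm <= cfg.outlier_ceiling_bpm:
            n_outliers += 1
            continue
        kept.append(s)
    if not kept:
        raise SignalQualityError(
            f"no usable signal: {len(samples)} samples in, "
            f"{n_missing} missing, {n_outliers} outliers"
        )
    report = CleanReport(len(samples), len(kept), n_missing, n_outliers)
    return kept, report


def scale_hr(bpm: float, cfg: ScaleConfig | None = None) -> float:
    """Map a bpm reading linearly onto [0, 1], clamping outside the range."""
    cfg = cfg or ScaleConfig()
    if not math.isfinite(bpm):
        raise SignalQualityError(f"non-finite bpm {bpm!r}")
    x = (bpm - cfg.hr_lo) / (cfg.hr_hi - cfg.hr_lo)
    return min(1.0, max(0.0, x))


def push_sample(
    window: ScaledWindow,
    sample: HRSample,
    cfg: ScaleConfig | None = None,
) -> ScaledWindow:
    """Append a calibrated, cleaned sample; evicts the oldest entry at capacity.

    Mutates and returns *window* (the deque maxlen enforces eviction).
    """
    window.values.append(scale_hr(sample.bpm, cfg))
    window.raw_values.append(sample.bpm)
    return window


def window_weight(window: ScaledWindow) -> float:
    """``w``: arithmetic mean of the scaled values currently in the window.

    With fewer than ``capacity`` samples the mean is taken over what is
    available.
    """
    if len(window) == 0:
        raise InsufficientSignalError("window is empty")
    return sum(window.values) / len(window.values)


def avg_hr(window: ScaledWindow) -> float:
    """``avgHR``: arithmetic mean (bpm) of the raw values in the window."""
    if len(window) == 0:
        raise InsufficientSignalError("window is empty")
    return sum(window.raw_values) / len(window.raw_values)


def _parse_device(raw: str) -> Device:
    try:
        return Device(raw.strip().lower())
    except ValueError as exc:
        raise SignalQualityError(f"unknown device {raw!r}") from exc


def read_hr_stream(path: str | Path) -> list[HRSample]:
    """Read a raw HR stream from CSV (header ``t,bpm,device``) or JSON-lines.

    Missing bpm (empty CSV field or JSON null) becomes NaN so that
    :func:`clean_stream` can account for it. The format is chosen from the
    file suffix (``.jsonl``/``.ndjson`` vs anything else -> CSV).
    """
    path = Path(path)
    samples: list[HRSample] = []
    if path.suffix in {".jsonl", ".ndjson"}:
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                bpm = rec.get("bpm")
                samples.append(
                    HRSample(
                        float(rec["t"]),
                        math.nan if bpm is None else float(bpm),
                        _parse_device(rec.get("device", "simulated")),
                    )
                )
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"t", "bpm"} <= set(reader.fieldnames):
                raise SignalQualityError(
                    f"expected header with 't,bpm[,device]', got {reader.fieldnames}"
                )
            for rec in reader:
                bpm_raw = (rec.get("bpm") or "").strip()
                samples.append(
                    HRSample(
                        float(rec["t"]),
                        float(bpm_raw) if bpm_raw else math.nan,
                        _parse_device(rec.get("device") or "simulated"),
                    )
                )
    for a, b in zip(samples, samples[1:]):
        if b.t < a.t:
            raise SignalQualityError(f"timestamps decrease at t={b.t}")
    return samples
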