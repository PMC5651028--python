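"""Serialization: event logs (CSV), motor maps (JSON), YAML configuration.

Event-log CSV columns (exactly, in order): slot_time_s, electrode_id, x_mm,
y_mm, intensity_pct, amplitude_uv, significant. Motor-map JSON carries grid
geometry, per-electrode MT in both % MSO and mA, an explicit status string
(no sentinel numbers), algorithm, muscle and seed. ``read(write(x))`` is an
identity for both formats.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import pandas as pd
import yaml

from .mt_core import IntensityGrid, MTEstimate
from .scheduler import MotorMap, ScheduleConfig, StimEvent
from .virtual_subject import ArrayGeometry, GeneratorParams

__all__ = [
    "EVENT_LOG_COLUMNS",
    "LogValidationError",
    "write_event_log",
    "read_event_log",
    "validate_event_log",
    "write_motor_map",
    "read_motor_map",
    "Config",
    "load_config",
    "save_config",
]

EVENT_LOG_COLUMNS = [
    "slot_time_s",
    "electrode_id",
    "x_mm",
    "y_mm",
    "intensity_pct",
    "amplitude_uv",
    "significant",
]


class LogValidationError(ValueError):
    """An event log violates a timing or format invariant."""


def write_event_log(path, events: List[StimEvent], geometry: ArrayGeometry) -> None:
    pos = geometry.positions()
    rows = [
        {
            "slot_time_s": ev.slot_time_s,
            "electrode_id": ev.electrode_id,
            "x_mm": pos[ev.electrode_id, 0],
            "y_mm": pos[ev.electrode_id, 1],
            "intensity_pct": ev.intensity_pct,
            "amplitude_uv": ev.mep_amplitude_uv,
            "significant": ev.significant,
        }
        for ev in events
    ]
    # %.17g guarantees bit-exact float round-trips
    pd.DataFrame(rows, columns=EVENT_LOG_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_event_log(path) -> List[StimEvent]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise LogValidationError(f"cannot parse event log {path}: {exc}") from exc
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise LogValidationError(f"event log missing columns {missing}")
    events = []
    for i, row in df.iterrows():
        try:
            events.append(
                StimEvent(
                    slot_time_s=float(row["slot_time_s"]),
                    electrode_id=int(row["electrode_id"]),
                    intensity_pct=float(row["intensity_pct"]),
                    mep_amplitude_uv=float(row["amplitude_uv"]),
                    significant=bool(row["significant"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise LogValidationError(f"malformed event-log row {i + 2}: {exc}") from exc
    return events


def validate_event_log(
    events: List[StimEvent], config: ScheduleConfig
) -> List[str]:
    """Check the timing invariants; returns human-readable violations.

    * every slot time is an integer multiple of the slot width;
    * per electrode, successive stimuli are at least the refractory apart.
    """
    problems = []
    slot = config.slot_s
    last: dict = {}
    for i, ev in enumerate(events):
        k = ev.slot_time_s / slot
        if abs(k - round(k)) > 1e-6:
            problems.append(
                f"event {i}: slot_time {ev.slot_time_s} not a multiple of {slot}"
            )
        prev = last.get(ev.electrode_id)
        if prev is not None and ev.slot_time_s - prev < config.refractory_s - 1e-9:
            problems.append(
                f"event {i}: electrode {ev.electrode_id} re-stimulated "
                f"{ev.slot_time_s - prev:.3f} s after previous (< {config.refractory_s} s)"
            )
        last[ev.electrode_id] = ev.slot_time_s
    return problems


# ---------------------------------------------------------------------------
# Motor maps
# ---------------------------------------------------------------------------

def write_motor_map(path, motor_map: MotorMap) -> None:
    pos = motor_map.positions()
    payload = {
        "grid": asdict(motor_map.grid),
        "geometry": asdict(motor_map.geometry),
        "algorithm": motor_map.algorithm,
        "muscle": motor_map.muscle,
        "session": motor_map.session,
        "seed": motor_map.seed,
        "electrodes": [
            {
                "electrode_id": e.electrode_id,
                "x_mm": float(pos[e.electrode_id, 0]),
                "y_mm": float(pos[e.electrode_id, 1]),
                "status": e.status,
                "mt_pct": e.mt_pct,
                "mt_ma": e.mt_ma,
                "n_stimuli_used": e.n_stimuli_used,
            }
            for e in motor_map.estimates
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_motor_map(path) -> MotorMap:
    payload = json.loads(Path(path).read_text())
    grid = IntensityGrid(**payload["grid"])
    geometry = ArrayGeometry(**payload["geometry"])
    estimates = [
        MTEstimate(
            electrode_id=rec["electrode_id"],
            mt_pct=rec["mt_pct"],
            n_stimuli_used=rec["n_stimuli_used"],
            algorithm=payload["algorithm"],
            mso_ma=grid.mso_ma,
        )
        for rec in sorted(payload["electrodes"], key=lambda r: r["electrode_id"])
    ]
    return MotorMap(
        geometry=geometry,
        estimates=estimates,
        grid=grid,
        algorithm=payload["algorithm"],
        muscle=payload["muscle"],
        session=payload.get("session", ""),
        seed=payload.get("seed"),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """One YAML-serializable schema covering grid, array geometry, stimulus
    train metadata, generator, scheduler and statistics parameters."""

    grid: IntensityGrid = field(default_factory=IntensityGrid)
    geometry: ArrayGeometry = field(default_factory=ArrayGeometry)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    stim_train: dict = field(
        default_factory=lambda: {
            "n_pulses": 10,
            "pulse_width_us": 500,
            "train_rate_hz": 1000,
            "polarity": "cathode-first",
        }
    )
    novel_frequency_hz: float = 4.0
    conventional_frequency_hz: float = 1.0
    refractory_s: float = 2.0
    start_pct: float = 50.0
    nonresponsive_repeats: int = 1
    n_perm: int = 2000
    alpha: float = 0.01

    def schedule(self, algorithm: str, seed=0) -> ScheduleConfig:
        if algorithm == "novel":
            return ScheduleConfig(
                stim_frequency_hz=self.novel_frequency_hz,
                refractory_s=self.refractory_s,
                n_electrodes=self.geometry.n_electrodes,
                seed=seed,
                start_pct=self.start_pct,
                nonresponsive_repeats=self.nonresponsive_repeats,
            )
        return ScheduleConfig(
            stim_frequency_hz=self.conventional_frequency_hz,
            refractory_s=0.0,
            n_electrodes=self.geometry.n_electrodes,
            seed=seed,
            start_pct=self.start_pct,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["theta_hot_range"] = list(d["generator"]["theta_hot_range"])
        return d


def load_config(path) -> Config:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "grid" in kwargs:
        kwargs["grid"] = IntensityGrid(**kwargs["grid"])
    if "geometry" in kwargs:
        kwargs["geometry"] = ArrayGeometry(**kwargs["geometry"])
    if "generator" in kwargs:
        gen = dict(kwargs["generator"])
        if "theta_hot_range" in gen:
            gen["theta_hot_range"] = tuple(gen["theta_hot_range"])
        kwargs["generator"] = GeneratorParams(**gen)
    return Config(**kwargs)


def save_config(path, config: Config) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
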