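"""Closed-loop mapping engine.

Interleaves MT estimation across the electrodes of a surface array on a
fixed stimulus-slot clock. At every slot (``k / stim_frequency`` seconds)
one electrode is drawn uniformly at random among those still unresolved and
outside their refractory window, and receives the intensity its estimator
demands; if no electrode is eligible a pause slot is recorded. Mapping ends
when every electrode is resolved or nonresponsive.

The fast ("novel") protocol runs at 4 Hz with a 2-s same-electrode
refractory window; the conventional protocol runs at 1 Hz with no extra
refractory (the 1-s slot spacing already exceeds conventional practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Union

import numpy as np

from .mt_core import (
    ConventionalState,
    IntensityGrid,
    MTEstimate,
    TrackerState,
)
from .virtual_subject import ArrayGeometry, VirtualSubject

__all__ = [
    "ScheduleConfig",
    "StimEvent",
    "MotorMap",
    "MappingResult",
    "eligible_electrodes",
    "run_mapping",
    "mapping_duration",
]

#: Stimulus-train constants carried as metadata only; within-train dynamics
#: (10 biphasic 500-μs pulses, cathode first, at 1000 Hz) are not simulated.
STIMULUS_TRAIN = {
    "n_pulses": 10,
    "pulse_width_us": 500,
    "train_rate_hz": 1000,
    "polarity": "cathode-first",
}


@dataclass(frozen=True)
class ScheduleConfig:
    """Slot clock and refractory rules for one mapping session."""

    stim_frequency_hz: float = 4.0
    refractory_s: float = 2.0
    n_electrodes: int = 32
    seed: Union[int, Sequence[int]] = 0
    start_pct: float = 50.0
    nonresponsive_repeats: int = 1

    def __post_init__(self) -> None:
        if self.stim_frequency_hz <= 0:
            raise ValueError("stimulus frequency must be positive")
        if self.refractory_s < 0:
            raise ValueError("refractory must be nonnegative")

    @property
    def slot_s(self) -> float:
        return 1.0 / self.stim_frequency_hz

    @classmethod
    def novel(cls, seed=0, **kw) -> "ScheduleConfig":
        return cls(stim_frequency_hz=4.0, refractory_s=2.0, seed=seed, **kw)

    @classmethod
    def conventional(cls, seed=0, **kw) -> "ScheduleConfig":
        return cls(stim_frequency_hz=1.0, refractory_s=0.0, seed=seed, **kw)


@dataclass(frozen=True)
class StimEvent:
    """One delivered stimulus; the event log is the timing audit trail."""

    slot_time_s: float
    electrode_id: int
    intensity_pct: float
    mep_amplitude_uv: float
    significant: bool


@dataclass
class MotorMap:
    """Per-electrode MT estimates with grid coordinates and metadata."""

    geometry: ArrayGeometry
    estimates: List[MTEstimate]
    grid: IntensityGrid = field(default_factory=IntensityGrid)
    algorithm: str = "novel"
    muscle: str = "ECR"
    session: str = ""
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.estimates) != self.geometry.n_electrodes:
            raise ValueError("one estimate per electrode required")

    def positions(self) -> np.ndarray:
        return self.geometry.positions()

    def mt_pct_array(self) -> np.ndarray:
        """MT in % MSO, NaN at nonresponsive electrodes."""
        return np.array(
            [np.nan if e.mt_pct is None else e.mt_pct for e in self.estimates]
        )

    def mt_ma_array(self) -> np.ndarray:
        return self.mt_pct_array() / 100.0 * self.grid.mso_ma

    @property
    def n_nonresponsive(self) -> int:
        return sum(not e.responsive for e in self.estimates)


@dataclass
class MappingResult:
    motor_map: MotorMap
    event_log: List[StimEvent]
    duration_s: float
    n_stimuli: int
    n_pause_slots: int
    config: ScheduleConfig

    def per_electrode_counts(self) -> Dict[int, int]:
        counts: Dict[int, int] = {}
        for ev in self.event_log:
            counts[ev.electrode_id] = counts.get(ev.electrode_id, 0) + 1
        return counts


def eligible_electrodes(
    clock_time_s: float,
    unresolved: Set[int],
    last_stim_times: Dict[int, float],
    config: ScheduleConfig,
) -> Set[int]:
    """Unresolved electrodes whose last stimulus lies at least the
    refractory interval before ``clock_time_s`` (never-stimulated electrodes
    are always eligible)."""
    out = set()
    for e in unresolved:
        last = last_stim_times.get(e)
        if last is None or clock_time_s - last >= config.refractory_s - 1e-9:
            out.add(e)
    return out


def _make_estimator(algorithm: str, grid: IntensityGrid, config: ScheduleConfig):
    if algorithm == "novel":
        return TrackerState(
            grid=grid,
            start_pct=config.start_pct,
            nonresponsive_repeats=config.nonresponsive_repeats,
        )
    if algorithm == "conventional":
        return ConventionalState(grid=grid, start_pct=config.start_pct)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def run_mapping(
    subject: VirtualSubject,
    algorithm: str,
    config: ScheduleConfig,
    muscle: str = "ECR",
    session: str = "",
    rng: Optional[np.random.Generator] = None,
    max_slots: int = 2_000_000,
) -> MappingResult:
    """Map all electrodes of ``subject`` with one MT criterion.

    A single seeded generator drives both the electrode draw and the
    subject's stochastic responses, so a full session is reproducible from
    ``config.seed``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    grid = subject.grid
    n = subject.n_electrodes
    if config.n_electrodes != n:
        raise ValueError("config.n_electrodes does not match the subject array")
    estimators = {e: _make_estimator(algorithm, grid, config) for e in range(n)}
    unresolved: Set[int] = set(range(n))
    last_stim: Dict[int, float] = {}
    events: List[StimEvent] = []
    n_pauses = 0

    k = 0
    while unresolved:
        if k >= max_slots:
            raise RuntimeError("mapping failed to terminate")
        t = k * config.slot_s
        elig = eligible_electrodes(t, unresolved, last_stim, config)
        if elig:
            electrode = int(rng.choice(sorted(elig)))
            est = estimators[electrode]
            intensity = est.next_intensity()
            amplitude, significant = subject.respond(electrode, intensity, rng)
            est.observe(intensity, significant)
            events.append(StimEvent(t, electrode, intensity, amplitude, significant))
            last_stim[electrode] = t
            if est.status != "running":
                unresolved.discard(electrode)
        else:
            n_pauses += 1
        k += 1

    estimates = [
        MTEstimate(
            electrode_id=e,
            mt_pct=estimators[e].mt_pct,
            n_stimuli_used=len(estimators[e].intensity_history)
            if algorithm == "novel"
            else estimators[e].n_stimuli,
            algorithm=algorithm,
            mso_ma=grid.mso_ma,
        )
        for e in range(n)
    ]
    seed = config.seed if isinstance(config.seed, int) else None
    motor_map = MotorMap(
        geometry=subject.geometry,
        estimates=estimates,
        grid=grid,
        algorithm=algorithm,
        muscle=muscle,
        session=session,
        seed=seed,
    )
    duration = mapping_duration(events, config)
    return MappingResult(motor_map, events, duration, len(events), n_pauses, config)


def mapping_duration(event_log: Sequence[StimEvent], config: ScheduleConfig) -> float:
    """Elapsed mapping time: closed span of occupied slots plus one slot
    width; pause slots inside the span count, trailing pauses do not."""
    if not event_log:
        raise ValueError("empty event log")
    first = event_log[0].slot_time_s
    last = event_log[-1].slot_time_s
    return last - first + config.slot_s
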