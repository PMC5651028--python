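"""Motor-threshold (MT) estimation criteria.

Two relative-frequency MT criteria operate on a stream of
``(intensity, significant?)`` observations for a single electrode:

* the **tracking** ("novel") criterion — a ±1-step staircase in the style of
  peripheral-nerve threshold tracking, with a stopping rule that resolves the
  MT as the mean of the last two intensities once the staircase has settled
  onto two adjacent levels;
* the **conventional** criterion — the lowest intensity evoking a significant
  motor evoked potential (MEP) in at least 5 of 10 consecutive trials,
  with pigeonhole early stopping per level.

Intensities live on a discrete grid expressed in % of maximum stimulator
output (MSO), 20–100% in 5% steps by default, with 100% MSO = 1.0 mA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

__all__ = [
    "IntensityGrid",
    "TrackerState",
    "LevelTally",
    "MTEstimate",
    "InvalidIntensityError",
    "InvalidStateError",
    "novel_next_intensity",
    "novel_check_stop",
    "novel_estimate_mt",
    "conv_update_level",
    "conv_estimate_mt",
    "NONRESPONSIVE",
]

#: Sentinel returned by :func:`novel_next_intensity` when the staircase
#: demands an intensity above the grid maximum (no significant MEP at 100%
#: MSO), i.e. the electrode is nonresponsive.
NONRESPONSIVE = "nonresponsive"


class InvalidIntensityError(ValueError):
    """An intensity does not lie on the stimulus grid."""


class InvalidStateError(RuntimeError):
    """An estimator state machine was advanced from a terminal state."""


@dataclass(frozen=True)
class IntensityGrid:
    """Discrete stimulus-intensity grid in % MSO.

    Parameters
    ----------
    min_pct, max_pct, step_pct
        Grid bounds and spacing in % MSO. ``max_pct - min_pct`` must be an
        integer multiple of ``step_pct``.
    mso_ma
        Stimulator output at 100% MSO, in mA.
    """

    min_pct: float = 20.0
    max_pct: float = 100.0
    step_pct: float = 5.0
    mso_ma: float = 1.0

    def __post_init__(self) -> None:
        if self.step_pct <= 0 or self.min_pct >= self.max_pct:
            raise ValueError("grid requires min < max and step > 0")
        span = self.max_pct - self.min_pct
        n = round(span / self.step_pct)
        if abs(n * self.step_pct - span) > 1e-9:
            raise ValueError("(max - min) must be divisible by step")

    @property
    def levels(self) -> List[float]:
        n = round((self.max_pct - self.min_pct) / self.step_pct)
        return [self.min_pct + i * self.step_pct for i in range(n + 1)]

    def contains(self, intensity_pct: float) -> bool:
        if not (self.min_pct - 1e-9 <= intensity_pct <= self.max_pct + 1e-9):
            return False
        k = (intensity_pct - self.min_pct) / self.step_pct
        return abs(k - round(k)) < 1e-9

    def require(self, intensity_pct: float) -> None:
        if not self.contains(intensity_pct):
            raise InvalidIntensityError(
                f"intensity {intensity_pct}% MSO is not on the "
                f"{self.min_pct}:{self.max_pct}:{self.step_pct} grid"
            )

    def to_ma(self, intensity_pct: float) -> float:
        return intensity_pct / 100.0 * self.mso_ma


@dataclass
class MTEstimate:
    """Per-electrode MT estimate.

    ``mt_pct`` is ``None`` iff the electrode is nonresponsive (no significant
    MEP at 100% MSO).
    """

    electrode_id: int
    mt_pct: Optional[float]
    n_stimuli_used: int
    algorithm: str  # "novel" | "conventional"
    mso_ma: float = 1.0

    @property
    def responsive(self) -> bool:
        return self.mt_pct is not None

    @property
    def mt_ma(self) -> Optional[float]:
        return None if self.mt_pct is None else self.mt_pct / 100.0 * self.mso_ma

    @property
    def status(self) -> str:
        return "resolved" if self.responsive else "nonresponsive"


# ---------------------------------------------------------------------------
# Novel (threshold-tracking) criterion
# ---------------------------------------------------------------------------

def novel_next_intensity(current: float, significant: bool, grid: IntensityGrid):
    """One staircase update: down one step after a significant MEP, up one
    step otherwise; clamped at the grid floor; returns :data:`NONRESPONSIVE`
    when an increase above the grid ceiling is demanded.
    """
    grid.require(current)
    if significant:
        return max(current - grid.step_pct, grid.min_pct)
    if current >= grid.max_pct - 1e-9:
        return NONRESPONSIVE
    return current + grid.step_pct


def novel_check_stop(intensity_history: List[float], grid: Optional[IntensityGrid] = None) -> bool:
    """True once the last five delivered intensities span at most one step,
    i.e. the staircase is confined to two adjacent levels.
    """
    step = (grid or IntensityGrid()).step_pct
    if len(intensity_history) < 5:
        return False
    last5 = intensity_history[-5:]
    return max(last5) - min(last5) <= step + 1e-9


@dataclass
class TrackerState:
    """State machine for the tracking criterion on one electrode.

    Feed observations with :meth:`observe`; query the next demanded
    intensity with :meth:`next_intensity`. ``status`` moves from ``running``
    to ``resolved`` (``mt_pct`` set to the mean of the last two intensities)
    or ``nonresponsive``.

    ``nonresponsive_repeats`` requires that many consecutive nonsignificant
    trials at the grid ceiling before declaring the electrode nonresponsive.
    """

    grid: IntensityGrid = field(default_factory=IntensityGrid)
    start_pct: float = 50.0
    nonresponsive_repeats: int = 1
    intensity_history: List[float] = field(default_factory=list)
    response_history: List[bool] = field(default_factory=list)
    status: str = "running"
    mt_pct: Optional[float] = None
    _fails_at_max: int = 0
    _next: Optional[float] = None

    def __post_init__(self) -> None:
        self.grid.require(self.start_pct)
        self._next = self.start_pct

    def next_intensity(self) -> float:
        if self.status != "running":
            raise InvalidStateError(f"tracker already {self.status}")
        return self._next

    def observe(self, intensity_pct: float, significant: bool) -> None:
        if self.status != "running":
            raise InvalidStateError(f"tracker already {self.status}")
        self.grid.require(intensity_pct)
        self.intensity_history.append(intensity_pct)
        self.response_history.append(bool(significant))
        if novel_check_stop(self.intensity_history, self.grid):
            self.status = "resolved"
            self.mt_pct = (self.intensity_history[-1] + self.intensity_history[-2]) / 2.0
            return
        nxt = novel_next_intensity(intensity_pct, significant, self.grid)
        if nxt == NONRESPONSIVE:
            # nonsignificant at the grid ceiling
            self._fails_at_max += 1
            if self._fails_at_max >= self.nonresponsive_repeats:
                self.status = "nonresponsive"
                return
            nxt = self.grid.max_pct  # retry the ceiling
        else:
            self._fails_at_max = 0
        self._next = nxt

    @property
    def n_stimuli(self) -> int:
        return len(self.intensity_history)


def novel_estimate_mt(
    responder: Callable[[float], bool],
    start: float = 50.0,
    grid: Optional[IntensityGrid] = None,
    electrode_id: int = 0,
    nonresponsive_repeats: int = 1,
    max_stimuli: int = 10_000,
) -> MTEstimate:
    """Run the tracking staircase against ``responder(intensity) -> bool``."""
    grid = grid or IntensityGrid()
    st = TrackerState(grid=grid, start_pct=start, nonresponsive_repeats=nonresponsive_repeats)
    while st.status == "running":
        if st.n_stimuli >= max_stimuli:
            raise RuntimeError("staircase failed to terminate")
        intensity = st.next_intensity()
        st.observe(intensity, responder(intensity))
    return MTEstimate(electrode_id, st.mt_pct, st.n_stimuli, "novel", grid.mso_ma)


# ---------------------------------------------------------------------------
# Conventional (5-of-10) criterion
# ---------------------------------------------------------------------------

@dataclass
class LevelTally:
    """Running 5-of-10 tally at one intensity level.

    Classification stops early: ``positive`` as soon as 5 significant MEPs
    are observed, ``negative`` as soon as 6 nonsignificant MEPs make 5-of-10
    impossible.
    """

    level_pct: float
    n_significant: int = 0
    n_nonsignificant: int = 0
    classification: str = "pending"  # pending | positive | negative

    @property
    def n_trials(self) -> int:
        return self.n_significant + self.n_nonsignificant


def conv_update_level(tally: LevelTally, significant: bool) -> LevelTally:
    """Record one trial at ``tally``'s level and reclassify (in place)."""
    if tally.classification != "pending":
        raise InvalidStateError(
            f"level {tally.level_pct}% already classified {tally.classification}"
        )
    if significant:
        tally.n_significant += 1
    else:
        tally.n_nonsignificant += 1
    if tally.n_significant >= 5:
        tally.classification = "positive"
    elif tally.n_nonsignificant >= 6:
        tally.classification = "negative"
    return tally


@dataclass
class ConventionalState:
    """State machine for the conventional criterion on one electrode.

    Walks the grid level by level (down after a positive level, up after a
    negative one); each level is classified at most once and cached. The MT
    is the positive level of the first adjacent positive/negative pair; a
    positive grid floor resolves at the floor; a negative grid ceiling is
    nonresponsive.
    """

    grid: IntensityGrid = field(default_factory=IntensityGrid)
    start_pct: float = 50.0
    status: str = "running"
    mt_pct: Optional[float] = None
    tallies: dict = field(default_factory=dict)  # level -> LevelTally
    _current: Optional[float] = None
    n_stimuli: int = 0

    def __post_init__(self) -> None:
        self.grid.require(self.start_pct)
        self._current = self.start_pct

    def next_intensity(self) -> float:
        if self.status != "running":
            raise InvalidStateError(f"estimator already {self.status}")
        return self._current

    def observe(self, intensity_pct: float, significant: bool) -> None:
        if self.status != "running":
            raise InvalidStateError(f"estimator already {self.status}")
        self.grid.require(intensity_pct)
        self.n_stimuli += 1
        tally = self.tallies.setdefault(intensity_pct, LevelTally(intensity_pct))
        conv_update_level(tally, significant)
        if tally.classification != "pending":
            self._advance(intensity_pct)

    def _classification(self, level: float) -> Optional[str]:
        t = self.tallies.get(level)
        if t is None or t.classification == "pending":
            return None
        return t.classification

    def _advance(self, level: float) -> None:
        # Walk from the just-classified level, consulting cached
        # classifications so a level is never re-tested.
        step = self.grid.step_pct
        while True:
            cls = self._classification(level)
            if cls == "positive":
                below = level - step
                if below < self.grid.min_pct - 1e-9:
                    self.status, self.mt_pct = "resolved", level
                    return
                below_cls = self._classification(below)
                if below_cls == "negative":
                    self.status, self.mt_pct = "resolved", level
                    return
                if below_cls is None:
                    self._current = below
                    return
                level = below  # cached positive: keep walking down
            else:  # negative
                above = level + step
                if above > self.grid.max_pct + 1e-9:
                    self.status = "nonresponsive"
                    return
                above_cls = self._classification(above)
                if above_cls == "positive":
                    self.status, self.mt_pct = "resolved", above
                    return
                if above_cls is None:
                    self._current = above
                    return
                level = above  # cached negative: keep walking up


def conv_estimate_mt(
    responder: Callable[[float], bool],
    start: float = 50.0,
    grid: Optional[IntensityGrid] = None,
    electrode_id: int = 0,
    max_stimuli: int = 10_000,
) -> MTEstimate:
    """Run the conventional 5-of-10 walk against a responder callable."""
    grid = grid or IntensityGrid()
    st = ConventionalState(grid=grid, start_pct=start)
    while st.status == "running":
        if st.n_stimuli >= max_stimuli:
            raise RuntimeError("level walk failed to terminate")
        intensity = st.next_intensity()
        st.observe(intensity, responder(intensity))
    return MTEstimate(electrode_id, st.mt_pct, st.n_stimuli, "conventional", grid.mso_ma)
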