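"""Simulated subjects: threshold landscapes and stochastic MEP responses.

A :class:`VirtualSubject` stands in for the anesthetized animal plus
recording hardware. Each of the 32 electrodes of an 8×4 epidural surface
array (700-μm pitch) carries a true recruitment threshold θ in % MSO drawn
from a spatially structured field,

    θ(x, y) = θ_hot + g · ‖(x, y) − hotspot‖ + jitter,

a low-threshold hotspot with thresholds rising radially away from it.
Responses follow a cumulative-Gaussian recruitment curve: a stimulus at
intensity I evokes a significant MEP with probability Φ((I − θ)/s), where
the spread s sets trial-to-trial variability (s = 0 gives a deterministic
step responder). Electrodes whose θ exceeds the grid ceiling by more than
half a step can never be resolved and are truly nonresponsive.

The module also fabricates intracortical-microstimulation (ICMS) style
point maps on a 0.5-mm lattice from the same underlying field, for
cross-modality comparison of surface-stimulation maps against the ICMS
reference modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.special import ndtr

from .mt_core import IntensityGrid

__all__ = [
    "ArrayGeometry",
    "GeneratorParams",
    "VirtualSubject",
    "ICMSMap",
    "make_subject",
    "make_icms_map",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Rectangular surface-electrode array; coordinates in mm."""

    n_cols: int = 8
    n_rows: int = 4
    pitch_mm: float = 0.7

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1 or self.pitch_mm <= 0:
            raise ValueError("array needs positive pitch and at least one electrode")

    @property
    def n_electrodes(self) -> int:
        return self.n_cols * self.n_rows

    def positions(self) -> np.ndarray:
        """(n_electrodes, 2) x/y positions, row-major (electrode 0 at origin)."""
        cols = np.arange(self.n_cols) * self.pitch_mm
        rows = np.arange(self.n_rows) * self.pitch_mm
        xx, yy = np.meshgrid(cols, rows)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def extent_mm(self) -> Tuple[float, float]:
        return ((self.n_cols - 1) * self.pitch_mm, (self.n_rows - 1) * self.pitch_mm)


@dataclass(frozen=True)
class GeneratorParams:
    """Threshold-field generator parameters.

    theta_hot_range : hotspot threshold drawn Uniform over this range, % MSO.
    gradient_pct_per_mm : radial rise of θ away from the hotspot.
    jitter_sd_pct : per-electrode Gaussian jitter, % MSO.
    spread_pct : recruitment-curve spread s, % MSO (0 ⇒ deterministic).
    predetermined_amplitude_uv : MEP significance amplitude, μV.
    """

    theta_hot_range: Tuple[float, float] = (30.0, 45.0)
    gradient_pct_per_mm: float = 14.0
    jitter_sd_pct: float = 3.0
    spread_pct: float = 2.5
    predetermined_amplitude_uv: float = 50.0

    def __post_init__(self) -> None:
        lo, hi = self.theta_hot_range
        if lo <= 0 or hi < lo:
            raise ValueError("theta_hot_range must be positive and ordered")
        if self.spread_pct < 0 or self.jitter_sd_pct < 0:
            raise ValueError("spread and jitter must be nonnegative")
        if self.predetermined_amplitude_uv <= 0:
            raise ValueError("predetermined amplitude must be positive")


@dataclass
class VirtualSubject:
    """Per-electrode true thresholds plus the smooth field they came from."""

    geometry: ArrayGeometry
    thetas_pct: np.ndarray  # (n_electrodes,) true thresholds, % MSO
    hotspot_xy: Tuple[float, float]
    theta_hot: float
    gradient_pct_per_mm: float
    spread_pct: float
    predetermined_amplitude_uv: float
    seed: int
    grid: IntensityGrid = field(default_factory=IntensityGrid)

    @property
    def n_electrodes(self) -> int:
        return self.geometry.n_electrodes

    def truly_nonresponsive(self) -> np.ndarray:
        """Electrodes whose θ exceeds the resolvable range (θ > max + step/2)."""
        return self.thetas_pct > self.grid.max_pct - self.grid.step_pct / 2.0

    def field_pct(self, x, y) -> np.ndarray:
        """Smooth (jitter-free) threshold field in % MSO at arbitrary (x, y) mm."""
        hx, hy = self.hotspot_xy
        d = np.hypot(np.asarray(x, float) - hx, np.asarray(y, float) - hy)
        return self.theta_hot + self.gradient_pct_per_mm * d

    def response_probability(self, electrode: int, intensity_pct: float) -> float:
        theta = self.thetas_pct[electrode]
        if self.truly_nonresponsive()[electrode]:
            return 0.0
        if self.spread_pct == 0.0:
            return 1.0 if intensity_pct >= theta else 0.0
        return float(ndtr((intensity_pct - theta) / self.spread_pct))

    def respond(
        self, electrode: int, intensity_pct: float, rng: np.random.Generator
    ) -> Tuple[float, bool]:
        """One stimulus → (MEP amplitude μV, significant?).

        Significance is Bernoulli with the cumulative-Gaussian recruitment
        probability; the amplitude is drawn above the significance criterion
        for significant trials and below it otherwise (log realism only —
        the estimators consume the boolean).
        """
        self.grid.require(intensity_pct)
        p = self.response_probability(electrode, intensity_pct)
        significant = bool(rng.random() < p)
        a = self.predetermined_amplitude_uv
        if significant:
            amplitude = a * (1.0 + rng.exponential(1.0))
        else:
            amplitude = a * rng.uniform(0.0, 0.8)
        return amplitude, significant

    def with_spread(self, spread_pct: float) -> "VirtualSubject":
        return replace(self, spread_pct=spread_pct)


def make_subject(
    geometry: Optional[ArrayGeometry] = None,
    params: Optional[GeneratorParams] = None,
    seed: int = 0,
    grid: Optional[IntensityGrid] = None,
) -> VirtualSubject:
    """Draw one subject: hotspot uniformly within the central half of the
    array, thresholds from the radial field plus per-electrode jitter.
    """
    geometry = geometry or ArrayGeometry()
    params = params or GeneratorParams()
    grid = grid or IntensityGrid()
    rng = np.random.default_rng(seed)
    w, h = geometry.extent_mm
    # central half: middle 50% of each axis
    hx = rng.uniform(0.25 * w, 0.75 * w)
    hy = rng.uniform(0.25 * h, 0.75 * h)
    theta_hot = rng.uniform(*params.theta_hot_range)
    pos = geometry.positions()
    d = np.hypot(pos[:, 0] - hx, pos[:, 1] - hy)
    jitter = rng.normal(0.0, params.jitter_sd_pct, size=geometry.n_electrodes)
    thetas = theta_hot + params.gradient_pct_per_mm * d + jitter
    thetas = np.maximum(thetas, 1.0)  # thresholds are positive
    return VirtualSubject(
        geometry=geometry,
        thetas_pct=thetas,
        hotspot_xy=(hx, hy),
        theta_hot=theta_hot,
        gradient_pct_per_mm=params.gradient_pct_per_mm,
        spread_pct=params.spread_pct,
        predetermined_amplitude_uv=params.predetermined_amplitude_uv,
        seed=seed,
        grid=grid,
    )


@dataclass
class ICMSMap:
    """Point map of intracortical MT estimates on a square lattice.

    ``mt_ua`` is NaN at nonresponsive sites (no movement at the maximum
    tested current).
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    mt_ua: np.ndarray  # NaN = nonresponsive
    pitch_mm: float = 0.5
    max_current_ua: float = 60.0

    @property
    def responsive(self) -> np.ndarray:
        return ~np.isnan(self.mt_ua)

    @property
    def n_responsive(self) -> int:
        return int(self.responsive.sum())


def make_icms_map(
    subject: VirtualSubject,
    pitch_mm: float = 0.5,
    seed: int = 0,
    noise_sd_ua: float = 1.5,
    max_current_ua: float = 60.0,
    scale_ua_per_pct: float = 0.6,
    sites: Optional[np.ndarray] = None,
) -> ICMSMap:
    """Sample the subject's smooth threshold field on an ICMS lattice.

    The surface-stimulation field (% MSO) is rescaled monotonically to μA
    (default 100% MSO ↦ 60 μA) with additive Gaussian noise; sites above
    ``max_current_ua`` are nonresponsive. When ``sites`` is None the lattice
    is grown outward from the array until the responsive region is fully
    surrounded by a ring of nonresponsive sites.

    Pass explicit ``sites`` (an (n, 2) array, mm) to probe chosen
    coordinates, e.g. the surface electrode positions themselves.
    """
    if pitch_mm <= 0:
        raise ValueError("lattice pitch must be positive")
    rng = np.random.default_rng(seed)

    def sample(xy: np.ndarray) -> np.ndarray:
        mt = subject.field_pct(xy[:, 0], xy[:, 1]) * scale_ua_per_pct
        if noise_sd_ua > 0:
            mt = mt + rng.normal(0.0, noise_sd_ua, size=len(xy))
        return mt

    if sites is not None:
        sites = np.asarray(sites, float)
        mt = sample(sites)
        mt = np.where(mt > max_current_ua, np.nan, mt)
        return ICMSMap(sites[:, 0], sites[:, 1], mt, pitch_mm, max_current_ua)

    w, h = subject.geometry.extent_mm
    margin = 0.0
    for _ in range(200):
        xs = np.arange(-margin, w + margin + 1e-9, pitch_mm)
        ys = np.arange(-margin, h + margin + 1e-9, pitch_mm)
        xx, yy = np.meshgrid(xs, ys)
        xy = np.column_stack([xx.ravel(), yy.ravel()])
        mt = sample(xy)
        mt = np.where(mt > max_current_ua, np.nan, mt)
        boundary = (
            (xy[:, 0] <= xs[0] + 1e-9)
            | (xy[:, 0] >= xs[-1] - 1e-9)
            | (xy[:, 1] <= ys[0] + 1e-9)
            | (xy[:, 1] >= ys[-1] - 1e-9)
        )
        if np.all(np.isnan(mt[boundary])):
            return ICMSMap(xy[:, 0], xy[:, 1], mt, pitch_mm, max_current_ua)
        margin += pitch_mm
    raise RuntimeError("could not surround the responsive region with a nonresponsive ring")
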