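"""Map comparison and reliability statistics.

Implements the analyses used to validate a mapping procedure against a
reference: tied-rank Spearman correlation between motor maps with a
permutation null (significance when the observed coefficient exceeds the
99th percentile of 2,000 rank resamplings), intraclass correlation (ICC,
two-way absolute-agreement single-measure) of map summary parameters across
sessions, piecewise-linear interpolation of a motor map over the electrode
hull, rank correlation between an interpolated surface-stimulation map and
an ICMS point map evaluated at the ICMS-responsive coordinates, and
session-level omnibus tests (Friedman with Wilcoxon/Bonferroni post hoc).

Nonresponsive electrodes enter the rank vectors with the tied worst rank by
default (they are the "highest threshold" entries); ``exclude_nonresponsive``
drops electrodes that are nonresponsive in either map instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "ComparisonResult",
    "ICCResult",
    "InterpolatedMap",
    "SessionTestReport",
    "DegenerateMapError",
    "rank_with_ties",
    "spearman_permutation_test",
    "min_mt",
    "map_area",
    "icc",
    "interpolate_map",
    "css_icms_correlation",
    "session_tests",
    "friedman_test",
]

RESPONSIVE_THRESHOLD_MA = 0.95  # map area counts electrodes with MT ≤ 0.95 mA


class DegenerateMapError(ValueError):
    """A map has no usable variation (all nonresponsive or all tied)."""


def _as_values(map_or_values) -> np.ndarray:
    """Accept a MotorMap or a plain array; NaN marks nonresponsive."""
    if hasattr(map_or_values, "mt_pct_array"):
        return map_or_values.mt_pct_array()
    return np.asarray(map_or_values, float)


def rank_with_ties(values, nonresponsive_to_max: bool = True) -> np.ndarray:
    """Average ranks with ties; NaN (nonresponsive) entries share the tied
    maximum rank."""
    v = _as_values(values)
    if v.size < 2:
        raise ValueError("need at least two entries to rank")
    nr = np.isnan(v)
    if nr.all():
        raise DegenerateMapError("all entries are nonresponsive")
    if nr.any() and not nonresponsive_to_max:
        raise ValueError("NaN entries present; use nonresponsive_to_max or mask them")
    return stats.rankdata(np.where(nr, np.inf, v))


@dataclass
class ComparisonResult:
    """Permutation-tested Spearman correlation between two maps."""

    rho: float
    p_perm: float
    n_perm: int
    significant: bool
    null_percentile_99: float
    n_used: int
    n_excluded: int = 0


def _pearson_of_ranks(ra: np.ndarray, rb: np.ndarray) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        raise DegenerateMapError("constant ranks: correlation undefined")
    return float((ra * rb).sum() / denom)


def spearman_permutation_test(
    map_a,
    map_b,
    n_perm: int = 2000,
    seed: Union[int, Sequence[int], np.random.Generator] = 0,
    exclude_nonresponsive: bool = False,
) -> ComparisonResult:
    """Tied-rank Spearman rho with an empirical permutation null.

    The null is built by permuting one map's rank vector ``n_perm`` times;
    the observed rho is significant when it exceeds the 99th percentile of
    the null (one-sided, upper tail). The p-value uses the +1 convention,
    bounded below by 1/(n_perm + 1).
    """
    va, vb = _as_values(map_a), _as_values(map_b)
    if va.shape != vb.shape:
        raise ValueError("maps must share the electrode set")
    n_excluded = 0
    if exclude_nonresponsive:
        keep = ~(np.isnan(va) | np.isnan(vb))
        n_excluded = int((~keep).sum())
        va, vb = va[keep], vb[keep]
        if va.size < 3:
            raise DegenerateMapError("fewer than 3 shared responsive electrodes")
    ra, rb = rank_with_ties(va), rank_with_ties(vb)
    rho = _pearson_of_ranks(ra, rb)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = rng.permuted(np.tile(rb, (n_perm, 1)), axis=1)
    ra_c = ra - ra.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra_c**2).sum() * (pc**2).sum(axis=1))
    null = (pc @ ra_c) / denom
    p99 = float(np.quantile(null, 0.99))
    p = float((1 + np.sum(null >= rho)) / (n_perm + 1))
    return ComparisonResult(
        rho=rho,
        p_perm=p,
        n_perm=n_perm,
        significant=bool(rho > p99),
        null_percentile_99=p99,
        n_used=int(ra.size),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Map summary parameters
# ---------------------------------------------------------------------------

def min_mt(motor_map) -> float:
    """Minimum MT over responsive electrodes, in mA (cortical excitability)."""
    if hasattr(motor_map, "mt_ma_array"):
        v = motor_map.mt_ma_array()
    else:
        v = np.asarray(motor_map, float)
    if np.isnan(v).all():
        raise DegenerateMapError("all electrodes nonresponsive: minimum MT undefined")
    return float(np.nanmin(v))


def map_area(motor_map, threshold_ma: float = RESPONSIVE_THRESHOLD_MA) -> int:
    """Map size: number of electrodes with MT ≤ ``threshold_ma``."""
    if hasattr(motor_map, "mt_ma_array"):
        v = motor_map.mt_ma_array()
    else:
        v = np.asarray(motor_map, float)
    return int(np.sum(v[~np.isnan(v)] <= threshold_ma + 1e-12))


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    variant: str
    parameter: str
    n_subjects: int
    n_sessions: int


def icc(
    session_matrix: np.ndarray,
    parameter: str = "",
) -> ICCResult:
    """Two-way, absolute-agreement, single-measure ICC (McGraw–Wong A,1).

    ``session_matrix`` is (n_subjects, n_sessions); test–retest reliability
    of one map parameter (minimum MT or map area) across mapping sessions.
    """
    m = np.asarray(session_matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if np.isnan(m).any():
        raise ValueError("missing cells in the session matrix")
    n, k = m.shape
    if np.ptp(m) == 0:
        # constant matrix: agreement is exact but the coefficient (a
        # variance ratio) is undefined
        return ICCResult(float("nan"), "ICC(A,1) / ICC2", parameter, n, k)
    # two-way ANOVA mean squares (subjects x sessions, one observation/cell)
    gm = m.mean()
    msr = k * np.sum((m.mean(axis=1) - gm) ** 2) / (n - 1)
    msc = n * np.sum((m.mean(axis=0) - gm) ** 2) / (k - 1)
    sse = np.sum((m - gm) ** 2) - (n - 1) * msr - (k - 1) * msc
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    value = float("nan") if denom == 0 else float((msr - mse) / denom)
    return ICCResult(
        icc=value,
        variant="ICC(A,1) / ICC2",
        parameter=parameter,
        n_subjects=n,
        n_sessions=k,
    )


# ---------------------------------------------------------------------------
# Interpolated maps and cross-modality correlation
# ---------------------------------------------------------------------------

@dataclass
class InterpolatedMap:
    """Piecewise-linear MT surface over the convex hull of the responsive
    electrode positions; queries outside the hull return NaN."""

    _interp: LinearNDInterpolator
    positions: np.ndarray
    values: np.ndarray

    def __call__(self, x, y) -> np.ndarray:
        return self._interp(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))

    def inside_hull(self, x, y) -> np.ndarray:
        return ~np.isnan(self(x, y))


def interpolate_map(
    positions: np.ndarray,
    values: np.ndarray,
) -> InterpolatedMap:
    """Triangulation-based linear interpolation of MT over electrode
    positions (merged across array placements); exact at the inputs.
    Nonresponsive electrodes (NaN) are dropped before triangulating.
    """
    positions = np.asarray(positions, float)
    values = np.asarray(values, float)
    if positions.ndim != 2 or positions.shape[0] != values.shape[0]:
        raise ValueError("positions must be (n, 2) matching values")
    keep = ~np.isnan(values)
    positions, values = positions[keep], values[keep]
    if len(values) < 3:
        raise ValueError("need at least 3 responsive positions")
    try:
        interp = LinearNDInterpolator(positions, values)
    except QhullError as exc:
        raise ValueError("responsive positions are collinear") from exc
    if interp.tri.npoints < 3 or len(interp.tri.simplices) == 0:
        raise ValueError("responsive positions are collinear")
    return InterpolatedMap(interp, positions, values)


def css_icms_correlation(
    icms_map,
    css_surface: InterpolatedMap,
    n_perm: int = 2000,
    seed: Union[int, Sequence[int], np.random.Generator] = 0,
) -> ComparisonResult:
    """Spearman correlation between ICMS MT ranks and the ranks of the
    interpolated surface-map MT evaluated at the ICMS-responsive
    coordinates, with the same 2,000-permutation / 99th-percentile
    significance rule. ICMS sites outside the surface-map hull are excluded
    and counted.
    """
    resp = icms_map.responsive
    x, y, mt_icms = icms_map.x_mm[resp], icms_map.y_mm[resp], icms_map.mt_ua[resp]
    if mt_icms.size < 3:
        raise ValueError("need at least 3 responsive ICMS sites")
    mt_css = np.asarray(css_surface(x, y)).ravel()
    inside = ~np.isnan(mt_css)
    n_excluded = int((~inside).sum())
    mt_icms, mt_css = mt_icms[inside], mt_css[inside]
    if mt_icms.size < 3:
        raise ValueError("fewer than 3 responsive ICMS sites inside the map hull")
    result = spearman_permutation_test(mt_icms, mt_css, n_perm=n_perm, seed=seed)
    result.n_excluded = n_excluded
    return result


# ---------------------------------------------------------------------------
# Session-level omnibus tests
# ---------------------------------------------------------------------------

def friedman_test(data: np.ndarray) -> Tuple[float, float]:
    """Tie-corrected Friedman test over a complete (subjects × conditions)
    design; returns (chi-square, p). A fully tied design yields (0, 1).
    """
    m = np.asarray(data, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete (subjects x conditions) matrix")
    if np.isnan(m).any():
        raise ValueError("missing cells in the within-subject design")
    n, k = m.shape
    r = np.apply_along_axis(stats.rankdata, 1, m)
    col_sums = r.sum(axis=0)
    c = n * k * (k + 1) ** 2 / 4.0
    a = (r**2).sum()
    num = (k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    if a - c <= 1e-12:  # every row fully tied
        return 0.0, 1.0
    chi2 = num / (a - c)
    return float(chi2), float(stats.chi2.sf(chi2, k - 1))


@dataclass
class PairwiseTest:
    condition_a: int
    condition_b: int
    statistic: float
    p_raw: float
    significant: bool  # at the Bonferroni-corrected level


@dataclass
class SessionTestReport:
    friedman_chi2: float
    friedman_p: float
    alpha: float
    alpha_corrected: float
    pairwise: List[PairwiseTest] = field(default_factory=list)


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(a, b)
    return float(stat), float(p)


def session_tests(
    data: np.ndarray,
    alpha: float = 0.01,
    condition_labels: Optional[Sequence[str]] = None,
) -> SessionTestReport:
    """Friedman omnibus over conditions plus pairwise Wilcoxon signed-rank
    tests with Bonferroni correction at α (default 0.01)."""
    m = np.asarray(data, float)
    chi2, p = friedman_test(m)
    k = m.shape[1]
    pairs = list(itertools.combinations(range(k), 2))
    alpha_corr = alpha / len(pairs)
    pairwise = []
    for i, j in pairs:
        stat, p_raw = _wilcoxon(m[:, i], m[:, j])
        pairwise.append(PairwiseTest(i, j, stat, p_raw, bool(p_raw < alpha_corr)))
    return SessionTestReport(chi2, p, alpha, alpha_corr, pairwise)
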