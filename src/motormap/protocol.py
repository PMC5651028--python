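"""The four-session mapping protocol and its cohort-level analyses.

Each subject is mapped four times in fixed order on the same threshold
landscape: pre1 and pre2 (conventional criterion, 1-Hz slots) establish the
baseline test–retest reliability, the novel session (tracking criterion,
4-Hz slots, 2-s refractory) is the procedure under validation, and post
(conventional) checks that the faster stimulation did not alter the map.

Cohort analyses mirror the validation battery: per-subject permutation-
tested Spearman correlations for the pre1–pre2, pre1–novel and pre1–post
pairs; ICC of minimum MT and map area across subjects for each pair;
Friedman/Wilcoxon omnibus tests on mapping durations and on the
correlation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .io import Config
from .map_stats import (
    ComparisonResult,
    ICCResult,
    SessionTestReport,
    icc,
    map_area,
    min_mt,
    session_tests,
    spearman_permutation_test,
)
from .scheduler import MappingResult, run_mapping
from .virtual_subject import VirtualSubject, make_subject

__all__ = ["SESSIONS", "SESSION_PAIRS", "SubjectResult", "ProtocolResult", "run_protocol"]

SESSIONS = ("pre1", "pre2", "novel", "post")
SESSION_PAIRS = (("pre1", "pre2"), ("pre1", "novel"), ("pre1", "post"))

_SESSION_ALGORITHM = {
    "pre1": "conventional",
    "pre2": "conventional",
    "novel": "novel",
    "post": "conventional",
}


@dataclass
class SubjectResult:
    subject: VirtualSubject
    mappings: Dict[str, MappingResult]
    correlations: Dict[str, ComparisonResult]  # keyed "pre1-pre2", ...

    def durations_s(self) -> Dict[str, float]:
        return {s: self.mappings[s].duration_s for s in SESSIONS if s in self.mappings}

    def stimulus_counts(self) -> Dict[str, int]:
        return {s: self.mappings[s].n_stimuli for s in SESSIONS if s in self.mappings}


@dataclass
class ProtocolResult:
    subjects: List[SubjectResult]
    icc_table: Dict[str, ICCResult] = field(default_factory=dict)
    duration_tests: Optional[SessionTestReport] = None
    correlation_tests: Optional[SessionTestReport] = None

    def median_duration_s(self, session: str) -> float:
        return float(np.median([s.mappings[session].duration_s for s in self.subjects]))

    def median_stimulus_count(self, session: str) -> float:
        return float(np.median([s.mappings[session].n_stimuli for s in self.subjects]))

    def parameter_matrix(self, parameter: str, sessions: Sequence[str]) -> np.ndarray:
        """(n_subjects, len(sessions)) matrix of a map parameter."""
        fn = {"min_mt": min_mt, "map_area": map_area}[parameter]
        return np.array(
            [
                [fn(s.mappings[sess].motor_map) for sess in sessions]
                for s in self.subjects
            ],
            float,
        )


def run_protocol(
    n_subjects: int = 12,
    seeds: Optional[Sequence[int]] = None,
    config: Optional[Config] = None,
    n_perm: int = 2000,
    sessions: Sequence[str] = SESSIONS,
) -> ProtocolResult:
    """Run the full protocol on a simulated cohort.

    ``seeds`` gives one seed per subject (default 1..n_subjects); the
    subject's landscape, each session's stimulation randomness and the
    permutation tests all derive deterministically from it, so repeated
    calls with the same seeds give identical results.
    """
    config = config or Config()
    if seeds is None:
        seeds = list(range(1, n_subjects + 1))
    if len(seeds) != n_subjects:
        raise ValueError("need exactly one seed per subject")
    for s in sessions:
        if s not in SESSIONS:
            raise ValueError(f"unknown session {s!r}")

    subject_results: List[SubjectResult] = []
    for seed in seeds:
        subject = make_subject(
            geometry=config.geometry,
            params=config.generator,
            seed=seed,
            grid=config.grid,
        )
        mappings: Dict[str, MappingResult] = {}
        for idx, session in enumerate(SESSIONS):
            if session not in sessions:
                continue
            algorithm = _SESSION_ALGORITHM[session]
            sched = config.schedule(algorithm, seed=seed)
            rng = np.random.default_rng([int(seed), idx])
            mappings[session] = run_mapping(
                subject, algorithm, sched, session=session, rng=rng
            )
        correlations: Dict[str, ComparisonResult] = {}
        for k, (a, b) in enumerate(SESSION_PAIRS):
            if a in mappings and b in mappings:
                correlations[f"{a}-{b}"] = spearman_permutation_test(
                    mappings[a].motor_map,
                    mappings[b].motor_map,
                    n_perm=n_perm,
                    seed=np.random.default_rng([int(seed), 100 + k]),
                )
        subject_results.append(SubjectResult(subject, mappings, correlations))

    result = ProtocolResult(subjects=subject_results)

    # ICC of the two map parameters for each session pair, across subjects
    for a, b in SESSION_PAIRS:
        if not all(a in s.mappings and b in s.mappings for s in subject_results):
            continue
        for parameter in ("min_mt", "map_area"):
            matrix = result.parameter_matrix(parameter, (a, b))
            result.icc_table[f"{parameter}:{a}-{b}"] = icc(matrix, parameter=parameter)

    if all(len(s.mappings) == len(SESSIONS) for s in subject_results):
        durations = np.array(
            [[s.mappings[sess].duration_s for sess in SESSIONS] for s in subject_results]
        )
        result.duration_tests = session_tests(durations, alpha=config.alpha)
        rhos = np.array(
            [
                [s.correlations[f"{a}-{b}"].rho for a, b in SESSION_PAIRS]
                for s in subject_results
            ]
        )
        result.correlation_tests = session_tests(rhos, alpha=config.alpha)
    return result
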