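"""Evaluation statistics: optimality ratio, OSPA-T, identity switches.

The OSPA-T distance between a truth point set and an estimate point set at
one frame combines cut-off localization error with a cardinality penalty::

    d_p^(c) = ( (1/n) ( min over injections sum_i min(c, d_i)^p
                        + c^p * (n - m) ) )^(1/p)

with m <= n (arguments swapped otherwise), normalization by the larger
cardinality, and the inner minimization solved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .assignment import solve_exact
from .policy import PolicyModel, decode, normalize_input

__all__ = [
    "OSPAParams",
    "optimality_ratio",
    "ospa_t_frame",
    "ospa_t_average",
    "count_id_switches",
    "evaluate_solver",
    "SolverSummary",
]

TrackPositions = Mapping[int, Mapping[int, np.ndarray]]  # id -> frame -> (2,)


@dataclass(frozen=True)
class OSPAParams:
    cutoff: float = 1.0
    order: float = 1.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff c must be positive")
        if self.order < 1:
            raise ValueError("order p must be >= 1")


def optimality_ratio(predicted_weight: float, optimal_weight: float) -> float:
    """``predicted / optimal`` for a maximization task; always in [0, 1]."""
    if optimal_weight <= 0:
        raise ValueError("optimal weight must be positive")
    if predicted_weight > optimal_weight * (1 + 1e-9):
        raise RuntimeError(
            f"predicted weight {predicted_weight} exceeds the optimum "
            f"{optimal_weight}: optimality violated"
        )
    return min(predicted_weight / optimal_weight, 1.0)


def ospa_t_frame(
    truth: Sequence, estimate: Sequence, params: OSPAParams = OSPAParams()
) -> float:
    """Single-frame OSPA-T distance between two 2-D point sets."""
    t = np.asarray(truth, dtype=float).reshape(-1, 2) if len(truth) else np.empty((0, 2))
    e = np.asarray(estimate, dtype=float).reshape(-1, 2) if len(estimate) else np.empty((0, 2))
    m, n = len(t), len(e)
    if m == 0 and n == 0:
        return 0.0  # convention: empty-vs-empty frame contributes nothing
    if m > n:
        t, e, m, n = e, t, n, m
    c, p = params.cutoff, params.order
    loc = 0.0
    if m > 0:
        d = np.minimum(cdist(t, e), c)
        rows, cols = linear_sum_assignment(d**p)
        loc = float((d[rows, cols] ** p).sum())
    return float(((loc + c**p * (n - m)) / n) ** (1.0 / p))


def _frames_of(tracks: TrackPositions) -> set[int]:
    frames: set[int] = set()
    for per_frame in tracks.values():
        frames.update(per_frame.keys())
    return frames


def ospa_t_average(
    truth: TrackPositions, estimate: TrackPositions,
    params: OSPAParams = OSPAParams(),
) -> float:
    """Mean per-frame OSPA-T over the union of frames of both track sets."""
    frames = sorted(_frames_of(truth) | _frames_of(estimate))
    if not frames:
        raise ValueError("no frames to evaluate")
    t_frames = _frames_of(truth)
    e_frames = _frames_of(estimate)
    if t_frames and e_frames and not (t_frames & e_frames):
        raise ValueError("truth and estimate frame ranges are disjoint")
    values = []
    for f in frames:
        t_pts = [pos[f] for pos in truth.values() if f in pos]
        e_pts = [pos[f] for pos in estimate.values() if f in pos]
        values.append(ospa_t_frame(t_pts, e_pts, params))
    return float(np.mean(values))


def count_id_switches(
    truth: TrackPositions, estimate: TrackPositions, match_radius: float = 1.0
) -> int:
    """Identity switches: frames at which a truth target's one-to-one matched
    estimate id differs from its previous matched id.

    CLEAR-MOT-style matching: a previous frame's (truth, estimate) pair is
    kept while both exist and stay within ``match_radius``; only the
    remainder is re-matched by the exact solver on the distance matrix.
    Invariant under global relabeling of estimate ids.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    frames = sorted(_frames_of(truth) | _frames_of(estimate))
    last_match: dict[int, int] = {}
    switches = 0
    for f in frames:
        t_ids = [tid for tid, pos in truth.items() if f in pos]
        e_ids = [eid for eid, pos in estimate.items() if f in pos]
        if not t_ids or not e_ids:
            continue
        kept: dict[int, int] = {}
        for tid in t_ids:
            eid = last_match.get(tid)
            if eid is not None and eid in e_ids:
                dist = float(np.linalg.norm(truth[tid][f] - estimate[eid][f]))
                if dist <= match_radius:
                    kept[tid] = eid
        free_t = [tid for tid in t_ids if tid not in kept]
        free_e = [eid for eid in e_ids if eid not in kept.values()]
        if free_t and free_e:
            d = cdist(
                np.array([truth[tid][f] for tid in free_t], dtype=float),
                np.array([estimate[eid][f] for eid in free_e], dtype=float),
            )
            rows, cols = linear_sum_assignment(np.minimum(d, 2 * match_radius))
            for i, j in zip(rows, cols):
                if d[i, j] <= match_radius:
                    kept[free_t[i]] = free_e[j]
        for tid, eid in kept.items():
            if tid in last_match and last_match[tid] != eid:
                switches += 1
            last_match[tid] = eid
    return switches


@dataclass(frozen=True)
class SolverSummary:
    median_ratio: float
    mean_ratio: float
    ratios: tuple[float, ...]


def evaluate_solver(
    instances: Sequence[np.ndarray],
    policy: PolicyModel | None = None,
    sense: str = "maximize",
) -> SolverSummary:
    """Greedy-decode each instance (or re-solve exactly) and score against
    the Hungarian optimum.  ``policy=None`` evaluates the exact solver
    against itself (all ratios 1), which is the oracle self-check.
    """
    from .assignment import CostMatrix, assignment_cost

    if len(instances) == 0:
        raise ValueError("no instances to evaluate")
    ratios = []
    if policy is not None:
        stacked = np.stack([
            normalize_input(inst, policy.normalization) for inst in instances
        ])
        scores = policy.forward(stacked, train=False)
    for k, inst in enumerate(instances):
        optimal = solve_exact(CostMatrix(inst, sense=sense))
        if policy is None:
            achieved = optimal.total_cost
        else:
            perm = decode(scores[k], mode="greedy",
                          temperature=policy.temperature).permutation
            achieved = assignment_cost(inst, perm)
        if sense == "maximize":
            ratios.append(optimality_ratio(achieved, optimal.total_cost))
        else:
            # minimization analogue: optimal / achieved, also in [0, 1]
            ratios.append(
                1.0 if achieved == 0 else
                min(optimal.total_cost / achieved, 1.0)
            )
    arr = np.asarray(ratios)
    return SolverSummary(
        median_ratio=float(np.median(arr)),
        mean_ratio=float(arr.mean()),
        ratios=tuple(float(r) for r in arr),
    )
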