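"""Cost matrices, exact assignment solvers, and the event-aware augmented matrix.

The augmented matrix embeds track lifecycle events into a single square
linear assignment problem: an ``(M+N) x (M+N)`` matrix whose top-left block
holds prediction-measurement distances, whose dummy diagonal blocks price a
prediction going *lost* or a measurement starting a *new* track at a fixed
threshold cost, and whose bottom-right block mirrors the distance block.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import factorial
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "CostMatrix",
    "AugmentedCostMatrix",
    "Assignment",
    "AssociationOutcome",
    "build_augmented_matrix",
    "augment_distance_matrix",
    "solve_exact",
    "solve_brute_force",
    "assignment_cost",
    "classify_outcome",
    "save_matrix",
    "load_matrix",
]

Sense = Literal["minimize", "maximize"]

BRUTE_FORCE_MAX_N = 9


@dataclass(frozen=True)
class CostMatrix:
    """A square cost (or weight) matrix with an optimization sense."""

    values: np.ndarray
    sense: Sense = "minimize"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"cost matrix must be square, got shape {values.shape}")
        if values.size == 0:
            raise ValueError("cost matrix must be non-empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("cost matrix entries must be finite")
        if self.sense not in ("minimize", "maximize"):
            raise ValueError(f"unknown sense {self.sense!r}")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AugmentedCostMatrix:
    """The event-aware ``(M+N) x (M+N)`` association matrix.

    Block layout (M predictions, N measurements)::

        [ L (MxN)   U (MxM) ]      L: prediction-measurement distances
        [ G (NxN)   L^T     ]      U, G: threshold on the diagonal,
                                         ``big_value`` elsewhere

    Row ``i < M`` is prediction ``i``; row ``M + j`` is the dummy row of
    measurement ``j``.  Column ``j < N`` is measurement ``j``; column
    ``N + i`` is the dummy ("lost") column of prediction ``i``.
    """

    values: np.ndarray
    m_predictions: int
    n_measurements: int
    threshold: float
    big_value: float
    sense: Sense = field(default="minimize")

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        size = self.m_predictions + self.n_measurements
        if values.shape != (size, size):
            raise ValueError(
                f"augmented matrix must be {size}x{size}, got {values.shape}"
            )
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def distance_block(self) -> np.ndarray:
        return self.values[: self.m_predictions, : self.n_measurements]


@dataclass(frozen=True)
class Assignment:
    """A one-to-one row-to-column assignment and its total cost."""

    permutation: tuple[int, ...]
    total_cost: float

    def __post_init__(self) -> None:
        n = len(self.permutation)
        if sorted(self.permutation) != list(range(n)):
            raise ValueError(f"not a permutation of 0..{n - 1}: {self.permutation}")


@dataclass(frozen=True)
class AssociationOutcome:
    """Partition of predictions and measurements into matched / lost / new."""

    matched_pairs: tuple[tuple[int, int], ...]
    lost_predictions: tuple[int, ...]
    new_measurements: tuple[int, ...]
    infeasible: bool = False


def _check_points(points: Sequence, name: str) -> np.ndarray:
    arr = np.asarray(points, dtype=float).reshape(-1, 2) if len(points) else np.empty((0, 2))
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite coordinates in {name}")
    return arr


def augment_distance_matrix(
    distances: np.ndarray, threshold: float, big_value: float | None = None
) -> AugmentedCostMatrix:
    """Assemble the augmented matrix from a precomputed ``M x N`` distance block.

    Used directly when distances are Mahalanobis rather than Euclidean.
    """
    lam = np.asarray(distances, dtype=float)
    if lam.ndim != 2:
        raise ValueError("distance block must be 2-D")
    m, n = lam.shape
    if m + n == 0:
        raise ValueError("at least one prediction or measurement required")
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite distances")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    lam_max = float(lam.max()) if lam.size else 0.0
    if big_value is None:
        big_value = 10.0 * max(threshold, lam_max, 1.0)
    if big_value <= threshold:
        raise ValueError("big_value must exceed threshold")

    size = m + n
    values = np.full((size, size), big_value, dtype=float)
    values[:m, :n] = lam
    values[:m, n:] = big_value
    values[np.arange(m), n + np.arange(m)] = threshold  # lost diagonal
    values[m:, :n] = big_value
    values[m + np.arange(n), np.arange(n)] = threshold  # new diagonal
    values[m:, n:] = lam.T
    return AugmentedCostMatrix(
        values=values,
        m_predictions=m,
        n_measurements=n,
        threshold=float(threshold),
        big_value=float(big_value),
    )


def build_augmented_matrix(
    predicted_positions: Sequence,
    measured_positions: Sequence,
    threshold: float,
    big_value: float | None = None,
) -> AugmentedCostMatrix:
    """Build the augmented matrix from 2-D points using Euclidean distances."""
    preds = _check_points(predicted_positions, "predicted_positions")
    meas = _check_points(measured_positions, "measured_positions")
    if len(preds) + len(meas) == 0:
        raise ValueError("at least one prediction or measurement required")
    if len(preds) and len(meas):
        lam = cdist(preds, meas)
    else:
        lam = np.empty((len(preds), len(meas)))
    return augment_distance_matrix(lam, threshold, big_value)


def _values_and_sense(matrix) -> tuple[np.ndarray, Sense]:
    if isinstance(matrix, (CostMatrix, AugmentedCostMatrix)):
        return matrix.values, matrix.sense
    values = np.asarray(matrix, dtype=float)
    return values, "minimize"


def _lexicographic_perturbation(values: np.ndarray, maximize: bool) -> np.ndarray:
    # Break cost ties toward the lexicographically smallest permutation by
    # adding a tiny column-index penalty whose magnitude decays by row.
    n = values.shape[0]
    spread = max(float(np.abs(values).max()), 1.0)
    eps = 1e-12 * spread
    row_scale = (0.5 ** np.arange(n))[:, None]
    cols = np.arange(n)[None, :]
    tilt = eps * row_scale * cols
    return values + tilt if not maximize else values - tilt


def solve_exact(matrix) -> Assignment:
    """Optimal assignment via the Hungarian algorithm (scipy LAP solver)."""
    values, sense = _values_and_sense(matrix)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {values.shape}")
    maximize = sense == "maximize"
    tilted = _lexicographic_perturbation(values, maximize)
    rows, cols = linear_sum_assignment(tilted, maximize=maximize)
    perm = tuple(int(c) for c in cols[np.argsort(rows)])
    total = float(values[np.arange(len(perm)), perm].sum())
    return Assignment(permutation=perm, total_cost=total)


def solve_brute_force(matrix) -> Assignment:
    """Exhaustive enumeration over all permutations; the test oracle.

    Iterates permutations in lexicographic order with strict improvement, so
    ties resolve to the lexicographically smallest permutation.
    """
    values, sense = _values_and_sense(matrix)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {values.shape}")
    n = values.shape[0]
    if n > BRUTE_FORCE_MAX_N:
        raise ValueError(
            f"brute force refused for n={n} ({factorial(n)} permutations); "
            f"limit is n={BRUTE_FORCE_MAX_N}"
        )
    better = (lambda a, b: a > b) if sense == "maximize" else (lambda a, b: a < b)
    best_perm: tuple[int, ...] | None = None
    best_cost = 0.0
    rows = np.arange(n)
    for perm in itertools.permutations(range(n)):
        cost = float(values[rows, perm].sum())
        if best_perm is None or better(cost, best_cost):
            best_perm, best_cost = perm, cost
    assert best_perm is not None
    return Assignment(permutation=best_perm, total_cost=best_cost)


def assignment_cost(matrix, permutation: Sequence[int]) -> float:
    """Total selected cost ``sum_i values[i, pi_i]`` of a permutation."""
    values, _ = _values_and_sense(matrix)
    perm = list(permutation)
    n = values.shape[0]
    if sorted(perm) != list(range(n)):
        raise ValueError(f"invalid permutation for a {n}x{n} matrix: {perm}")
    return float(values[np.arange(n), perm].sum())


def classify_outcome(
    matrix: AugmentedCostMatrix, assignment: Assignment
) -> AssociationOutcome:
    """Read lifecycle events off an assignment of the augmented matrix.

    Prediction row ``i`` sent to a measurement column is *matched*; sent to
    its own dummy column it is *lost*.  Measurement ``j`` whose dummy row
    claims column ``j`` is *new*.  Selections landing on ``big_value`` cells
    are flagged infeasible but still classified (off-diagonal dummy picks
    count as lost/new).
    """
    m, n = matrix.m_predictions, matrix.n_measurements
    perm = assignment.permutation
    if len(perm) != m + n:
        raise ValueError("assignment size does not match the augmented matrix")

    infeasible = False
    matched: list[tuple[int, int]] = []
    lost: list[int] = []
    for i in range(m):
        j = perm[i]
        if j < n:
            matched.append((i, j))
        else:
            lost.append(i)
            if j != n + i:
                infeasible = True

    claimed = {j for _, j in matched}
    new: list[int] = []
    for k in range(n):
        j = perm[m + k]
        if j < n:
            if j != k:
                infeasible = True
            if j not in claimed:
                new.append(j)
            else:
                infeasible = True
    # Any measurement not matched and not claimed by a dummy row means the
    # permutation routed it through a big_value cell somewhere.
    unaccounted = set(range(n)) - claimed - set(new)
    if unaccounted:
        infeasible = True
        new.extend(sorted(unaccounted))

    return AssociationOutcome(
        matched_pairs=tuple(matched),
        lost_predictions=tuple(lost),
        new_measurements=tuple(sorted(new)),
        infeasible=infeasible,
    )


def save_matrix(values: np.ndarray, path) -> None:
    """Write a matrix as comma-separated plain text, one row per line."""
    np.savetxt(path, np.atleast_2d(np.asarray(values, dtype=float)), delimiter=",")


def load_matrix(path) -> np.ndarray:
    """Read a comma-separated matrix written by :func:`save_matrix`."""
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    return values
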