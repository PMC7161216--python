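"""Seeded generators for synthetic matching and tracking inputs.

Three generators cover everything the experiments need: bipartite matching
instances from random planar points, association instances between two
simulated frames, and a multi-target constant-velocity crossing scenario
with Gaussian measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .assignment import AugmentedCostMatrix, build_augmented_matrix

__all__ = [
    "MWMInstance",
    "TrackingScenario",
    "generate_mwm",
    "generate_association_instance",
    "generate_crossing_scenario",
]


@dataclass(frozen=True)
class MWMInstance:
    """A maximum-weight bipartite matching instance on planar points.

    ``weights[i, j]`` is the Euclidean distance between left vertex ``i``
    and right vertex ``j``; all points live in the unit square.
    """

    left: np.ndarray    # (n, 2)
    right: np.ndarray   # (n, 2)
    weights: np.ndarray  # (n, n)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class TrackingScenario:
    """Ground truth and noisy measurements for a crossing-targets run.

    ``truth`` has shape (n_targets, n_frames, 2); ``velocities`` is the
    per-target constant velocity (n_targets, 2); ``measurements`` mirrors
    ``truth`` with additive Gaussian noise of covariance ``noise_cov``.
    Measurement rows are NOT labeled for the tracker — the target axis is
    kept only for scoring.
    """

    truth: np.ndarray
    velocities: np.ndarray
    measurements: np.ndarray
    noise_cov: np.ndarray

    @property
    def n_targets(self) -> int:
        return self.truth.shape[0]

    @property
    def n_frames(self) -> int:
        return self.truth.shape[1]

    def detections_by_frame(self) -> list[np.ndarray]:
        """Per-frame unlabeled detection arrays (one per target, no clutter)."""
        return [self.measurements[:, t, :] for t in range(self.n_frames)]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_mwm(n: int, seed) -> MWMInstance:
    """Sample ``2n`` uniform points on the unit square; weights = distances."""
    if n < 1:
        raise ValueError(f"instance size must be >= 1, got {n}")
    rng = _as_rng(seed)
    points = rng.uniform(0.0, 1.0, size=(2 * n, 2))
    left, right = points[:n], points[n:]
    return MWMInstance(left=left, right=right, weights=cdist(left, right))


def generate_association_instance(
    m: int, n: int, threshold: float, seed, big_value: float | None = None
) -> AugmentedCostMatrix:
    """Random two-frame association instance on the unit square."""
    if m + n < 1:
        raise ValueError("need at least one prediction or measurement")
    rng = _as_rng(seed)
    preds = rng.uniform(0.0, 1.0, size=(m, 2))
    meas = rng.uniform(0.0, 1.0, size=(n, 2))
    return build_augmented_matrix(preds, meas, threshold, big_value)


def generate_crossing_scenario(
    n_targets: int = 5,
    n_frames: int = 40,
    noise_cov: np.ndarray | float = 0.01,
    seed=0,
    radius: float = 1.0,
    crossing_spread: float = 0.3,
) -> TrackingScenario:
    """Targets on a circle move at constant velocity through the center.

    Each target starts on a circle of ``radius`` and travels in a straight
    line to (approximately) the antipodal point, passing near the origin at
    the mid-frame.  Per-target offsets of scale ``crossing_spread`` keep the
    crossing tight but non-coincident, so identities are ambiguous without
    motion information.  Measurements are truth + N(0, noise_cov).
    """
    if n_targets < 2:
        raise ValueError("need at least 2 targets")
    if n_frames < 4:
        raise ValueError("need at least 4 frames")
    cov = np.asarray(noise_cov, dtype=float)
    if cov.ndim == 0:
        cov = float(cov) * np.eye(2)
    if cov.shape != (2, 2):
        raise ValueError("noise covariance must be scalar or 2x2")
    if not np.all(np.isfinite(cov)) or np.any(np.linalg.eigvalsh(cov) < -1e-12):
        raise ValueError("noise covariance must be finite and PSD")

    rng = _as_rng(seed)
    angles = 2 * np.pi * np.arange(n_targets) / n_targets
    starts = radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    # Small per-target crossing offsets: where each line passes at mid-frame.
    offsets = crossing_spread * radius * rng.uniform(-1.0, 1.0, size=(n_targets, 2))
    ends = -starts + 2.0 * offsets  # mid-point of start->end is offsets
    velocities = (ends - starts) / (n_frames - 1)

    frames = np.arange(n_frames)[None, :, None]
    truth = starts[:, None, :] + velocities[:, None, :] * frames

    noise = rng.multivariate_normal(
        np.zeros(2), cov, size=(n_targets, n_frames)
    ) if np.any(cov) else np.zeros_like(truth)
    return TrackingScenario(
        truth=truth,
        velocities=velocities,
        measurements=truth + noise,
        noise_cov=cov,
    )
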