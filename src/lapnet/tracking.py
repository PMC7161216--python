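"""Kalman-filter multi-target tracker with assignment-based association.

Per frame: predict every live track, build the event-aware augmented cost
matrix between predicted positions and detections, solve it (exact solver or
a trained policy), then update matched tracks, coast lost ones, spawn tracks
from new measurements, and terminate tracks lost for more than ``patience``
consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .assignment import (
    AssociationOutcome,
    augment_distance_matrix,
    classify_outcome,
    solve_exact,
)
from .policy import PolicyModel, decode, normalize_input
from .assignment import Assignment, assignment_cost

__all__ = [
    "KalmanModel",
    "TrackState",
    "Track",
    "Detection",
    "constant_velocity_model",
    "kalman_predict",
    "kalman_update",
    "associate_frame",
    "track_sequence",
]


@dataclass(frozen=True)
class KalmanModel:
    """Linear-Gaussian motion/measurement model ``x' = Ax + w``, ``z = Hx + v``."""

    transition: np.ndarray       # A
    process_noise: np.ndarray    # Q
    observation: np.ndarray      # H
    measurement_noise: np.ndarray  # R

    def __post_init__(self) -> None:
        a = np.asarray(self.transition, dtype=float)
        q = np.asarray(self.process_noise, dtype=float)
        h = np.asarray(self.observation, dtype=float)
        r = np.asarray(self.measurement_noise, dtype=float)
        d = a.shape[0]
        if a.shape != (d, d) or q.shape != (d, d):
            raise ValueError("A and Q must be square with matching dimension")
        if h.shape[1] != d or r.shape != (h.shape[0], h.shape[0]):
            raise ValueError("H/R dimensions inconsistent with the state")
        for mat, name in ((q, "Q"), (r, "R")):
            if not np.allclose(mat, mat.T, atol=1e-9):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(mat) < -1e-9):
                raise ValueError(f"{name} must be positive semi-definite")
        object.__setattr__(self, "transition", a)
        object.__setattr__(self, "process_noise", q)
        object.__setattr__(self, "observation", h)
        object.__setattr__(self, "measurement_noise", r)

    @property
    def state_dim(self) -> int:
        return self.transition.shape[0]


@dataclass(frozen=True)
class TrackState:
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("covariance shape does not match the state mean")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def position(self) -> np.ndarray:
        return self.mean[:2]


@dataclass
class Track:
    id: int
    history: list[tuple[int, TrackState]] = field(default_factory=list)
    status: Literal["tracked", "lost", "new"] = "new"
    consecutive_lost: int = 0

    @property
    def state(self) -> TrackState:
        return self.history[-1][1]

    def positions(self) -> dict[int, np.ndarray]:
        return {frame: st.position for frame, st in self.history}


@dataclass(frozen=True)
class Detection:
    frame: int
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ValueError("detection coordinates must be finite")
        object.__setattr__(self, "position", pos)


def constant_velocity_model(
    dt: float = 1.0, sigma_accel: float = 0.1, sigma_meas: float = 0.1
) -> KalmanModel:
    """Planar constant-velocity model with white-acceleration process noise.

    State is ``[x, y, vx, vy]``; only positions are measured.
    """
    a = np.array([
        [1, 0, dt, 0],
        [0, 1, 0, dt],
        [0, 0, 1, 0],
        [0, 0, 0, 1],
    ], dtype=float)
    # white-acceleration (discrete) noise for one axis
    q1 = sigma_accel**2 * np.array([
        [dt**4 / 4, dt**3 / 2],
        [dt**3 / 2, dt**2],
    ])
    q = np.zeros((4, 4))
    q[np.ix_([0, 2], [0, 2])] = q1
    q[np.ix_([1, 3], [1, 3])] = q1
    h = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
    r = sigma_meas**2 * np.eye(2)
    return KalmanModel(a, q, h, r)


def kalman_predict(model: KalmanModel, state: TrackState) -> TrackState:
    """Time update: propagate mean and covariance through the dynamics."""
    a, q = model.transition, model.process_noise
    if state.mean.size != model.state_dim:
        raise ValueError("state dimension does not match the model")
    return TrackState(mean=a @ state.mean, covariance=a @ state.covariance @ a.T + q)


def kalman_update(model: KalmanModel, state: TrackState, measurement) -> TrackState:
    """Measurement update with the standard (Joseph-free) innovation form."""
    z = measurement.position if isinstance(measurement, Detection) else np.asarray(
        measurement, dtype=float
    )
    h, r = model.observation, model.measurement_noise
    if state.mean.size != model.state_dim or z.size != h.shape[0]:
        raise ValueError("dimension mismatch in Kalman update")
    innovation = z - h @ state.mean
    s = h @ state.covariance @ h.T + r
    try:
        gain = np.linalg.solve(s, h @ state.covariance).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular innovation covariance S={s!r}"
        ) from exc
    mean = state.mean + gain @ innovation
    cov = state.covariance - gain @ h @ state.covariance
    cov = 0.5 * (cov + cov.T)
    return TrackState(mean=mean, covariance=cov)


def innovation_distances(
    model: KalmanModel, states: Sequence[TrackState], detections: Sequence[Detection]
) -> np.ndarray:
    """Mahalanobis distances under each track's innovation covariance."""
    h, r = model.observation, model.measurement_noise
    out = np.empty((len(states), len(detections)))
    for i, st in enumerate(states):
        s = h @ st.covariance @ h.T + r
        s_inv = np.linalg.inv(s)
        pred = h @ st.mean
        for j, det in enumerate(detections):
            nu = det.position - pred
            out[i, j] = float(np.sqrt(nu @ s_inv @ nu))
    return out


def _euclidean_distances(states, detections) -> np.ndarray:
    out = np.empty((len(states), len(detections)))
    for i, st in enumerate(states):
        for j, det in enumerate(detections):
            out[i, j] = float(np.linalg.norm(det.position - st.position))
    return out


def _solve_augmented(aug, policy: PolicyModel | None) -> Assignment:
    if policy is None:
        return solve_exact(aug)
    x = normalize_input(aug.values, policy.normalization)
    scores = policy.forward(x, train=False)
    dec = decode(scores, mode="greedy", temperature=policy.temperature)
    perm = dec.permutation
    return Assignment(permutation=perm, total_cost=assignment_cost(aug, perm))


def associate_frame(
    predicted_states: Sequence[TrackState],
    detections: Sequence[Detection],
    model: KalmanModel,
    threshold: float,
    solver: Literal["exact", "policy"] = "exact",
    distance: Literal["euclidean", "mahalanobis"] = "euclidean",
    policy: PolicyModel | None = None,
    big_value: float | None = None,
) -> tuple[AssociationOutcome, float]:
    """Associate one frame; returns the outcome and the assignment cost."""
    if len(predicted_states) == 0 and len(detections) == 0:
        return AssociationOutcome((), (), ()), 0.0
    if distance == "mahalanobis":
        lam = innovation_distances(model, predicted_states, detections)
    else:
        lam = _euclidean_distances(predicted_states, detections)
    aug = augment_distance_matrix(lam, threshold, big_value)
    if solver == "policy":
        if policy is None:
            raise ValueError("policy solver selected but no policy given")
        assignment = _solve_augmented(aug, policy)
    else:
        assignment = _solve_augmented(aug, None)
    return classify_outcome(aug, assignment), assignment.total_cost


def track_sequence(
    detections_by_frame: Sequence[Sequence[Detection]] | Sequence[np.ndarray],
    model: KalmanModel,
    threshold: float,
    solver: Literal["exact", "policy"] = "exact",
    distance: Literal["euclidean", "mahalanobis"] = "euclidean",
    policy: PolicyModel | None = None,
    patience: int = 2,
    initial_velocity_var: float = 1.0,
) -> list[Track]:
    """Run the tracker over consecutive frames of detections.

    ``detections_by_frame[t]`` holds the frame-``t`` detections either as
    :class:`Detection` objects or as an ``(n, 2)`` position array.  Lost
    tracks keep being predicted ("coasted") until terminated.
    """
    tracks: list[Track] = []
    finished: list[Track] = []
    next_id = 0
    meas_dim = model.observation.shape[0]

    def _spawn(frame: int, position: np.ndarray) -> Track:
        nonlocal next_id
        mean = np.zeros(model.state_dim)
        mean[:meas_dim] = position
        cov = np.diag(
            np.concatenate([
                np.diag(model.measurement_noise),
                np.full(model.state_dim - meas_dim, initial_velocity_var),
            ])
        )
        track = Track(id=next_id, history=[(frame, TrackState(mean, cov))],
                      status="new")
        next_id += 1
        return track

    for frame, raw in enumerate(detections_by_frame):
        dets = [
            d if isinstance(d, Detection) else Detection(frame, np.asarray(d, float))
            for d in raw
        ]
        if not tracks:
            tracks.extend(_spawn(frame, d.position) for d in dets)
            continue

        predicted = [kalman_predict(model, t.state) for t in tracks]
        outcome, _ = associate_frame(
            predicted, dets, model, threshold,
            solver=solver, distance=distance, policy=policy,
        )
        survivors: list[Track] = []
        for (i, j) in outcome.matched_pairs:
            track = tracks[i]
            track.history.append(
                (frame, kalman_update(model, predicted[i], dets[j]))
            )
            track.status = "tracked"
            track.consecutive_lost = 0
            survivors.append(track)
        for i in outcome.lost_predictions:
            track = tracks[i]
            track.consecutive_lost += 1
            track.status = "lost"
            if track.consecutive_lost > patience:
                finished.append(track)
            else:
                track.history.append((frame, predicted[i]))  # coast
                survivors.append(track)
        for j in outcome.new_measurements:
            survivors.append(_spawn(frame, dets[j].position))
        tracks = survivors

    return finished + tracks
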