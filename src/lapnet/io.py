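"""Plain-text round-tripping of detections, tracks, and run configs."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .tracking import Detection, Track

__all__ = [
    "read_detections",
    "write_detections",
    "write_tracks",
    "read_tracks",
    "write_config",
]

DETECTION_HEADER = ["frame", "x", "y"]
TRACK_HEADER = ["track_id", "frame", "x", "y", "status"]


class SchemaError(ValueError):
    pass


def _parse_header(line: str, expected: list[str], path) -> None:
    fields = [f.strip() for f in line.strip().split(",")]
    if fields != expected:
        raise SchemaError(
            f"{path}: expected header {','.join(expected)!r}, got {line.strip()!r}"
        )


def read_detections(path) -> dict[int, list[Detection]]:
    """Read `frame,x,y` CSV into detections grouped by frame index."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file (missing header)")
    _parse_header(lines[0], DETECTION_HEADER, path)
    grouped: dict[int, list[Detection]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise SchemaError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        try:
            frame = int(parts[0])
            x, y = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: non-numeric value ({exc})") from None
        grouped.setdefault(frame, []).append(Detection(frame, np.array([x, y])))
    return grouped


def write_detections(detections: Mapping[int, Sequence], path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(DETECTION_HEADER) + "\n")
        for frame in sorted(detections):
            for det in detections[frame]:
                pos = det.position if isinstance(det, Detection) else np.asarray(det)
                fh.write(f"{frame},{float(pos[0])!r},{float(pos[1])!r}\n")


def detections_to_frame_list(grouped: Mapping[int, Sequence[Detection]]):
    """Dense per-frame list from frame 0 to the max frame (empty frames allowed)."""
    if not grouped:
        return []
    last = max(grouped)
    return [grouped.get(f, []) for f in range(last + 1)]


def write_tracks(tracks: Sequence[Track], path) -> None:
    """Write `track_id,frame,x,y,status` rows, ordered by id then frame."""
    with open(path, "w") as fh:
        fh.write(",".join(TRACK_HEADER) + "\n")
        for track in sorted(tracks, key=lambda t: t.id):
            for frame, state in track.history:
                x, y = state.position
                fh.write(f"{track.id},{frame},{float(x)!r},{float(y)!r},{track.status}\n")


def read_tracks(path) -> dict[int, dict[int, np.ndarray]]:
    """Read a tracks CSV into id -> frame -> position (for metric input)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file (missing header)")
    _parse_header(lines[0], TRACK_HEADER, path)
    out: dict[int, dict[int, np.ndarray]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 5:
            raise SchemaError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            tid, frame = int(parts[0]), int(parts[1])
            pos = np.array([float(parts[2]), float(parts[3])])
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: non-numeric value ({exc})") from None
        out.setdefault(tid, {})[frame] = pos
    return out


def write_config(config: Mapping, path) -> None:
    """Write the resolved run configuration as flat `key: value` lines."""
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key}: {config[key]}\n")
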