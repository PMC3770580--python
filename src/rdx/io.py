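"""Trajectory and observable writers.

The XYZ dialect is the plain multi-frame format loadable by VMD: a particle
count line, a comment line carrying ``step=<n> time=<t>``, then one
``<typename> x y z`` line per particle. The written output is readable back
as input, so a final frame doubles as a restart file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .model import SystemState, TypeRegistry

__all__ = ["TrajectoryFrame", "write_xyz", "read_xyz", "frame_from_state",
           "state_from_frame", "write_csv_observable"]


@dataclass
class TrajectoryFrame:
    """One stored configuration: step, time and per-particle records."""

    step: int
    time: float
    ids: np.ndarray
    type_names: list
    positions: np.ndarray


def frame_from_state(state: SystemState) -> TrajectoryFrame:
    names = state.registry.names
    return TrajectoryFrame(
        step=state.step_index,
        time=state.time,
        ids=state.ids.copy(),
        type_names=[names[t] for t in state.type_indices],
        positions=state.positions.copy(),
    )


def state_from_frame(frame: TrajectoryFrame, registry: TypeRegistry,
                     box_origin, box_extent) -> SystemState:
    """Rebuild a state from a stored frame (fresh ids are assigned)."""
    state = SystemState.empty(registry, box_origin, box_extent)
    for name in sorted(set(frame.type_names)):
        sel = [k for k, t in enumerate(frame.type_names) if t == name]
        state.add_particles(name, frame.positions[sel])
    state.time = frame.time
    state.step_index = frame.step
    return state


def write_xyz(frames, path) -> None:
    """Write one or more frames (TrajectoryFrame or SystemState) as XYZ."""
    if isinstance(frames, (TrajectoryFrame, SystemState)):
        frames = [frames]
    with open(path, "w") as fh:
        for frame in frames:
            if isinstance(frame, SystemState):
                frame = frame_from_state(frame)
            fh.write(f"{len(frame.type_names)}\n")
            fh.write(f"step={frame.step} time={frame.time:.9g}\n")
            for name, pos in zip(frame.type_names, frame.positions):
                fh.write(f"{name} {pos[0]:.7f} {pos[1]:.7f} {pos[2]:.7f}\n")


_COMMENT_RE = re.compile(r"step=(\S+)\s+time=(\S+)")


def read_xyz(path) -> list[TrajectoryFrame]:
    """Read a multi-frame XYZ trajectory written by :func:`write_xyz`."""
    frames: list[TrajectoryFrame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: expected a particle count at line {k + 1}") from exc
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        m = _COMMENT_RE.search(comment)
        step = int(m.group(1)) if m else len(frames)
        time = float(m.group(2)) if m else 0.0
        names, positions = [], []
        for row in lines[k + 2: k + 2 + n]:
            parts = row.split()
            names.append(parts[0])
            positions.append([float(v) for v in parts[1:4]])
        if len(names) != n:
            raise ValueError(f"{path}: truncated frame starting at line {k + 1}")
        frames.append(TrajectoryFrame(
            step=step, time=time,
            ids=np.arange(n, dtype=np.int64),
            type_names=names,
            positions=np.asarray(positions, dtype=float).reshape(n, 3),
        ))
        k += 2 + n
    return frames


def write_csv_observable(df, path) -> None:
    """Write an observable table (anything with ``to_dataframe`` or a DataFrame)."""
    if hasattr(df, "to_dataframe"):
        df = df.to_dataframe()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
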