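"""Trajectory analysis: run/tumble segmentation and motility statistics."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class MotilitySummary:
    mean_speed: float = float("nan")  # um/s over run segments
    run_durations: list = field(default_factory=list)  # s
    tumble_durations: list = field(default_factory=list)  # s
    reorientation_angles: list = field(default_factory=list)  # degrees [0, 180]

    @property
    def mean_run_duration(self) -> float:
        return float(np.mean(self.run_durations)) if self.run_durations else float("nan")

    @property
    def mean_tumble_duration(self) -> float:
        return (
            float(np.mean(self.tumble_durations))
            if self.tumble_durations
            else float("nan")
        )

    @property
    def mean_reorientation(self) -> float:
        return (
            float(np.mean(self.reorientation_angles))
            if self.reorientation_angles
            else float("nan")
        )


def _segments(states: list[str]) -> list[tuple[str, int, int]]:
    """(state, start index, end index exclusive) for constant-state stretches."""
    out = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            out.append((states[start], start, i))
            start = i
    return out


def summarize_motility(
    positions: np.ndarray, states: list[str], dt: float
) -> MotilitySummary:
    """Compute motility statistics from a labeled trajectory.

    ``positions`` is (n, 2) in um sampled at fixed ``dt``; ``states[i]``
    labels the interval ending at sample i (run / tumble / nonmotile).
    Speed is the per-step displacement over run intervals; the
    reorientation angle is the angle between net-displacement headings
    of consecutive run segments.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) != len(states):
        raise ValueError("positions and states must align")
    segs = _segments(list(states))
    run_speeds = []
    summary = MotilitySummary()
    headings = []
    for state, start, end in segs:
        duration = (end - start) * dt
        if state == "run":
            summary.run_durations.append(duration)
            # intervals within the segment: displacement start-1 -> ...
            lo = max(start - 1, 0)
            steps = np.diff(positions[lo : end], axis=0)
            if len(steps):
                run_speeds.extend(np.linalg.norm(steps, axis=1) / dt)
                net = positions[end - 1] - positions[lo]
                if np.linalg.norm(net) > 0:
                    headings.append(math.atan2(net[1], net[0]))
                else:
                    headings.append(None)
            else:
                headings.append(None)
        elif state == "tumble":
            summary.tumble_durations.append(duration)
    previous = None
    for heading in headings:
        if heading is None:
            continue
        if previous is not None:
            delta = abs(heading - previous)
            delta = delta % (2 * math.pi)
            if delta > math.pi:
                delta = 2 * math.pi - delta
            summary.reorientation_angles.append(math.degrees(delta))
        previous = heading
    if run_speeds:
        summary.mean_speed = float(np.mean(run_speeds))
    else:
        warnings.warn("trajectory contains no run segments", stacklevel=2)
    return summary


def trajectory_from_records(
    records: list[dict], agent: str = "cell"
) -> tuple[np.ndarray, list[str], float]:
    """Extract (positions, states, dt) for one agent from emitted records."""
    loc_key = f"agents/{agent}/boundary/location"
    state_key = f"agents/{agent}/boundary/motile_state"
    rows = [r for r in records if loc_key in r]
    if len(rows) < 2:
        raise ValueError(f"no trajectory for agent {agent!r}")
    positions = np.array([r[loc_key] for r in rows])
    states = [r.get(state_key, "nonmotile") for r in rows]
    dt = rows[1]["time"] - rows[0]["time"]
    return positions, states, dt
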