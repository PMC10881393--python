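"""Behavioural time-series processing for tethered walking in closed-loop
visual virtual reality.

The ball tracker provides heading (via the bar position), forward and
sideward translation and turning velocity at 50 Hz.  The pipeline
reconstructs the fly's virtual 2D trajectory, masks standstill, isolates
straight-walking ("menotaxis") bouts with the Ramer-Douglas-Peucker
polyline simplification, and assigns each bout a goal angle: the circular
mean heading over the bout, excluding standstill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circ import boxcar_filter, circ_mean, heading_from_bar, wrap_angle

__all__ = [
    "BehaviorSeries",
    "Trajectory2D",
    "Bout",
    "standstill_mask",
    "reconstruct_trajectory",
    "rdp_simplify",
    "detect_bouts",
    "shift_latency",
]

#: Filtered forward velocity at or below this (mm/s) counts as standing still.
STANDSTILL_MM_S = 1.0


@dataclass
class BehaviorSeries:
    """50 Hz behavioural record.  ``heading`` is the inverse of ``bar``."""

    t: np.ndarray  # s
    heading: np.ndarray  # deg
    bar: np.ndarray  # deg
    fwd_vel: np.ndarray  # mm/s
    side_vel: np.ndarray  # mm/s
    turn_vel: np.ndarray  # deg/s

    @property
    def fs(self):
        return 1.0 / np.median(np.diff(self.t))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame):
        bar = df["bar_deg"].to_numpy(float) if "bar_deg" in df else -df["heading_deg"].to_numpy(float)
        heading = (df["heading_deg"].to_numpy(float) if "heading_deg" in df
                   else heading_from_bar(bar))
        return cls(t=df["t"].to_numpy(float), heading=wrap_angle(heading),
                   bar=wrap_angle(bar),
                   fwd_vel=df["fwd_mm_s"].to_numpy(float),
                   side_vel=df.get("side_mm_s", pd.Series(np.zeros(len(df)))).to_numpy(float),
                   turn_vel=df.get("turn_deg_s", pd.Series(np.zeros(len(df)))).to_numpy(float))

    def to_dataframe(self):
        return pd.DataFrame({"t": self.t, "heading_deg": self.heading,
                             "bar_deg": self.bar, "fwd_mm_s": self.fwd_vel,
                             "side_mm_s": self.side_vel, "turn_deg_s": self.turn_vel})


@dataclass
class Trajectory2D:
    x: np.ndarray  # mm
    y: np.ndarray  # mm


@dataclass
class Bout:
    """A straight-walking segment with its assigned goal angle."""

    start_idx: int
    end_idx: int  # inclusive
    displacement_L: float  # mm, straight-line distance between endpoints
    goal: float  # deg
    epsilon_used: float  # mm


def shift_latency(x, latency_s, fs):
    """Shift a series backward in time by a fixed acquisition latency
    (e.g. the 30 ms ball-tracker processing delay), padding the tail."""
    n = int(round(latency_s * fs))
    if n <= 0:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    return np.concatenate([x[n:], np.full(n, x[-1])])


def standstill_mask(fwd_vel, fs=50.0, prefiltered=False):
    """True where the 500-ms-boxcar-filtered forward velocity is <= 1 mm/s."""
    v = np.asarray(fwd_vel, dtype=float)
    if not prefiltered:
        v = boxcar_filter(v, width=0.5, fs=fs)
    return v <= STANDSTILL_MM_S


def reconstruct_trajectory(series: BehaviorSeries) -> Trajectory2D:
    """Integrate the virtual 2D path from heading and translational velocity.

    Heading 0 points along +y; positive headings rotate anticlockwise.
    Sideward velocity is taken positive toward the fly's right.
    """
    dt = np.diff(series.t, prepend=series.t[0] - (series.t[1] - series.t[0]))
    h = np.radians(series.heading)
    ux, uy = -np.sin(h), np.cos(h)  # forward unit vector
    rx, ry = np.cos(h), np.sin(h)  # rightward unit vector (forward rotated -90 deg)
    vx = series.fwd_vel * ux + series.side_vel * rx
    vy = series.fwd_vel * uy + series.side_vel * ry
    return Trajectory2D(x=np.cumsum(vx * dt), y=np.cumsum(vy * dt))


def _point_line_dist(px, py, ax, ay, bx, by):
    """Perpendicular distance from points to the line through A and B."""
    dx, dy = bx - ax, by - ay
    norm = np.hypot(dx, dy)
    if norm == 0:
        return np.hypot(px - ax, py - ay)
    return np.abs(dy * (px - ax) - dx * (py - ay)) / norm


def rdp_simplify(traj: Trajectory2D, epsilon: float):
    """Ramer-Douglas-Peucker polyline simplification; returns the sorted
    indices of retained points (endpoints always kept).

    Every original point lies within ``epsilon`` mm of the simplified
    polyline.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x, y = np.asarray(traj.x, float), np.asarray(traj.y, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two points")
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        seg = slice(i + 1, j)
        d = _point_line_dist(x[seg], y[seg], x[i], y[i], x[j], y[j])
        k = int(np.argmax(d))
        if d[k] > epsilon:
            k += i + 1
            keep[k] = True
            stack.append((i, k))
            stack.append((k, j))
    return np.flatnonzero(keep)


def detect_bouts(traj: Trajectory2D, heading, standstill=None,
                 epsilon=25.0, L_min=200.0, goal_mode="mean",
                 prejump_goal=None):
    """Segment the trajectory into menotaxis bouts.

    Bouts are the intervals between consecutive retained points of the
    RDP-simplified trajectory whose endpoint-to-endpoint displacement exceeds
    ``L_min`` mm (defaults: epsilon 25 mm, L 200 mm).  Each bout's goal is
    the circular mean heading over the bout with standstill samples excluded
    (``goal_mode="mean"``), or a caller-supplied pre-jump heading for virtual
    rotation experiments (``goal_mode="prejump"``).
    """
    heading = np.asarray(heading, dtype=float)
    if standstill is None:
        standstill = np.zeros(len(heading), dtype=bool)
    idx = rdp_simplify(traj, epsilon)
    bouts = []
    for a, b in zip(idx[:-1], idx[1:]):
        L = float(np.hypot(traj.x[b] - traj.x[a], traj.y[b] - traj.y[a]))
        if L <= L_min:
            continue
        if goal_mode == "prejump":
            if prejump_goal is None:
                raise ValueError("prejump goal_mode needs prejump_goal")
            goal = float(prejump_goal)
        else:
            seg = slice(a, b + 1)
            moving = heading[seg][~standstill[seg]]
            if moving.size == 0:
                warnings.warn("bout entirely standstill; dropped")
                continue
            goal, _ = circ_mean(moving)
        bouts.append(Bout(start_idx=int(a), end_idx=int(b), displacement_L=L,
                          goal=float(goal), epsilon_used=float(epsilon)))
    return bouts


def bouts_to_dataframe(bouts, fs=50.0):
    return pd.DataFrame({"start_s": [b.start_idx / fs for b in bouts],
                         "end_s": [b.end_idx / fs for b in bouts],
                         "L_mm": [b.displacement_L for b in bouts],
                         "goal_deg": [b.goal for b in bouts]})
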