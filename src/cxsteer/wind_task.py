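"""Metrics for the wind-induced angular-memory task.

Flies experience six blocks of three trials each; in every trial wind blows
for 30 s from a fixed allocentric direction, followed by a test period (30 s
starting 5 s after wind offset, skipping a 2-s open-loop 180-degree bar
jump).  A fly remembers the wind direction if its mean test-period heading
stays near the previously experienced allocentric wind direction.

The allocentric wind direction is always computed from the data (mean of
bar minus spigot during the wind-on window), never taken from the nominal
set point, because the spigot's mechanical latency can offset the two by up
to ~13 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circ import circ_dist, circ_mean, wrap_angle

__all__ = [
    "WindTrial",
    "WindBlockResult",
    "allocentric_wind_direction",
    "wind_direction_error",
    "performance_index",
    "summarize_blocks",
    "trials_from_table",
]

CORRECT_THRESHOLD_DEG = 30.0


@dataclass
class WindTrial:
    block: int  # 1..6
    trial_in_block: int  # 1..3
    wind_dir: float  # computed allocentric wind direction, deg
    heading_wind_on: np.ndarray  # deg, standstill already removed
    heading_test: np.ndarray  # deg, standstill already removed


@dataclass
class WindBlockResult:
    block: int
    wind_dir: float
    mean_heading_test: float  # over trials 2-3 test windows
    error_test: float  # deg in [0, 180]
    error_wind_on: float
    PI: float
    correct: bool


def allocentric_wind_direction(bar, spigot, wind_on=None):
    """Circular mean of (bar - spigot) over the wind-on window."""
    bar = np.asarray(bar, dtype=float)
    spigot = np.asarray(spigot, dtype=float)
    if wind_on is not None:
        m = np.asarray(wind_on, dtype=bool)
        bar, spigot = bar[m], spigot[m]
    if bar.size == 0:
        raise ValueError("empty wind-on window")
    mean, _ = circ_mean(circ_dist(bar, spigot))
    return float(mean)


def wind_direction_error(heading, wind_dir):
    """Absolute circular distance between the mean heading and the wind
    direction, in [0, 180] degrees; NaN for an empty (fully-standstill)
    window."""
    heading = np.asarray(heading, dtype=float)
    heading = heading[np.isfinite(heading)]
    if heading.size == 0:
        return float("nan")
    mean, _ = circ_mean(heading)
    return float(abs(circ_dist(mean, wind_dir)))


def performance_index(heading, wind_dir):
    """Fraction of time oriented within the 180-degree hemifield centred on
    the wind direction minus the fraction in the opposite hemifield."""
    heading = np.asarray(heading, dtype=float)
    heading = heading[np.isfinite(heading)]
    if heading.size == 0:
        return float("nan")
    toward = np.abs(circ_dist(heading, wind_dir)) < 90.0
    return float(toward.mean() - (~toward).mean())


def summarize_blocks(trials, correct_threshold=CORRECT_THRESHOLD_DEG):
    """Per-block and per-fly summary of one fly's trials.

    Per block the mean heading over the test periods of trials 2 and 3
    (concatenated; a single available trial is used alone) gives the
    wind-direction error, the performance index, and a correct flag
    (error strictly below 30 degrees).  Returns a dict with the block
    results, the mean test error, the correct count (0-6), and the
    per-trial-number learning curve (mean absolute distance to wind during
    the test window versus trial number).
    """
    by_block = {}
    for tr in trials:
        by_block.setdefault(tr.block, []).append(tr)
    results = []
    per_trial_dist = {}
    for block, trs in sorted(by_block.items()):
        trs = sorted(trs, key=lambda t: t.trial_in_block)
        wind = circ_mean([t.wind_dir for t in trs])[0]
        late = [t for t in trs if t.trial_in_block >= 2]
        heading_test = np.concatenate([t.heading_test for t in late]) if late else np.empty(0)
        heading_wind = np.concatenate([t.heading_wind_on for t in late]) if late else np.empty(0)
        heading_test = heading_test[np.isfinite(heading_test)]
        if heading_test.size == 0:
            raise ValueError(f"block {block}: no analysable test samples; fly excluded")
        mean_heading, _ = circ_mean(heading_test)
        err = wind_direction_error(heading_test, wind)
        results.append(WindBlockResult(
            block=block, wind_dir=float(wind),
            mean_heading_test=float(mean_heading),
            error_test=err,
            error_wind_on=wind_direction_error(heading_wind, wind),
            PI=performance_index(heading_test, wind),
            correct=bool(err < correct_threshold)))
        for t in trs:
            h = t.heading_test[np.isfinite(t.heading_test)]
            if h.size:
                per_trial_dist.setdefault(t.trial_in_block, []).append(
                    np.abs(circ_dist(h, wind)).mean())
    learning = {k: float(np.mean(v)) for k, v in sorted(per_trial_dist.items())}
    return {"blocks": results,
            "mean_error_test": float(np.mean([r.error_test for r in results])),
            "correct_count": int(sum(r.correct for r in results)),
            "learning_curve": learning}


def trials_from_table(df: pd.DataFrame, fs=50.0, test_delay_s=5.0,
                      test_dur_s=30.0, standstill=None):
    """Build :class:`WindTrial` objects from a tidy trial table.

    Expected columns: fly, block, trial, t, heading_deg, bar_deg,
    spigot_deg, wind_on (bool/int).  ``standstill`` may be a boolean column
    name in the table; standstill samples are removed from the heading
    series before any circular mean.
    """
    trials = []
    for (block, trial), g in df.groupby(["block", "trial"], sort=True):
        g = g.sort_values("t")
        wind_on = g["wind_on"].to_numpy(bool)
        heading = wrap_angle(g["heading_deg"].to_numpy(float))
        if standstill is not None and standstill in g:
            heading = np.where(g[standstill].to_numpy(bool), np.nan, heading)
        wind = allocentric_wind_direction(g["bar_deg"].to_numpy(float),
                                          g["spigot_deg"].to_numpy(float),
                                          wind_on)
        t = g["t"].to_numpy(float)
        t_off = t[wind_on][-1]
        test = (t > t_off + test_delay_s) & (t <= t_off + test_delay_s + test_dur_s)
        trials.append(WindTrial(block=int(block), trial_in_block=int(trial),
                                wind_dir=wind,
                                heading_wind_on=heading[wind_on],
                                heading_test=heading[test]))
    return trials
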