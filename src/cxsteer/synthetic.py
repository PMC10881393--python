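"""Synthetic-data generators.

Every analysis stage in the package is exercised against data produced
here: a closed-loop menotaxis agent whose turning follows the PFL3 model, a
von-Mises bump generator for columnar calcium signals, Poisson spike trains
from the single-cell model, LAL calcium traces, and a wind-task cohort.
Each generator is deterministic under a fixed seed and returns ground truth
alongside the observables, so the measurement pipeline can be validated by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorSeries
from .circ import wrap_angle
from .steering_model import (DEFAULT_FIT, Population, SingleCellFit,
                             build_population, column_angles, lal_sums,
                             pfl3_rate, silence_cells, turning_signal,
                             zero_heading)

__all__ = [
    "AgentConfig",
    "BumpConfig",
    "simulate_menotaxis_agent",
    "simulate_bump_series",
    "simulate_pfl3_spikes",
    "synthesize_vm_trace",
    "simulate_lal_series",
    "simulate_wind_cohort",
]


@dataclass
class AgentConfig:
    """Closed-loop menotaxis agent.

    The agent's turning velocity is the model's right-minus-left LAL signal
    times ``turn_gain`` plus Brownian heading noise; forward velocity grows
    when heading and goal align.  Bar jumps displace the closed-loop cue by
    +-90 degrees every 2 min with a 2 s open-loop hold.
    """

    fit: SingleCellFit = DEFAULT_FIT
    turn_gain: float = 1.0  # deg/s per Hz of R-L signal
    heading_noise: float = 30.0  # deg/sqrt(s) Brownian rotation
    fwd_base: float = 2.0  # mm/s
    fwd_gain: float = 8.0  # mm/s at perfect goal alignment
    goal_schedule: tuple = ((0.0, 0.0),)  # (start s, goal deg)
    bar_jump_every: float = 120.0  # s; 0 disables jumps
    open_loop_s: float = 2.0
    dt: float = 0.02  # 50 Hz
    seed: int = 0


def _goal_at(schedule, t):
    g = schedule[0][1]
    for start, goal in schedule:
        if t >= start:
            g = goal
    return g


def simulate_menotaxis_agent(cfg: AgentConfig, duration=300.0,
                             pop: Population = None):
    """Run the closed-loop agent; returns (BehaviorSeries, ground truth dict).

    The ground truth holds the goal series, the bar-jump onsets/signs, and
    the perceived heading (the inverse of the bar, which the model steers
    by).  The turning signal is evaluated at the perceived heading; during
    the open-loop hold after a jump the bar is frozen, so the perceived
    heading stays fixed while the fly turns.
    """
    if pop is None:
        pop = build_population(fit=cfg.fit)
    rng = np.random.default_rng(cfg.seed)
    n = int(round(duration / cfg.dt))
    t = np.arange(n) * cfg.dt
    H = np.empty(n)  # true (motor) heading
    bar = np.empty(n)
    goal = np.array([_goal_at(cfg.goal_schedule, ti) for ti in t])
    H[0] = _goal_at(cfg.goal_schedule, 0.0)
    bar_offset = 0.0
    frozen_bar = None
    open_until = -1.0
    jump_onsets, jump_signs = [], []
    next_jump = cfg.bar_jump_every if cfg.bar_jump_every > 0 else np.inf
    h = H[0]
    for i in range(n):
        if t[i] >= next_jump:
            sign = 90.0 if rng.random() < 0.5 else -90.0
            bar_offset = wrap_angle(bar_offset + sign)
            frozen_bar = wrap_angle(-h + bar_offset)
            open_until = t[i] + cfg.open_loop_s
            jump_onsets.append(i)
            jump_signs.append(sign)
            next_jump += cfg.bar_jump_every
        if t[i] < open_until:
            b = frozen_bar
        else:
            if frozen_bar is not None:
                # closed loop resumes from the bar's current position
                bar_offset = wrap_angle(frozen_bar + h)
                frozen_bar = None
            b = wrap_angle(-h + bar_offset)
        H[i] = h
        bar[i] = b
        h_perc = -b
        turn = cfg.turn_gain * turning_signal(h_perc, goal[i], pop)
        h = wrap_angle(h + turn * cfg.dt
                       + cfg.heading_noise * np.sqrt(cfg.dt) * rng.standard_normal())
    h_perc_series = wrap_angle(-bar)
    align = np.maximum(0.0, np.cos(np.radians(h_perc_series - goal)))
    fwd = cfg.fwd_base + cfg.fwd_gain * align
    turn_vel = np.gradient(np.unwrap(np.radians(H))) / cfg.dt
    series = BehaviorSeries(t=t, heading=h_perc_series, bar=bar,
                            fwd_vel=fwd, side_vel=np.zeros(n),
                            turn_vel=np.degrees(turn_vel))
    truth = {"goal": goal, "true_heading": H,
             "jump_onsets": np.array(jump_onsets, dtype=int),
             "jump_signs": np.array(jump_signs)}
    return series, truth


@dataclass
class BumpConfig:
    """Von-Mises activity bump over a columnar ROI array.

    ``kind="fb"`` makes a single bump whose position tracks the driver
    angle through the PVA convention; ``kind="pb"`` makes the bridge double
    bump (two bumps 8.5 glomeruli apart over 16 glomeruli).  The phase lags
    the driver by ``lag_s`` (the compass-signal latency, ~200 ms for a
    heading-driven bump; 0 for a goal-driven bump); amplitude optionally
    grows with forward velocity, and the signal is low-pass filtered by a
    first-order calcium kernel before noise is added.
    """

    n_roi: int = 16
    kind: str = "fb"
    kappa: float = 2.5
    baseline: float = 0.1
    amp: float = 1.0
    amp_fwd_coupling: bool = False
    fwd_halfsat: float = 2.0  # mm/s
    lag_s: float = 0.2
    noise_sd: float = 0.05
    calcium_tau: float = 0.3  # s
    seed: int = 0


def _calcium_kernel(x, tau, dt):
    if tau <= 0:
        return x
    alpha = dt / (tau + dt)
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, len(x)):
        y[i] = y[i - 1] + alpha * (x[i] - y[i - 1])
    return y


def simulate_bump_series(cfg: BumpConfig, driver, fwd_vel=None, fs=10.0):
    """ROI dF/F0 matrix (frames x n_roi) whose bump phase tracks ``driver``.

    Returns (dff matrix, ground-truth phase series).
    """
    rng = np.random.default_rng(cfg.seed)
    driver = wrap_angle(np.asarray(driver, dtype=float))
    lag = int(round(cfg.lag_s * fs))
    phase = np.concatenate([np.full(lag, driver[0]), driver[:-lag]]) if lag else driver
    n = len(phase)
    if cfg.amp_fwd_coupling and fwd_vel is not None:
        v = np.asarray(fwd_vel, dtype=float)
        amp = cfg.amp * (0.3 + 0.7 * v / (v + cfg.fwd_halfsat))
    else:
        amp = np.full(n, cfg.amp)
    if cfg.kind == "fb":
        ang = column_angles(cfg.n_roi)
        bump = np.exp(cfg.kappa * (np.cos(np.radians(phase[:, None] - ang[None, :])) - 1.0))
        v = cfg.baseline + amp[:, None] * bump
    elif cfg.kind == "pb":
        if cfg.n_roi != 16:
            raise ValueError("bridge bumps need 16 glomeruli")
        # bump position in glomerulus-index units; the period-8.5 decode of
        # a double bump at (i0, i0+8.5) advances 360 deg per 8.5 glomeruli
        i0 = -phase * 8.5 / 360.0
        idx = np.arange(16)
        def g(center):
            return np.exp(cfg.kappa * (np.cos(2 * np.pi * (idx[None, :] - center[:, None]) / 16.0) - 1.0))
        v = cfg.baseline + amp[:, None] * (g(i0) + g(i0 + 8.5))
    else:
        raise ValueError(f"unknown bump kind {cfg.kind!r}")
    dt = 1.0 / fs
    v = np.column_stack([_calcium_kernel(v[:, j], cfg.calcium_tau, dt)
                         for j in range(v.shape[1])])
    # ground truth = decoded phase of the noiseless filtered signal (the
    # calcium kernel is linear, so this is exact, and it keeps the truth
    # free of the indicator lag that is not the decoder's to undo)
    if cfg.kind == "fb":
        w = np.exp(1j * np.radians(column_angles(cfg.n_roi)))
    else:
        w = np.exp(-2j * np.pi * np.arange(16) / 8.5)
    truth = wrap_angle(np.degrees(np.angle(v @ w)))
    v = v + rng.normal(0.0, cfg.noise_sd, size=v.shape)
    return v, truth


def simulate_pfl3_spikes(fit: SingleCellFit, cell, H, G, dt=0.02, seed=None):
    """Inhomogeneous-Poisson spike counts per frame from the single-cell
    model evaluated along (H, G) series."""
    rng = np.random.default_rng(seed)
    rate = pfl3_rate(np.asarray(H, float), np.asarray(G, float), cell, fit)
    return rng.poisson(np.asarray(rate) * dt)


def synthesize_vm_trace(spike_times, duration, fs=10000.0, baseline=-55.0,
                        spike_amp=40.0, spike_sigma=0.0007, noise_sd=0.5,
                        seed=None):
    """Membrane-voltage trace with stereotyped spike waveforms injected at
    known times plus Gaussian noise, for exercising spike detection."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    vm = baseline + rng.normal(0.0, noise_sd, size=n)
    half = int(round(4 * spike_sigma * fs))
    tt = (np.arange(-half, half + 1)) / fs
    waveform = spike_amp * np.exp(-0.5 * (tt / spike_sigma) ** 2)
    for ts in np.asarray(spike_times, dtype=float):
        i = int(round(ts * fs))
        a, b = max(0, i - half), min(n, i + half + 1)
        vm[a:b] += waveform[half - (i - a):half + (b - i)]
    return vm


def simulate_lal_series(pop: Population, H, G, fs=10.0, calcium_tau=0.3,
                        noise_sd=0.02, scale=0.01, seed=None):
    """Left and right LAL dF/F0-like traces from the population model.

    LAL sums (Hz) are scaled to calcium-signal units, low-pass filtered by
    the calcium kernel and perturbed by Gaussian noise.  Returns
    (L, R, ground-truth R-L before filtering/noise).
    """
    rng = np.random.default_rng(seed)
    R, L = lal_sums(np.asarray(H, float), np.asarray(G, float), pop)
    truth = scale * (R - L)
    dt = 1.0 / fs
    Lc = _calcium_kernel(scale * L, calcium_tau, dt) + rng.normal(0, noise_sd, len(L))
    Rc = _calcium_kernel(scale * R, calcium_tau, dt) + rng.normal(0, noise_sd, len(R))
    return Lc, Rc, truth


def simulate_wind_cohort(n_flies, memory_noise=25.0, anemotaxis_noise=15.0,
                         phenotype="control", n_silenced=12, goal_noise=30.0,
                         seed=None, fs=10.0, pop: Population = None):
    """Wind-task trial tables for a synthetic cohort.

    Structure per fly: 6 wind-direction blocks x 3 trials; 30 s wind on,
    then a test window (30 s starting 5 s after wind off).  Phenotypes:

    - ``control``: heads upwind during wind (anemotaxis noise); in the test
      period heads toward a remembered direction drawn once per block as
      wind + N(0, memory_noise) -- the memory of the allocentric wind
      direction.
    - ``epg_silenced``: upwind during wind, but without a compass the
      remembered direction is uniform at random (one arbitrary held heading
      per block).
    - ``pfl3_partial``: steers via the zero heading of a population with
      ``n_silenced`` randomly silenced PFL3 cells, with wrapped-normal goal
      noise of sd ``goal_noise`` resampled per trial.

    Returns a tidy DataFrame (fly, block, trial, t, heading_deg, bar_deg,
    spigot_deg, wind_on, fwd_mm_s).
    """
    rng = np.random.default_rng(seed)
    if phenotype == "pfl3_partial" and pop is None:
        pop = build_population()
    dt = 1.0 / fs
    n_wind = int(round(30.0 * fs))
    n_gap = int(round(5.0 * fs))
    n_test = int(round(30.0 * fs))
    n_trial = n_wind + n_gap + n_test
    wind_dirs = wrap_angle(np.arange(6) * 60.0)
    rows = []
    for fly in range(n_flies):
        dirs = rng.permutation(wind_dirs)
        fly_pop = (silence_cells(pop, n_random=n_silenced,
                                 seed=int(rng.integers(2**31)))
                   if phenotype == "pfl3_partial" else None)
        for block, W in enumerate(dirs, start=1):
            if phenotype == "control":
                remembered = wrap_angle(W + rng.normal(0.0, memory_noise))
            elif phenotype == "epg_silenced":
                remembered = wrap_angle(rng.uniform(-180.0, 180.0))
            elif phenotype == "pfl3_partial":
                remembered = wrap_angle(W + rng.normal(0.0, memory_noise))
            else:
                raise ValueError(f"unknown phenotype {phenotype!r}")
            for trial in range(1, 4):
                t = np.arange(n_trial) * dt
                heading = np.empty(n_trial)
                heading[:n_wind] = W + rng.normal(0.0, anemotaxis_noise, n_wind)
                if phenotype == "pfl3_partial":
                    target = zero_heading(
                        wrap_angle(remembered + rng.normal(0.0, goal_noise)),
                        fly_pop)
                    if np.isnan(target):
                        target = rng.uniform(-180.0, 180.0)
                else:
                    target = remembered
                heading[n_wind:] = target + rng.normal(0.0, anemotaxis_noise,
                                                       n_gap + n_test)
                heading = wrap_angle(heading)
                bar = wrap_angle(-heading)
                spigot = wrap_angle(bar - W)
                wind_on = np.zeros(n_trial, dtype=bool)
                wind_on[:n_wind] = True
                rows.append(pd.DataFrame({
                    "fly": fly, "block": block, "trial": trial, "t": t,
                    "heading_deg": heading, "bar_deg": bar,
                    "spigot_deg": spigot, "wind_on": wind_on,
                    "fwd_mm_s": 5.0}))
    return pd.concat(rows, ignore_index=True)
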