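"""Fluorescence-derived quantities: dF/F0, bump phase and amplitude in the
fan-shaped body and protocerebral bridge, bump metrics, virtual-rotation
(bar-jump) trial analysis, goal-bump phase-jump detection, LAL transient and
goal-tuning analysis, and columnar-stimulation geometry.

Bump phase is decoded with a population vector average (PVA): the activity
vector over ROIs weighs unit vectors at the ROI angles; the argument of the
resultant is the phase and its length, normalized by the summed activity, is
the PVA amplitude in [0, 1].  The bridge compass phase instead uses a
single-frequency Fourier projection at the anatomical period of 8.5
glomeruli across the 16-glomerulus array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .circ import (boxcar_filter, circ_dist, circ_mean, gaussian_filter,
                   wrap_angle)

__all__ = [
    "PhaseSample",
    "JumpTrial",
    "TransientEvent",
    "dff",
    "pva_phase",
    "pva_series",
    "epg_phase_bridge",
    "phase_bar_offset",
    "bump_metrics",
    "analyze_bar_jumps",
    "detect_fc2_phase_jumps",
    "unwrap_phase",
    "lal_transients",
    "lal_goal_tuning",
    "stimulation_geometry",
    "align_to_events",
]


@dataclass
class PhaseSample:
    phase: float  # deg; NaN when the amplitude vanishes
    amplitude: float  # resultant length in [0, 1]


def dff(F, axis=0, frac=0.05):
    """dF/F0 with F0 the mean of the lowest 5% of each ROI's raw values."""
    F = np.asarray(F, dtype=float)
    n = F.shape[axis]
    k = max(1, int(np.ceil(frac * n)))
    lowest = np.sort(F, axis=axis).take(range(k), axis=axis)
    F0 = lowest.mean(axis=axis, keepdims=True)
    if np.any(F0 <= 0):
        raise ValueError("baseline F0 <= 0")
    return (F - F0) / F0


def pva_phase(v, roi_angles) -> PhaseSample:
    """Population-vector-average phase and amplitude of one activity vector.

    Negative entries are clipped to zero (phase decoding only; keep raw
    values for bump metrics).
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        warnings.warn("negative activity clipped to 0 for phase decoding")
        v = np.clip(v, 0.0, None)
    total = v.sum()
    if total == 0:
        return PhaseSample(phase=float("nan"), amplitude=0.0)
    z = (v * np.exp(1j * np.radians(np.asarray(roi_angles, float)))).sum()
    return PhaseSample(phase=wrap_angle(np.degrees(np.angle(z))),
                       amplitude=float(np.abs(z) / total))


def pva_series(dff_mat, roi_angles):
    """Frame-by-frame PVA decoding; returns (phase array, amplitude array)."""
    dff_mat = np.asarray(dff_mat, dtype=float)
    v = np.clip(dff_mat, 0.0, None)
    z = v @ np.exp(1j * np.radians(np.asarray(roi_angles, float)))
    total = v.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(total > 0, np.abs(z) / total, 0.0)
    phase = wrap_angle(np.degrees(np.angle(z)))
    phase = np.where(total > 0, phase, np.nan)
    return phase, amp


def epg_phase_bridge(v) -> PhaseSample:
    """Compass phase of a 16-glomerulus bridge vector.

    The phase is the argument of the Fourier component at the non-integer
    period of 8.5 glomeruli (the anatomical spacing of the double bump);
    this is a single-frequency projection, not an FFT bin, so a uniform
    vector leaks a small non-zero amplitude.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 16:
        raise ValueError("bridge vector must have 16 glomeruli")
    n = np.arange(16)
    z = (v * np.exp(-2j * np.pi * n / 8.5)).sum(axis=-1)
    total = np.abs(v).sum(axis=-1)
    if np.ndim(z) == 0:
        if total == 0:
            return PhaseSample(phase=float("nan"), amplitude=0.0)
        return PhaseSample(phase=wrap_angle(np.degrees(np.angle(z))),
                           amplitude=float(np.abs(z) / total))
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(total > 0, np.abs(z) / total, 0.0)
    phase = np.where(total > 0, wrap_angle(np.degrees(np.angle(z))), np.nan)
    return phase, amp


def phase_bar_offset(phase, bar, exclude=None):
    """Mean circular difference between bump phase and bar position.

    ``exclude`` marks samples to drop (standstill, bar in the rear gap,
    undefined phase).  Used to overlay the decoded phase on the bar.
    """
    phase = np.asarray(phase, dtype=float)
    bar = np.asarray(bar, dtype=float)
    keep = np.isfinite(phase) & np.isfinite(bar)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if not keep.any():
        raise ValueError("no retained samples for offset estimation")
    mean, _ = circ_mean(circ_dist(phase[keep], bar[keep]))
    return float(mean)


def bump_metrics(v):
    """Three scalar bump-strength metrics of one ROI vector: PVA amplitude
    (over equally spaced ROI angles), mean dF/F0, and max minus min."""
    v = np.asarray(v, dtype=float)
    n = len(v)
    angles = 360.0 * np.arange(n) / n
    pva = pva_phase(v, angles).amplitude
    return {"pva_amp": pva, "mean_dff": float(v.mean()),
            "max_minus_min": float(v.max() - v.min())}


@dataclass
class JumpTrial:
    onset_idx: int
    jump_sign: float  # +90 or -90
    pre_phase: float  # mean phase 1 s pre-jump (the zero reference)
    final_phase: float  # mean zeroed phase over the final 1 s of open loop
    in_bout: bool
    returned_within_30: bool
    bar_visible_target: bool
    pva_above_threshold: bool

    def passes(self, strict=True):
        base = self.bar_visible_target and self.pva_above_threshold
        if strict:
            base = base and self.in_bout and self.returned_within_30
        return base and np.isfinite(self.final_phase)


def analyze_bar_jumps(phase, bar, pva, onsets, jump_signs, bouts=None,
                      fs=10.0, open_loop_s=2.0, strict=True,
                      pva_threshold=0.3, gap_halfwidth=45.0):
    """Virtual-rotation trial analysis.

    For each bar-jump onset the bump phase is zeroed to its circular mean
    over the 1 s preceding the jump and scored as its mean over the final
    1 s of the open-loop window.  Trials must have the post-jump bar visible
    (outside the rear 90 deg gap) and PVA above 0.3 throughout the scoring
    window; strict mode additionally requires the jump to fall inside a
    menotaxis bout and the fly to return to its pre-jump heading (mean bar
    5-10 s post within 30 deg of the mean bar over 5 s pre).  The summary
    averages the scored phases with -90 deg trials sign-flipped, so a
    heading-tracking bump scores ~+90 and a goal-tracking bump ~0.

    Returns (list of JumpTrial, summary mean in degrees or NaN).
    """
    phase = np.asarray(phase, dtype=float)
    bar = np.asarray(bar, dtype=float)
    pva = np.asarray(pva, dtype=float)
    n1s = int(round(fs))
    n_open = int(round(open_loop_s * fs))
    trials = []
    for onset, sign in zip(onsets, jump_signs):
        onset = int(onset)
        pre = slice(max(0, onset - n1s), onset)
        score = slice(onset + n_open - n1s, onset + n_open)
        pre_phase, _ = circ_mean(phase[pre])
        zeroed = circ_dist(phase[score], pre_phase)
        final_phase, _ = circ_mean(zeroed) if np.isfinite(zeroed).any() else (float("nan"), 0)
        in_bout = bool(bouts) and any(b.start_idx <= onset <= b.end_idx for b in bouts or [])
        pre5 = slice(max(0, onset - 5 * n1s), onset)
        post = slice(onset + 5 * n1s, min(len(bar), onset + 10 * n1s))
        pre_bar, _ = circ_mean(bar[pre5])
        post_bar, _ = circ_mean(bar[post]) if post.stop > post.start else (float("nan"), 0)
        returned = bool(np.isfinite(post_bar) and abs(circ_dist(post_bar, pre_bar)) < 30.0)
        target_bar = bar[min(onset + 1, len(bar) - 1)]
        visible = abs(wrap_angle(target_bar)) < 180.0 - gap_halfwidth
        pva_ok = bool(np.all(pva[score] > pva_threshold))
        trials.append(JumpTrial(onset_idx=onset, jump_sign=float(sign),
                                pre_phase=float(pre_phase),
                                final_phase=float(final_phase),
                                in_bout=in_bout, returned_within_30=returned,
                                bar_visible_target=visible,
                                pva_above_threshold=pva_ok))
    scored = [t.final_phase if t.jump_sign > 0 else -t.final_phase
              for t in trials if t.passes(strict=strict)]
    if scored:
        summary, _ = circ_mean(scored)
    else:
        summary = float("nan")
    return trials, float(summary)


def unwrap_phase(phase):
    """Unwrap a wrapped phase series using shortest-arc differences."""
    phase = np.asarray(phase, dtype=float)
    steps = circ_dist(phase[1:], phase[:-1])
    return np.concatenate([[phase[0]], phase[0] + np.cumsum(steps)])


def detect_fc2_phase_jumps(phase, pva, fs=10.0, min_velocity=40.0,
                           pva_floor=0.15, pva_mean_min=0.25):
    """Detect rapid goal-bump relocations.

    Peaks of the 500-ms-boxcar-filtered absolute phase velocity above
    ``min_velocity`` deg/s qualify if the PVA stays above 0.15 at every
    sample within 1 s of the peak and averages above 0.25 there.  Returns
    (peak indices, signed peak velocities).
    """
    phase = unwrap_phase(phase)
    vel = np.gradient(phase) * fs
    vel_f = boxcar_filter(vel, width=0.5, fs=fs)
    peaks, _ = sp_signal.find_peaks(np.abs(vel_f), height=min_velocity)
    n1s = int(round(fs))
    pva = np.asarray(pva, dtype=float)
    kept, signed = [], []
    for p in peaks:
        win = pva[max(0, p - n1s):p + n1s + 1]
        if win.size and win.min() > pva_floor and win.mean() > pva_mean_min:
            kept.append(int(p))
            signed.append(float(vel_f[p]))
    return np.array(kept, dtype=int), np.array(signed)


@dataclass
class TransientEvent:
    peak_idx: int
    peak_time: float  # s
    polarity: str  # "R>L" or "L>R"


def _transient_peaks(x, fs, height, min_dur, min_space, prominence):
    peaks, _ = sp_signal.find_peaks(x, height=height,
                                    distance=max(1, int(round(min_space * fs))),
                                    prominence=prominence)
    # require the signal to stay above the height threshold for >= min_dur
    above = x > height
    n_dur = int(round(min_dur * fs))
    region = np.cumsum(np.concatenate([[0], np.diff(above.astype(int)) != 0]))
    good = []
    for p in peaks:
        if above[p] and (region == region[p]).sum() >= n_dur:
            good.append(int(p))
    return good


def lal_transients(r_minus_l, fs, sigma=0.2, height=0.1, min_dur=1.0,
                   min_space=3.0, prominence=1.0):
    """Transient left-right asymmetries of the LAL dF/F0 signal.

    The right-minus-left signal is Gaussian-smoothed (sigma 200 ms); peaks
    must exceed 0.1 dF/F0 for at least 1 s, be spaced by at least 3 s and
    have prominence 1.  Transient decreases are found on the negated signal.
    """
    x = gaussian_filter(np.asarray(r_minus_l, float), sigma=sigma, fs=fs)
    events = [TransientEvent(p, p / fs, "R>L")
              for p in _transient_peaks(x, fs, height, min_dur, min_space, prominence)]
    events += [TransientEvent(p, p / fs, "L>R")
               for p in _transient_peaks(-x, fs, height, min_dur, min_space, prominence)]
    return sorted(events, key=lambda e: e.peak_idx)


def align_to_events(x, fs, event_indices, window_s=4.0, fs_out=100.0):
    """Event-triggered windows of ``x`` resampled to a common time base
    (default 100 Hz).  Returns (lag times, events x samples matrix)."""
    x = np.asarray(x, dtype=float)
    lags = np.arange(-window_s, window_s + 1e-9, 1.0 / fs_out)
    t = np.arange(len(x)) / fs
    rows = []
    for p in event_indices:
        rows.append(np.interp(p / fs + lags, t, x, left=np.nan, right=np.nan))
    return lags, np.array(rows)


def lal_goal_tuning(L, R, heading_rel_goal, keep=None, shift_frames=2,
                    bin_deg=10.0):
    """Binned LAL activity versus heading-relative-to-goal.

    The neural signals are advanced by ``shift_frames`` imaging volumes
    (~218 ms at ~9 Hz) before relating them to behaviour, compensating the
    compass-signal latency.  ``keep`` selects menotaxis-bout, non-standstill
    samples.  Returns (bin centers, mean L, mean R, mean R-L); empty bins
    are NaN.
    """
    L = np.asarray(L, dtype=float)
    R = np.asarray(R, dtype=float)
    rel = np.asarray(heading_rel_goal, dtype=float)
    if shift_frames > 0:
        L = np.concatenate([L[shift_frames:], np.full(shift_frames, np.nan)])
        R = np.concatenate([R[shift_frames:], np.full(shift_frames, np.nan)])
    ok = np.isfinite(L) & np.isfinite(R) & np.isfinite(rel)
    if keep is not None:
        ok &= np.asarray(keep, dtype=bool)
    edges = np.arange(-180.0, 180.0 + bin_deg, bin_deg)
    centers = edges[:-1] + bin_deg / 2
    which = np.digitize(wrap_angle(rel[ok]), edges) - 1
    which = np.clip(which, 0, len(centers) - 1)
    mL = np.full(len(centers), np.nan)
    mR = np.full(len(centers), np.nan)
    for b in range(len(centers)):
        sel = which == b
        if sel.any():
            mL[b] = L[ok][sel].mean()
            mR[b] = R[ok][sel].mean()
    return centers, mL, mR, mR - mL


def stimulation_geometry(frac_in_stim, roi_angles=None):
    """Geometry of a columnar optogenetic stimulation site.

    ``frac_in_stim`` holds the fraction of each column ROI's pixels inside
    the stimulation region.  Returns the stimulation-location angle (PVA of
    the fraction vector), the stimulation site (argmax), and each ROI's
    wrapped distance in ROI counts.
    """
    frac = np.asarray(frac_in_stim, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if frac.sum() == 0:
        raise ValueError("all-zero stimulation fractions")
    n = len(frac)
    if roi_angles is None:
        from .steering_model import column_angles
        roi_angles = column_angles(n)
    stim_angle = pva_phase(frac, roi_angles).phase
    site = int(np.argmax(frac))
    i = np.arange(n)
    wrapped = np.minimum(np.abs(i - site), n - np.abs(i - site))
    return {"stim_angle": float(stim_angle), "site": site,
            "wrapped_distance": wrapped}


def predicted_goal_heading(mean_heading_other, stim_angle_this, stim_angle_other):
    """Predicted goal heading for one stimulation location from the fly's
    mean heading at the other location plus the angular separation of the
    two stimulation sites in the fan-shaped body."""
    return wrap_angle(mean_heading_other + circ_dist(stim_angle_this, stim_angle_other))
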