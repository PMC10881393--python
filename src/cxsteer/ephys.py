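"""Whole-cell recording analysis: spike detection and removal, downsampling
to behaviour frames, heading and goal-conditioned tuning curves, cosine
fits, spike-rate-versus-Vm alignment, and the single-cell model fit.

The single-cell model expresses a PFL3 cell's firing rate in coordinates
relative to its electrophysiologically preferred heading (H' and G'):

    rate = f(cos(H') + d * cos(G' - delta)),   f(x) = a*log(1+exp(b(x+c)))

where delta = G_pref - H_pref is shared across cells.  The five parameters
(delta, d, a, b, c) are fitted jointly to the population-averaged
goal-conditioned tuning matrix by least squares with a multi-start over
delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal as sp_signal

from .circ import circ_dist, wrap_angle
from .steering_model import SingleCellFit, SoftplusParams, softplus

__all__ = [
    "TuningCurve1D",
    "CosineFit",
    "GoalConditionedTuning",
    "RateVmAlignment",
    "detect_spikes",
    "remove_spikes",
    "spike_rate_per_frame",
    "downsample_vm",
    "heading_tuning",
    "fit_cosine",
    "goal_conditioned_tuning",
    "population_average",
    "fit_single_cell_model",
    "rate_vs_vm_alignment",
    "variance_explained",
]


def detect_spikes(vm, fs=10000.0, band=(10.0, 400.0), threshold=1.0,
                  min_space=0.005):
    """Spike times from a membrane-voltage trace.

    The trace is Butterworth band-passed (zero-phase), then peaks above
    ``threshold`` (mV, in the filtered trace) spaced by more than 5 ms are
    kept.  Corner frequencies and threshold are per-cell configuration.
    """
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError("invalid bandpass corners")
    sos = sp_signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = sp_signal.sosfiltfilt(sos, np.asarray(vm, dtype=float))
    peaks, _ = sp_signal.find_peaks(filt, height=threshold,
                                    distance=max(1, int(np.ceil(min_space * fs)) + 1))
    return peaks / fs


def remove_spikes(vm, spike_times, fs=10000.0, halfwidth=0.010):
    """NaN out Vm samples within +-10 ms of each spike (windows may merge)."""
    vm = np.asarray(vm, dtype=float).copy()
    n = len(vm)
    w = int(round(halfwidth * fs))
    for ts in np.asarray(spike_times, dtype=float):
        i = int(round(ts * fs))
        vm[max(0, i - w):min(n, i + w + 1)] = np.nan
    return vm


def _frame_edges(frame_times):
    ft = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(ft) <= 0):
        raise ValueError("frame times must be strictly increasing")
    dt = np.median(np.diff(ft))
    return np.concatenate([ft, [ft[-1] + dt]])


def spike_rate_per_frame(spike_times, frame_times):
    """Spike rate (Hz) per behaviour frame: count in the inter-trigger
    interval divided by its duration."""
    edges = _frame_edges(frame_times)
    counts, _ = np.histogram(np.asarray(spike_times, dtype=float), bins=edges)
    return counts / np.diff(edges)


def downsample_vm(t, vm, frame_times):
    """Mean spike-removed Vm per behaviour frame; all-NaN intervals stay NaN."""
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    edges = _frame_edges(frame_times)
    which = np.digitize(t, edges) - 1
    out = np.full(len(frame_times), np.nan)
    ok = np.isfinite(vm) & (which >= 0) & (which < len(frame_times))
    sums = np.bincount(which[ok], weights=vm[ok], minlength=len(frame_times))
    ns = np.bincount(which[ok], minlength=len(frame_times))
    nz = ns > 0
    out[nz] = sums[nz] / ns[nz]
    return out


@dataclass
class TuningCurve1D:
    bin_centers: np.ndarray  # deg
    mean: np.ndarray  # NaN where the bin is empty
    sem: np.ndarray
    n: np.ndarray


def heading_tuning(y, heading, bin_deg=15.0, keep=None) -> TuningCurve1D:
    """Binned mean/sem/n of a 50 Hz signal versus heading (15 deg bins)."""
    y = np.asarray(y, dtype=float)
    heading = wrap_angle(np.asarray(heading, dtype=float))
    ok = np.isfinite(y) & np.isfinite(heading)
    if keep is not None:
        ok &= np.asarray(keep, dtype=bool)
    edges = np.arange(-180.0, 180.0 + bin_deg, bin_deg)
    centers = edges[:-1] + bin_deg / 2
    which = np.clip(np.digitize(heading[ok], edges) - 1, 0, len(centers) - 1)
    mean = np.full(len(centers), np.nan)
    sem = np.full(len(centers), np.nan)
    n = np.zeros(len(centers), dtype=int)
    for b in range(len(centers)):
        vals = y[ok][which == b]
        n[b] = len(vals)
        if len(vals):
            mean[b] = vals.mean()
            sem[b] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return TuningCurve1D(bin_centers=centers, mean=mean, sem=sem, n=n)


@dataclass
class CosineFit:
    A: float  # amplitude >= 0 after canonicalization
    H_pref: float  # deg; NaN when the curve is flat
    V0: float


def fit_cosine(curve: TuningCurve1D) -> CosineFit:
    """Least-squares fit of A*cos(H - H_pref) + V0 to a tuning curve.

    Linear in (A cos H_pref, A sin H_pref, V0), so the fit is exact on its
    own model class.  A negative amplitude is folded into H_pref + 180.
    """
    ok = np.isfinite(curve.mean)
    if ok.sum() < 3:
        raise ValueError("need at least three populated bins")
    H = np.radians(curve.bin_centers[ok])
    y = curve.mean[ok]
    X = np.column_stack([np.cos(H), np.sin(H), np.ones_like(H)])
    (c1, c2, v0), *_ = np.linalg.lstsq(X, y, rcond=None)
    A = float(np.hypot(c1, c2))
    if A < 1e-12:
        return CosineFit(A=0.0, H_pref=float("nan"), V0=float(v0))
    return CosineFit(A=A, H_pref=wrap_angle(np.degrees(np.arctan2(c2, c1))),
                     V0=float(v0))


@dataclass
class GoalConditionedTuning:
    """Mean-rate matrix over (goal-relative, heading-relative) 45 deg bins.

    Rows are goal bins, columns heading bins; bins with no data are NaN,
    never zero-filled.
    """

    goal_centers: np.ndarray
    heading_centers: np.ndarray
    mean: np.ndarray  # (n_goal, n_heading)
    n: np.ndarray


def goal_conditioned_tuning(rate, heading, goal, H_pref, keep=None,
                            bin_deg=45.0, fold_right=False) -> GoalConditionedTuning:
    """Spike-rate tuning to heading, parsed by the fly's goal angle.

    Heading and goal are re-expressed relative to the cell's preferred
    heading (H' = H - H_pref, G' = G - H_pref).  ``fold_right`` mirrors a
    right-LAL cell into the left-cell convention by negating both relative
    angles.
    """
    rate = np.asarray(rate, dtype=float)
    relH = circ_dist(heading, H_pref)
    relG = circ_dist(goal, H_pref)
    if fold_right:
        relH = wrap_angle(-relH)
        relG = wrap_angle(-relG)
    ok = np.isfinite(rate) & np.isfinite(relH) & np.isfinite(relG)
    if keep is not None:
        ok &= np.asarray(keep, dtype=bool)
    edges = np.arange(-180.0, 180.0 + bin_deg, bin_deg)
    centers = edges[:-1] + bin_deg / 2
    gi = np.clip(np.digitize(relG[ok], edges) - 1, 0, len(centers) - 1)
    hi = np.clip(np.digitize(relH[ok], edges) - 1, 0, len(centers) - 1)
    nb = len(centers)
    sums = np.zeros((nb, nb))
    ns = np.zeros((nb, nb), dtype=int)
    np.add.at(sums, (gi, hi), rate[ok])
    np.add.at(ns, (gi, hi), 1)
    mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return GoalConditionedTuning(goal_centers=centers, heading_centers=centers,
                                 mean=mean, n=ns)


def population_average(tunings):
    """Average goal-conditioned matrices across cells (pairwise-complete)."""
    stack = np.array([t.mean for t in tunings])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    n = np.isfinite(stack).sum(axis=0)
    t0 = tunings[0]
    return GoalConditionedTuning(goal_centers=t0.goal_centers,
                                 heading_centers=t0.heading_centers,
                                 mean=mean, n=n)


def _model_matrix(params, Hp, Gp):
    delta, d, a, b, c = params
    drive = np.cos(Hp) + d * np.cos(Gp - np.radians(delta))
    return a * np.logaddexp(0.0, b * (drive + c))


def fit_single_cell_model(tuning: GoalConditionedTuning, n_starts=24):
    """Fit (delta = G_pref - H_pref, d, a, b, c) to a goal-conditioned matrix.

    Least squares over populated bins with a multi-start over delta (every
    360/n_starts degrees) to avoid local minima.  Returns
    (SingleCellFit, variance explained).
    """
    ok = np.isfinite(tuning.mean)
    if ok.sum() < 10:
        raise ValueError("need at least 10 populated matrix cells")
    G, H = np.meshgrid(np.radians(tuning.goal_centers),
                       np.radians(tuning.heading_centers), indexing="ij")
    y = tuning.mean[ok]
    Hp, Gp = H[ok], G[ok]

    def resid(p):
        return _model_matrix(p, Hp, Gp) - y

    a0 = max(float(np.nanmax(y)) / 3.0, 1.0)
    best = None
    for delta0 in np.arange(-180.0, 180.0, 360.0 / n_starts):
        x0 = [delta0, 0.5, a0, 2.0, -0.5]
        try:
            sol = optimize.least_squares(
                resid, x0,
                bounds=([-360.0, 0.0, 1e-3, 1e-3, -5.0],
                        [360.0, 10.0, 1e4, 50.0, 5.0]))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("single-cell model fit failed to converge")
    delta, d, a, b, c = best.x
    fit = SingleCellFit(softplus=SoftplusParams(a=float(a), b=float(b), c=float(c)),
                        d=float(d), delta_pref=float(wrap_angle(delta)))
    r2 = variance_explained(_model_matrix(best.x, Hp, Gp), y)
    return fit, r2


@dataclass
class RateVmAlignment:
    vm_centers: np.ndarray  # mV
    curves: np.ndarray  # (n_goal_bins, n_vm_bins) mean rate, NaN where empty
    shifts: np.ndarray  # mV per goal bin, reference bin = 0
    alpha: float  # Hz
    beta: float  # 1/mV
    goal_bins: np.ndarray


def rate_vs_vm_alignment(rate, vm, goal_rel, keep=None, vm_bin=4.0,
                         cutoff=-46.0, goal_bin_deg=45.0):
    """Align per-goal-bin spike-rate-versus-Vm curves to a common softplus.

    Vm samples above the cutoff (-46 mV) are discarded; rates are binned in
    4 mV bins separately per goal bin; the per-bin horizontal shifts and the
    shared softplus (alpha, beta) are fitted jointly, minimizing the squared
    difference to alpha*log(1+exp(beta*(Vm + shift))).  Shifts are relative
    to the first populated goal bin.
    """
    rate = np.asarray(rate, dtype=float)
    vm = np.asarray(vm, dtype=float)
    ok = np.isfinite(rate) & np.isfinite(vm) & (vm <= cutoff)
    if keep is not None:
        ok &= np.asarray(keep, dtype=bool)
    goal_rel = wrap_angle(np.asarray(goal_rel, dtype=float))
    gedges = np.arange(-180.0, 180.0 + goal_bin_deg, goal_bin_deg)
    gcent = gedges[:-1] + goal_bin_deg / 2
    vlo = np.floor(vm[ok].min() / vm_bin) * vm_bin
    vedges = np.arange(vlo, cutoff + vm_bin, vm_bin)
    vcent = vedges[:-1] + vm_bin / 2
    curves = np.full((len(gcent), len(vcent)), np.nan)
    for g in range(len(gcent)):
        sel = ok & (np.digitize(goal_rel, gedges) - 1 == g)
        if not sel.any():
            continue
        vi = np.clip(np.digitize(vm[sel], vedges) - 1, 0, len(vcent) - 1)
        for b in range(len(vcent)):
            vals = rate[sel][vi == b]
            if len(vals):
                curves[g, b] = vals.mean()
    populated = [g for g in range(len(gcent)) if np.isfinite(curves[g]).sum() >= 2]
    if len(populated) < 2:
        raise ValueError("need at least two populated goal bins to align")

    def unpack(p):
        shifts = np.zeros(len(gcent))
        for i, g in enumerate(populated):
            shifts[g] = p[i]
        return shifts, p[-2], p[-1]

    def resid(p):
        shifts, alpha, beta = unpack(p)
        out = []
        for g in populated:
            okb = np.isfinite(curves[g])
            pred = alpha * np.logaddexp(0.0, beta * (vcent[okb] + shifts[g]))
            out.append(pred - curves[g][okb])
        return np.concatenate(out)

    # all shifts are free during the fit (the curves share no absolute
    # voltage origin); they are reported relative to the first populated bin
    x0 = np.concatenate([np.full(len(populated), -float(vcent.mean())),
                         [max(np.nanmax(curves), 1.0), 0.5]])
    sol = optimize.least_squares(resid, x0)
    shifts, alpha, beta = unpack(sol.x)
    shifts = shifts - shifts[populated[0]]
    return RateVmAlignment(vm_centers=vcent, curves=curves, shifts=shifts,
                           alpha=float(alpha), beta=float(beta), goal_bins=gcent)


def variance_explained(pred, data):
    """R-squared = 1 - SSE/SST over pairwise-complete entries."""
    pred = np.asarray(pred, dtype=float).ravel()
    data = np.asarray(data, dtype=float).ravel()
    ok = np.isfinite(pred) & np.isfinite(data)
    d = data[ok]
    sst = ((d - d.mean()) ** 2).sum()
    if sst == 0:
        return float("nan")
    sse = ((pred[ok] - d) ** 2).sum()
    return float(1.0 - sse / sst)
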