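"""PFL3 population steering model.

Each PFL3 neuron receives a sinusoidal heading input (via the protocerebral
bridge) and a sinusoidal goal input (via the fan-shaped body) and fires at

    r = f(cos(H - H_pref) + d * cos(G - G_pref)),   f(x) = a*log(1 + exp(b(x+c)))

with the same softplus nonlinearity ``f`` and goal weight ``d`` for every
cell, but connectome-derived preferred angles that differ across the 24 cells
(12 projecting to the left LAL, 12 to the right).  The difference between the
summed right- and left-LAL activity is the egocentric turning signal; the
heading at which it crosses zero with negative slope is the stabilized
("zero") heading, which tracks the goal angle with sub-degree accuracy.

Angles are degrees, positive anticlockwise, wrapped to (-180, 180].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .circ import circ_dist, circ_mean, circ_std, wrap_angle

__all__ = [
    "SoftplusParams",
    "SingleCellFit",
    "PFL3Cell",
    "Population",
    "TurningCurve",
    "SilencingResult",
    "DEFAULT_FIT",
    "softplus",
    "pfl3_rate",
    "build_population",
    "lal_sums",
    "turning_signal",
    "turning_curve",
    "zero_heading",
    "zero_heading_error_stats",
    "silence_cells",
    "silencing_simulation",
    "calibrate_noise",
    "predict_turning_from_fc2",
    "column_angles",
]

# Connectome-derived preferred angles (degrees).  The overall minus sign
# converts ellipsoid-body-referenced angles to heading-referenced angles
# (the compass bump and the heading differ by a sign).
G_PREF_12 = [-a for a in (15.0, 45.0, 75.0, 105.0, 135.0, 165.0,
                          -165.0, -135.0, -105.0, -75.0, -45.0, -15.0)]
H_PREF_RIGHT = [-a for a in (67.5, 112.5, 157.5, 157.5, -157.5, -112.5,
                             -112.5, -67.5, -22.5, -22.5, 22.5, 67.5)]
H_PREF_LEFT = [-a for a in (-67.5, -22.5, 22.5, 22.5, 67.5, 112.5,
                            112.5, 157.5, -157.5, -157.5, -112.5, -67.5)]
# Alternative 9-column goal-angle assignment (first and last columns share 0).
G_PREF_9 = [-a for a in (0.0, 45.0, 90.0, 135.0, 180.0, -135.0, -90.0, -45.0, 0.0)]
# Two-cell columns in the 9-column grouping, identified by the duplicated
# entries of the heading-preference lists (cells 2-3, 5-6, 8-9 share a column).
_NINE_COL_GROUPS = (0, 1, 2, 2, 3, 4, 4, 5, 6, 6, 7, 8)

# Glomerular angle scheme for the 18 bridge glomeruli, left to right
# (the default scheme follows the Delta7 innervation).
BRIDGE_ANGLES_DELTA7 = (-22.5, 22.5, 67.5, 112.5, 157.5, -157.5, -112.5, -67.5,
                        -22.5, 22.5, 67.5, 112.5, 157.5, -157.5, -112.5, -67.5,
                        -22.5, 22.5)


@dataclass(frozen=True)
class SoftplusParams:
    """Softplus nonlinearity f(x) = a*log(1 + exp(b(x+c)))."""

    a: float  # output scale, Hz
    b: float  # gain
    c: float  # input offset

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("softplus requires a > 0 and b > 0")


@dataclass(frozen=True)
class SingleCellFit:
    """Fitted single-cell model: softplus parameters, goal weight d, and the
    fitted preferred-angle offset G_pref - H_pref (degrees)."""

    softplus: SoftplusParams
    d: float
    delta_pref: float

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("goal weight d must be non-negative")

    def to_json(self):
        return json.dumps({"a": self.softplus.a, "b": self.softplus.b,
                           "c": self.softplus.c, "d": self.d,
                           "delta_pref": self.delta_pref})

    @classmethod
    def from_json(cls, s):
        o = json.loads(s)
        return cls(SoftplusParams(o["a"], o["b"], o["c"]), o["d"], o["delta_pref"])


#: Optimal parameters of the single-cell fit to the population-averaged
#: goal-conditioned tuning data.
DEFAULT_FIT = SingleCellFit(softplus=SoftplusParams(a=29.23, b=2.17, c=-0.7),
                            d=0.63, delta_pref=-48.0)


@dataclass(frozen=True)
class PFL3Cell:
    side: str  # "left" or "right": the LAL the axon targets
    column: int  # fan-shaped-body column, 1-based
    H_pref: float
    G_pref: float
    bridge_glomerulus: int  # 1..18, innermost of the innervated pair
    silenced: bool = False


@dataclass(frozen=True)
class Population:
    """The 24-cell PFL3 population plus the shared single-cell fit."""

    cells: tuple
    fit: SingleCellFit
    scheme: str = "delta7"
    n_columns: int = 12

    # Cached per-side angle/mask arrays for vectorized evaluation.
    def __post_init__(self):
        object.__setattr__(self, "_H_pref", np.array([c.H_pref for c in self.cells]))
        object.__setattr__(self, "_G_pref", np.array([c.G_pref for c in self.cells]))
        object.__setattr__(self, "_right", np.array([c.side == "right" for c in self.cells]))
        object.__setattr__(self, "_active", np.array([not c.silenced for c in self.cells], dtype=float))

    @property
    def H_pref(self):
        return self._H_pref

    @property
    def G_pref(self):
        return self._G_pref

    @property
    def right_mask(self):
        return self._right

    @property
    def active(self):
        return self._active


def softplus(x, p: SoftplusParams):
    """Evaluate a*log(1+exp(b(x+c))) overflow-safely (elementwise)."""
    z = p.b * (np.asarray(x, dtype=float) + p.c)
    out = p.a * np.logaddexp(0.0, z)
    return out if out.ndim else float(out)


def pfl3_rate(H, G, cell: PFL3Cell, fit: SingleCellFit):
    """Firing rate of one PFL3 cell at heading H and goal G (degrees)."""
    if cell.silenced:
        return np.zeros_like(np.asarray(H, dtype=float)) if np.ndim(H) else 0.0
    drive = (np.cos(np.radians(np.asarray(H, float) - cell.H_pref))
             + fit.d * np.cos(np.radians(np.asarray(G, float) - cell.G_pref)))
    return softplus(drive, fit.softplus)


def _nearest_glomerulus(connectome_angle, side):
    """Innermost bridge glomerulus (1..18) matching a connectome-frame angle.

    The innervated glomeruli are the innermost 14 (3..16); ties between the
    two glomeruli sharing an angle are broken toward the bridge midline.
    """
    candidates = [g for g in range(3, 17)
                  if BRIDGE_ANGLES_DELTA7[g - 1] == connectome_angle]
    if not candidates:
        return 0
    return min(candidates, key=lambda g: abs(g - 9.5))


def build_population(fit: SingleCellFit = DEFAULT_FIT, scheme: str = "delta7",
                     n_columns: int = 12) -> Population:
    """Build the 24-cell population from the connectome-derived angle lists.

    ``n_columns=12`` is the default functional-column assignment; the
    alternative 9-column assignment groups the three duplicated-heading cell
    pairs per side into shared columns.
    """
    if scheme != "delta7":
        raise ValueError(f"unsupported glomerular angle scheme: {scheme!r}")
    if n_columns not in (12, 9):
        raise ValueError("n_columns must be 12 or 9")
    cells = []
    for side, hlist in (("right", H_PREF_RIGHT), ("left", H_PREF_LEFT)):
        for i, hp in enumerate(hlist):
            if n_columns == 12:
                col, gp = i + 1, G_PREF_12[i]
            else:
                col = _NINE_COL_GROUPS[i] + 1
                gp = G_PREF_9[col - 1]
            glom = _nearest_glomerulus(-hp, side)
            cells.append(PFL3Cell(side=side, column=col, H_pref=wrap_angle(hp),
                                  G_pref=wrap_angle(gp), bridge_glomerulus=glom))
    return Population(cells=tuple(cells), fit=fit, scheme=scheme, n_columns=n_columns)


def _rates(H, G, pop: Population):
    """Rates of all 24 cells; H and G broadcast against the cell axis (last)."""
    H = np.asarray(H, dtype=float)[..., None]
    G = np.asarray(G, dtype=float)[..., None]
    drive = (np.cos(np.radians(H - pop.H_pref))
             + pop.fit.d * np.cos(np.radians(G - pop.G_pref)))
    return softplus(drive, pop.fit.softplus) * pop.active


def lal_sums(H, G, pop: Population):
    """Summed right-LAL and left-LAL PFL3 activity (Hz) at (H, G)."""
    r = _rates(H, G, pop)
    R = r[..., pop.right_mask].sum(axis=-1)
    L = r[..., ~pop.right_mask].sum(axis=-1)
    if R.ndim == 0:
        return float(R), float(L)
    return R, L


def turning_signal(H, G, pop: Population):
    """Right-minus-left LAL activity (Hz): positive drives rightward turns."""
    R, L = lal_sums(H, G, pop)
    return R - L


@dataclass
class TurningCurve:
    offsets: np.ndarray  # heading-minus-goal grid, degrees
    R_sum: np.ndarray
    L_sum: np.ndarray

    @property
    def turn(self):
        return self.R_sum - self.L_sum


def turning_curve(pop: Population, G=0.0, step=1.0) -> TurningCurve:
    """LAL sums and turning signal versus heading offset from the goal."""
    offsets = np.arange(-180.0, 180.0, step)
    R, L = lal_sums(wrap_angle(G + offsets), G, pop)
    return TurningCurve(offsets=offsets, R_sum=R, L_sum=L)


def _neg_slope_crossings(H_grid, T):
    """Linear-interpolated headings where T crosses zero going negative,
    including the wrap-around interval."""
    T_next = np.roll(T, -1)
    idx = np.flatnonzero((T > 0) & (T_next <= 0))
    if idx.size == 0:
        return np.empty(0)
    step = H_grid[1] - H_grid[0]
    frac = T[idx] / (T[idx] - T_next[idx])
    return wrap_angle(H_grid[idx] + frac * step)


def zero_heading(G, pop: Population, grid_step=0.1):
    """Heading where the turning signal crosses zero with negative slope.

    Searched on a ``grid_step`` grid with linear interpolation; if several
    crossings exist, the one nearest the goal is returned.  NaN if the curve
    has no negative-slope crossing (possible under heavy silencing).
    """
    H_grid = np.arange(-180.0, 180.0, grid_step)
    T = turning_signal(H_grid, G, pop)
    crossings = _neg_slope_crossings(H_grid, T)
    if crossings.size == 0:
        return float("nan")
    return float(crossings[np.argmin(np.abs(circ_dist(crossings, G)))])


def zero_heading_error_stats(pop: Population, goal_step=0.5, grid_step=0.1):
    """Signed error e(G) = zero_heading(G) - G over a full goal grid.

    Returns ``(mean_error, std_error)`` in degrees.  The mean is the circular
    mean of the signed errors; the std is the circular standard deviation
    (indistinguishable from the linear std of the wrapped errors at this
    dispersion).
    """
    goals = np.arange(-180.0, 180.0, goal_step)
    errs = np.array([circ_dist(zero_heading(g, pop, grid_step), g) for g in goals])
    if np.isnan(errs).any():
        raise ValueError("undefined zero crossing on the goal grid")
    mean, R = circ_mean(errs)
    return float(mean), circ_std(R=R)


def silence_cells(pop: Population, cell_indices=None, n_random=None, seed=None):
    """Return a population with the given cells (or ``n_random`` randomly
    chosen cells, without replacement) silenced."""
    if cell_indices is None:
        if n_random is None:
            raise ValueError("give cell_indices or n_random")
        if not 0 <= n_random <= len(pop.cells):
            raise ValueError("n_random out of range")
        rng = np.random.default_rng(seed)
        cell_indices = rng.choice(len(pop.cells), size=n_random, replace=False)
    cell_indices = set(int(i) for i in cell_indices)
    if cell_indices and (min(cell_indices) < 0 or max(cell_indices) >= len(pop.cells)):
        raise ValueError("cell index out of range")
    cells = tuple(replace(c, silenced=(i in cell_indices)) for i, c in enumerate(pop.cells))
    return Population(cells=cells, fit=pop.fit, scheme=pop.scheme, n_columns=pop.n_columns)


@dataclass
class SilencingResult:
    n_silenced: int
    noise_amp: float
    n_sims: int
    mean_abs_error: float  # degrees
    mean_correct_directions: float


def silencing_simulation(pop: Population, n_silenced, noise_amp, n_sims=5000,
                         directions=6, correct_threshold=30.0, seed=None,
                         grid_step=0.5) -> SilencingResult:
    """Monte-Carlo silencing experiment.

    Per simulation, a random subset of ``n_silenced`` cells is set to zero and
    each of ``directions`` evenly spaced goal directions is perturbed by
    wrapped-normal noise of sd ``noise_amp`` before the zero heading is read
    off the turning curve.  The error is the absolute circular distance
    between the zero heading and the unperturbed goal; a turning curve with no
    negative-slope crossing counts as maximally wrong (180 deg, incorrect).
    """
    if noise_amp < 0:
        raise ValueError("noise_amp must be non-negative")
    if n_silenced < 0 or n_silenced > len(pop.cells):
        raise ValueError("n_silenced out of range")
    rng = np.random.default_rng(seed)
    goals = wrap_angle(np.arange(directions) * 360.0 / directions)
    H_grid = np.arange(-180.0, 180.0, grid_step)
    cosH = np.cos(np.radians(H_grid[:, None] - pop.H_pref[None, :]))  # (H, 24)
    right = pop.right_mask
    sp = pop.fit.softplus
    sign = np.where(right, 1.0, -1.0)

    abs_err = np.empty((n_sims, directions))
    for s in range(n_sims):
        active = np.ones(len(pop.cells))
        if n_silenced:
            active[rng.choice(len(pop.cells), size=n_silenced, replace=False)] = 0.0
        noisy_G = goals + rng.normal(0.0, noise_amp, size=directions)
        goal_term = pop.fit.d * np.cos(np.radians(noisy_G[:, None] - pop.G_pref[None, :]))
        drive = sp.b * (cosH[None, :, :] + goal_term[:, None, :] + sp.c)
        T = (sp.a * np.logaddexp(0.0, drive) * (active * sign)).sum(axis=-1)  # (dir, H)
        for k in range(directions):
            crossings = _neg_slope_crossings(H_grid, T[k])
            if crossings.size == 0:
                abs_err[s, k] = 180.0
            else:
                abs_err[s, k] = np.min(np.abs(circ_dist(crossings, goals[k])))
    correct = (abs_err < correct_threshold).sum(axis=1)
    return SilencingResult(n_silenced=int(n_silenced), noise_amp=float(noise_amp),
                           n_sims=int(n_sims),
                           mean_abs_error=float(abs_err.mean()),
                           mean_correct_directions=float(correct.mean()))


def calibrate_noise(pop: Population, target_correct_directions, n_sims=500,
                    directions=6, seed=None, tol=0.05, max_iter=30):
    """Goal-input noise amplitude (deg) at which the intact model's mean
    correct-direction count matches a behavioural control target (bisection)."""
    if not 0 < target_correct_directions <= directions:
        raise ValueError("target out of range")
    lo, hi = 0.0, 180.0
    score_hi = silencing_simulation(pop, 0, hi, n_sims, directions, seed=seed).mean_correct_directions
    if score_hi > target_correct_directions:
        raise ValueError("target unattainable: even maximal noise scores above it")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        score = silencing_simulation(pop, 0, mid, n_sims, directions, seed=seed).mean_correct_directions
        if abs(score - target_correct_directions) < tol:
            return mid
        if score > target_correct_directions:
            lo = mid
        else:
            hi = mid
        if hi - lo < 0.05:
            break
    return 0.5 * (lo + hi)


def column_angles(n):
    """Angles of n equally spaced fan-shaped-body columns, matching the
    orientation of the 12-column preferred-goal list."""
    return wrap_angle(-(360.0 * (np.arange(n) + 0.5) / n))


def predict_turning_from_fc2(fc2_dff, bar, fit: SingleCellFit = DEFAULT_FIT,
                             fs=10.0, lag_heading=0.2, pop: Population = None):
    """Predict the right-minus-left PFL3 signal using measured FC2 activity
    as the goal input and a bar-locked synthetic compass signal as the
    heading input.

    Per frame, the 16-column FC2 dF/F0 array is periodically interpolated to
    the model's 12 columns and each column min-max normalized to [-1, 1] over
    the whole recording; the normalized value replaces cos(G - G_pref).  The
    heading input is cos(H - H_pref) with H the inverse of the bar position
    after adding a constant offset aligning the mean bar angle with the mean
    FC2 phase, delayed by ``lag_heading`` seconds (nearest frame) to emulate
    the compass-signal latency.
    """
    import warnings

    from .imaging import pva_phase

    fc2_dff = np.asarray(fc2_dff, dtype=float)
    if fc2_dff.ndim != 2 or fc2_dff.shape[1] != 16:
        raise ValueError("fc2_dff must be frames x 16 ROIs")
    bar = np.asarray(bar, dtype=float)
    if pop is None:
        pop = build_population(fit=fit)

    # periodic interpolation of 16 ROIs onto the 12 model columns
    x16 = (np.arange(16) + 0.5) / 16.0
    x12 = (np.arange(12) + 0.5) / 12.0
    xp = np.concatenate([x16 - 1.0, x16, x16 + 1.0])
    fp = np.concatenate([fc2_dff, fc2_dff, fc2_dff], axis=1)
    cols = np.empty((fc2_dff.shape[0], 12))
    for j, x in enumerate(x12):
        i = np.searchsorted(xp, x) - 1
        w = (x - xp[i]) / (xp[i + 1] - xp[i])
        cols[:, j] = (1 - w) * fp[:, i] + w * fp[:, i + 1]

    lo, hi = cols.min(axis=0), cols.max(axis=0)
    span = hi - lo
    flat = span <= 0
    if flat.any():
        warnings.warn("constant FC2 column(s) normalized to 0")
        span = np.where(flat, 1.0, span)
    goal_cos = 2.0 * (cols - lo) / span - 1.0
    goal_cos[:, flat] = 0.0

    # Constant bar offset aligning the mean bar with the mean FC2 phase.
    # The bump's anatomical position tracks the bar (both live in brain
    # coordinates), so the alignment phase is decoded with the anatomical
    # column angles, i.e. the negated preferred-goal angles.
    roi_ang = -column_angles(16)
    fc2_phase = np.array([pva_phase(v, roi_ang).phase for v in fc2_dff])
    offset, _ = circ_mean(circ_dist(fc2_phase, bar))
    bar_adj = wrap_angle(bar + offset)
    lag = int(round(lag_heading * fs))
    if lag:
        bar_adj = np.concatenate([np.full(lag, bar_adj[0]), bar_adj[:-lag]])
    H = wrap_angle(-bar_adj)

    # map columns to cells: cell i of each side sits in column cell.column
    col_of_cell = np.array([c.column - 1 for c in pop.cells])
    drive = (np.cos(np.radians(H[:, None] - pop.H_pref[None, :]))
             + fit.d * goal_cos[:, col_of_cell])
    rates = softplus(drive, fit.softplus) * pop.active
    return rates[:, pop.right_mask].sum(axis=1) - rates[:, ~pop.right_mask].sum(axis=1)
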