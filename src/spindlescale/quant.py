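"""Trajectory fits and population-scaling statistics.

Pole-to-pole traces are summarised by a four-parameter sigmoid

    f(t) = L1 + L2 / (1 + exp(-(t - t0) / tau)),

whose derived quantities are the final spindle length FLPP = L1 + L2 and
the elongation rate at the inflection point ERPP = (L2 / (4 tau)) * 60 in
um/min. Chromosome separation is summarised by the saturating exponential
f(t) = a (1 - exp(-t / k)) with final separation FLCC = a and segregation
rate SRCC = (a / k) * 60 um/min. Cell size is the cube root of cell
volume; scaling is quantified as the log-log regression slope of a
quantity against cell size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError
from .trajectory import Trajectory

__all__ = [
    "SigmoidFit",
    "ExpFit",
    "StageSummary",
    "ScalingFit",
    "PiecewiseFit",
    "StageAverage",
    "fit_sigmoid",
    "fit_exponential",
    "cell_size_from_volume",
    "scaling_regression",
    "piecewise_transition",
    "anova_f",
    "stage_average",
]


@dataclass(frozen=True)
class SigmoidFit:
    l1: float
    l2: float
    t0: float
    tau: float
    rss: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @property
    def flpp(self) -> float:
        """Final pole-to-pole length L1 + L2 (um)."""
        return self.l1 + self.l2

    @property
    def erpp(self) -> float:
        """Elongation rate at the inflection point, (L2 / 4 tau) * 60 (um/min)."""
        return (self.l2 / (4.0 * self.tau)) * 60.0


@dataclass(frozen=True)
class ExpFit:
    a: float
    k: float
    rss: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.a < 0:
            raise ValueError("a must be >= 0")

    @property
    def flcc(self) -> float:
        """Final chromosome separation a (um)."""
        return self.a

    @property
    def srcc(self) -> float:
        """Segregation rate (a / k) * 60 (um/min)."""
        return (self.a / self.k) * 60.0


@dataclass(frozen=True)
class StageSummary:
    """Across-cell summary of one developmental stage."""

    stage: int
    cell_size: float  # mean cube-root-of-volume (um)
    flpp_mean: float
    flpp_sd: float
    flcc_mean: float
    flcc_sd: float
    erpp_mean: float = float("nan")
    erpp_sd: float = float("nan")
    srcc_mean: float = float("nan")
    srcc_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        for sd in (self.flpp_sd, self.flcc_sd, self.erpp_sd, self.srcc_sd):
            if np.isfinite(sd) and sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class ScalingFit:
    slope: float
    slope_sd: float
    intercept: float
    ci95: tuple[float, float]
    convention: str  # "loglog" | "linear"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.slope <= hi):
            raise ValueError("confidence interval must contain the slope")


@dataclass(frozen=True)
class PiecewiseFit:
    breakpoint: float       # transition size s* (um)
    plateau: float          # rate level for sizes >= s*
    slope_below: float      # d(rate)/d(size) below the break
    rss: float
    degenerate: bool = False


@dataclass(frozen=True)
class StageAverage:
    times: np.ndarray
    d_pp_mean: np.ndarray
    d_pp_sd: np.ndarray
    d_cc_mean: np.ndarray
    d_cc_sd: np.ndarray
    n_cells: int


def _sigmoid(t, l1, l2, t0, tau):
    return l1 + l2 / (1.0 + np.exp(-(t - t0) / tau))


def fit_sigmoid(traj: Trajectory) -> SigmoidFit:
    """Least-squares sigmoid fit to the pole-to-pole trace.

    Initialisation: L1 = first sample, L2 = range, t0 = half-range
    crossing, tau = range / (4 * max slope); on non-convergence the start
    is multi-started over +/-50% perturbations.
    """
    mask = np.isfinite(traj.d_pp)
    t, y = traj.times[mask], traj.d_pp[mask]
    if t.size < 6:
        raise FitError("sigmoid fit needs at least 6 finite samples spanning the rise")
    rng_y = float(np.ptp(y))
    l1_0 = float(y[0])
    l2_0 = rng_y if rng_y > 0 else 1e-6
    half = y.min() + 0.5 * rng_y
    above = np.nonzero(y >= half)[0]
    t0_0 = float(t[above[0]]) if above.size else float(t[t.size // 2])
    slopes = np.diff(y) / np.diff(t)
    max_slope = float(np.max(np.abs(slopes))) if slopes.size else 0.0
    tau_0 = l2_0 / (4.0 * max_slope) if max_slope > 0 else float(np.ptp(t)) / 4.0
    tau_0 = max(tau_0, 1e-3)

    starts = [(l1_0, l2_0, t0_0, tau_0)]
    rng = np.random.default_rng(0)
    for _ in range(8):
        f = rng.uniform(0.5, 1.5, size=4)
        starts.append((l1_0 * f[0], l2_0 * f[1], t0_0 * f[2] if t0_0 else f[2], tau_0 * f[3]))

    # data-supported parameter box: without it the fit can escape to the
    # degenerate quasi-linear branch (t0 -> -inf with L1 -> -inf, L2
    # compensating), which leaves FLPP finite but makes ERPP meaningless
    span = float(np.ptp(t)) if np.ptp(t) > 0 else 1.0
    amp = rng_y if rng_y > 0 else 1e-6
    lower = [y.min() - 5 * amp, -10 * amp, t[0] - span, 1e-6]
    upper = [y.max() + 5 * amp, 10 * amp, t[-1] + span, 10 * span]
    last_err: Exception | None = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _sigmoid, t, y, p0=np.clip(p0, lower, upper), bounds=(lower, upper),
                maxfev=20000,
            )
            rss = float(np.sum((y - _sigmoid(t, *popt)) ** 2))
            return SigmoidFit(float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]), rss)
        except (RuntimeError, ValueError) as exc:
            last_err = exc
    raise FitError(f"sigmoid fit failed after multi-start: {last_err}")


def _saturating_exp(t, a, k):
    return a * (1.0 - np.exp(-t / k))


def fit_exponential(traj: Trajectory) -> ExpFit:
    """Least-squares saturating-exponential fit to the chromosome trace."""
    mask = np.isfinite(traj.d_cc) & (traj.times >= 0)
    t, y = traj.times[mask], traj.d_cc[mask]
    if t.size < 5:
        raise FitError("exponential fit needs at least 5 finite post-onset samples")
    a0 = float(y[-1])
    if np.ptp(y) < 1e-12 and abs(a0) < 1e-12:
        # all-zero trace: amplitude zero, time constant undetermined
        return ExpFit(a=0.0, k=1.0, rss=float(np.sum(y**2)), degenerate=True)
    crossing = np.nonzero(y >= a0 * (1.0 - 1.0 / math.e))[0]
    k0 = float(t[crossing[0]]) if crossing.size and t[crossing[0]] > 0 else float(np.ptp(t)) / 3.0
    k0 = max(k0, 1e-3)
    starts = [(max(a0, 1e-6), k0)]
    rng = np.random.default_rng(0)
    for _ in range(8):
        f = rng.uniform(0.5, 1.5, size=2)
        starts.append((max(a0, 1e-6) * f[0], k0 * f[1]))
    last_err: Exception | None = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _saturating_exp, t, y, p0=p0, bounds=([0.0, 1e-6], [np.inf, np.inf]),
                maxfev=20000,
            )
            rss = float(np.sum((y - _saturating_exp(t, *popt)) ** 2))
            return ExpFit(float(popt[0]), float(popt[1]), rss)
        except (RuntimeError, ValueError) as exc:
            last_err = exc
    raise FitError(f"exponential fit failed after multi-start: {last_err}")


def cell_size_from_volume(volume: float) -> float:
    """Cell size as the cube root of cell volume (um from um^3)."""
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be > 0")
    out = np.cbrt(v)
    return float(out) if out.ndim == 0 else out


def scaling_regression(
    summaries: Sequence[StageSummary],
    quantity: str = "flpp",
    convention: str = "loglog",
) -> ScalingFit:
    """Scaling slope of a per-stage quantity against cell size.

    ``loglog`` (the default) regresses log(quantity) on log(size), so the
    slope is the power-law exponent; ``linear`` uses untransformed axes.
    """
    if len(summaries) < 3:
        raise ValueError("scaling regression needs at least 3 stages")
    attr = f"{quantity}_mean"
    sizes = np.array([s.cell_size for s in summaries], dtype=float)
    vals = np.array([getattr(s, attr) for s in summaries], dtype=float)
    if convention == "loglog":
        if np.any(vals <= 0):
            raise ValueError("log-log regression requires positive quantities")
        x, y = np.log(sizes), np.log(vals)
    elif convention == "linear":
        x, y = sizes, vals
    else:
        raise ValueError("convention must be 'loglog' or 'linear'")
    res = stats.linregress(x, y)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    tcrit = stats.t.ppf(0.975, len(x) - 2) if len(x) > 2 else float("inf")
    half = tcrit * se if np.isfinite(tcrit) else 0.0
    return ScalingFit(
        slope=float(res.slope),
        slope_sd=se,
        intercept=float(res.intercept),
        ci95=(float(res.slope) - half, float(res.slope) + half),
        convention=convention,
    )


def piecewise_transition(sizes, rates, n_grid: int = 401) -> PiecewiseFit:
    """Continuous flat-then-linear fit of rate against cell size.

    rate(s) = plateau for s >= s*; plateau + slope_below * (s - s*) below.
    The breakpoint is profiled over a grid (including the observed sizes)
    and chosen to minimise the residual sum of squares.
    """
    s = np.asarray(sizes, dtype=float)
    r = np.asarray(rates, dtype=float)
    mask = np.isfinite(s) & np.isfinite(r)
    s, r = s[mask], r[mask]
    if s.size < 6:
        raise ValueError("piecewise fit needs at least 6 (size, rate) points")
    lo, hi = float(s.min()), float(s.max())
    grid = np.union1d(np.linspace(lo, hi, n_grid), s)
    grid = grid[(grid > lo) & (grid < hi)]
    if grid.size == 0:
        raise ValueError("no interior breakpoint candidates in the size range")
    best = (np.inf, lo, 0.0, 0.0)
    for s_star in grid:
        hinge = np.minimum(s - s_star, 0.0)
        design = np.column_stack([np.ones_like(s), hinge])
        coef, *_ = np.linalg.lstsq(design, r, rcond=None)
        rss = float(np.sum((r - design @ coef) ** 2))
        if rss < best[0] - 1e-15:
            best = (rss, float(s_star), float(coef[0]), float(coef[1]))
    rss, s_star, plateau, slope_below = best
    # degenerate when a single flat line explains the data as well
    flat_rss = float(np.sum((r - r.mean()) ** 2))
    degenerate = flat_rss <= rss * (1.0 + 1e-9) + 1e-12
    return PiecewiseFit(s_star, plateau, slope_below, rss, degenerate=degenerate)


def anova_f(groups: Sequence[Sequence[float]]) -> float:
    """One-way ANOVA F = MS_between / MS_within.

    Returns inf (flagged by value) when the within-group variance is zero
    but the group means differ.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    if ms_within == 0.0:
        return 0.0 if ms_between == 0.0 else float("inf")
    return float(ms_between / ms_within)


def stage_average(
    trajs: Sequence[Trajectory],
    grid_spacing: float = 10.3,
    grid: Optional[np.ndarray] = None,
) -> StageAverage:
    """Pointwise mean and sample SD of trajectories on a common time grid.

    The default grid spans the overlapping time range of all inputs at the
    acquisition spacing; each trajectory is linearly interpolated onto it.
    """
    if len(trajs) == 0:
        raise ValueError("stage_average needs at least one trajectory")
    if grid is None:
        t_lo = max(tr.times[0] for tr in trajs)
        t_hi = min(tr.times[-1] for tr in trajs)
        if t_hi < t_lo:
            raise ValueError("trajectories have no overlapping time range")
        grid = t_lo + grid_spacing * np.arange(int((t_hi - t_lo) / grid_spacing) + 1)
    grid = np.asarray(grid, dtype=float)
    pp = np.vstack([np.interp(grid, tr.times, tr.d_pp) for tr in trajs])
    cc = np.vstack([np.interp(grid, tr.times, tr.d_cc) for tr in trajs])
    ddof = 1 if len(trajs) > 1 else 0
    return StageAverage(
        times=grid,
        d_pp_mean=pp.mean(axis=0),
        d_pp_sd=pp.std(axis=0, ddof=ddof),
        d_cc_mean=cc.mean(axis=0),
        d_cc_sd=cc.std(axis=0, ddof=ddof),
        n_cells=len(trajs),
    )
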