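"""Pole and chromosome readout from spindle-axis kymographs.

A kymograph is a time-by-position intensity matrix sampled along the 3D
spindle axis. Per frame, the two spindle poles are located as the two most
prominent intensity peaks and refined to sub-pixel precision with the
four-parameter Gaussian

    f(x) = a * exp(-((x - b) / c)^2) + d,

exactly as printed (no factor 2 in the exponent denominator, so ``c`` is
sqrt(2) times the usual Gaussian sigma). Chromosome peaks are searched
strictly between the detected poles. Frames whose detections fail carry
NaN and never contribute fabricated positions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, signal

from .errors import OnsetNotFoundError, PeakDetectionError
from .trajectory import Trajectory

__all__ = [
    "Kymograph",
    "PeakFit",
    "detect_pole_peaks",
    "refine_peak_gaussian",
    "extract_tracks",
    "euclidean_distance",
    "detect_anaphase_onset",
]

DEFAULT_VOXEL_SIZE = (0.1, 0.1, 0.5)  # um, acquisition voxel in x, y, z


@dataclass(frozen=True)
class Kymograph:
    """Intensity matrix with rows = time frames, columns = axial position."""

    intensity: np.ndarray
    channel: str            # "poles" | "chromosomes"
    pixel_size: float       # um per column
    frame_interval: float   # s per row

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2:
            raise ValueError("intensity must be a 2D (time x position) matrix")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        object.__setattr__(self, "intensity", arr)

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]


@dataclass(frozen=True)
class PeakFit:
    """Gaussian refinement of one intensity peak."""

    a: float
    b: float        # center, pixels (sub-pixel)
    c: float        # width, pixels
    d: float        # offset
    center_um: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("width c must be > 0")


def _robust_noise(profile: np.ndarray) -> float:
    """Scaled median absolute deviation of the profile."""
    med = np.median(profile)
    return 1.4826 * float(np.median(np.abs(profile - med)))


def detect_pole_peaks(profile, min_prominence: Optional[float] = None) -> tuple[int, int]:
    """Initial pixel positions of the two spindle poles in one frame.

    The two most prominent local maxima above the prominence floor
    (default 3x the scaled-MAD noise estimate), tie-broken by proximity to
    the profile centre. Raises :class:`PeakDetectionError` for flagged
    frames with fewer than two peaks.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 16:
        raise ValueError("profile too short for pole detection (need >= 16 samples)")
    if min_prominence is None:
        min_prominence = 3.0 * _robust_noise(p)
    peaks, props = signal.find_peaks(p, prominence=max(min_prominence, 1e-12))
    if peaks.size < 2:
        raise PeakDetectionError(
            f"found {peaks.size} peak(s) above prominence {min_prominence:.3g}; frame flagged"
        )
    prom = props["prominences"]
    center = (p.size - 1) / 2.0
    order = np.lexsort((np.abs(peaks - center), -prom))
    chosen = np.sort(peaks[order[:2]])
    return int(chosen[0]), int(chosen[1])


def _gauss(x, a, b, c, d):
    return a * np.exp(-(((x - b) / c) ** 2)) + d


def refine_peak_gaussian(
    profile,
    initial_center: float,
    window: int = 11,
    pixel_size: float = 1.0,
) -> PeakFit:
    """Sub-pixel peak centre from a Gaussian fit in a window of ``window``
    samples around the initial centre.

    A window clipped at the profile edge is fitted on the available
    samples and flagged; non-convergence falls back to the initial centre,
    flagged.
    """
    p = np.asarray(profile, dtype=float)
    if window < 7:
        raise ValueError("window must span at least 7 samples")
    half = window // 2
    i0 = int(round(initial_center))
    lo, hi = max(i0 - half, 0), min(i0 + half + 1, p.size)
    clipped = (hi - lo) < window
    x = np.arange(lo, hi, dtype=float)
    y = p[lo:hi]
    a0 = max(float(y.max() - y.min()), 1e-12)
    p0 = (a0, float(initial_center), max(window / 4.0, 1.0), float(y.min()))
    try:
        popt, _ = optimize.curve_fit(
            _gauss, x, y, p0=p0,
            bounds=([0.0, lo - 1.0, 1e-6, -np.inf], [np.inf, hi, window * 2.0, np.inf]),
            maxfev=10000,
        )
        a, b, c, d = (float(v) for v in popt)
        return PeakFit(a, b, c, d, center_um=b * pixel_size, flagged=clipped)
    except (RuntimeError, ValueError):
        return PeakFit(
            a0, float(initial_center), max(window / 4.0, 1.0), float(y.min()),
            center_um=float(initial_center) * pixel_size, flagged=True,
        )


def _frame_centers(profile, pixel_size) -> tuple[PeakFit, PeakFit]:
    left, right = detect_pole_peaks(profile)
    return (
        refine_peak_gaussian(profile, left, pixel_size=pixel_size),
        refine_peak_gaussian(profile, right, pixel_size=pixel_size),
    )


def extract_tracks(kymo_poles: Kymograph, kymo_chrom: Kymograph) -> Trajectory:
    """Per-frame pole and chromosome positions converted to distances.

    Chromosome peaks are searched strictly between the refined pole
    centres; a frame whose chromosome centres fall outside the pole
    boundaries (or whose detection fails) is flagged with NaN.
    """
    if kymo_poles.n_frames != kymo_chrom.n_frames:
        raise ValueError("pole and chromosome kymographs must have matching frame counts")
    if not np.isclose(kymo_poles.pixel_size, kymo_chrom.pixel_size) or not np.isclose(
        kymo_poles.frame_interval, kymo_chrom.frame_interval
    ):
        raise ValueError("pole and chromosome kymographs must share calibration")
    px = kymo_poles.pixel_size
    n = kymo_poles.n_frames
    d_pp = np.full(n, np.nan)
    d_cc = np.full(n, np.nan)
    d_pc = np.full(n, np.nan)
    for f in range(n):
        try:
            pole_l, pole_r = _frame_centers(kymo_poles.intensity[f], px)
        except PeakDetectionError:
            continue
        b_l, b_r = pole_l.b, pole_r.b
        if b_r <= b_l:
            continue
        d_pp[f] = (b_r - b_l) * px
        profile = kymo_chrom.intensity[f]
        lo, hi = int(np.ceil(b_l)) + 1, int(np.floor(b_r))
        if hi - lo < 5:
            continue
        segment = profile[lo:hi]
        floor = 3.0 * _robust_noise(profile)
        peaks, props = signal.find_peaks(segment, prominence=max(floor, 1e-12))
        if peaks.size == 0:
            continue
        order = np.argsort(props["prominences"])[::-1]
        chosen = np.sort(peaks[order[:2]]) + lo
        fits = [refine_peak_gaussian(profile, c, pixel_size=px) for c in chosen]
        centers = [fit.b for fit in fits]
        if any(not (b_l < b < b_r) for b in centers):
            continue  # chromosome outside pole boundaries: corrupted frame
        if len(centers) == 1:
            c_l = c_r = centers[0]  # unseparated metaphase plate
        else:
            c_l, c_r = centers
        d_cc[f] = (c_r - c_l) * px
        d_pc[f] = 0.5 * ((c_l - b_l) + (b_r - c_r)) * px
    times = kymo_poles.frame_interval * np.arange(n, dtype=float)
    return Trajectory(times=times, d_pp=d_pp, d_cc=d_cc, d_pc=d_pc, cell_id="kymo")


def euclidean_distance(p1, p2, voxel_size=DEFAULT_VOXEL_SIZE) -> float:
    """Anisotropic Euclidean distance (um) between two voxel coordinates."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    v = np.asarray(voxel_size, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(np.sqrt(np.sum(((a - b) * v) ** 2)))


def detect_anaphase_onset(d_cc, min_sustained: int = 2) -> int:
    """Anaphase onset: the last frame before a sustained chromosome rise.

    A rise at frame j is sustained when ``min_sustained`` consecutive
    values exceed the pre-rise baseline (median + 3 scaled-MAD over frames
    before j). Returns j - 1; raises :class:`OnsetNotFoundError` when no
    sustained rise exists.
    """
    y = np.asarray(d_cc, dtype=float)
    if y.size < min_sustained + 1:
        raise OnsetNotFoundError("series too short for onset detection")
    for j in range(1, y.size - min_sustained + 1):
        base = y[:j]
        thr = float(np.median(base)) + 3.0 * 1.4826 * float(np.median(np.abs(base - np.median(base))))
        if np.all(y[j : j + min_sustained] > thr):
            return j - 1
    raise OnsetNotFoundError("no sustained chromosome-separation rise found")
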