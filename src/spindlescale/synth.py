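"""Synthetic data with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration and seed. The
atlas generator emulates the reductive cleavage of the early C. elegans
embryo: cell volumes halve each division from an ellipsoidal embryo
volume, spindle final length follows a power law in cell size (default
exponent 0.75), the elongation rate is flat above a transition size
(~12 um) and declines below it, and chromosome dynamics follow the
near-invariant saturating-exponential law (weak size exponent, default
0.09). Distances carry additive Gaussian measurement noise; kymograph
intensities carry Poisson-like noise (variance proportional to the mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kymo import Kymograph
from .ablation import AblationRecord
from .tomo import MTTrace, SpindleGeometry
from .trajectory import Trajectory

__all__ = [
    "AtlasGenConfig",
    "gen_trajectory",
    "gen_atlas",
    "gen_kymograph",
    "gen_ablation",
    "gen_mt_set",
]

# Anchors for the per-cell laws (16-cell-lineage reference cell):
# spindle final length 11.17 um and elongation rate 2.97 um/min at
# cell size 11 um; chromosome final separation 5.93 um at the same size.
_REF_SIZE = 11.0
_REF_FLPP = 11.17
_REF_ERPP = 2.97
_REF_FLCC = 5.93


@dataclass(frozen=True)
class AtlasGenConfig:
    """Study conditions for the synthetic lineage atlas."""

    seed: int
    stages: tuple[int, ...] = (2, 4, 8, 16, 32, 64)
    cells_per_stage: int = 20
    embryo_length: float = 51.0        # um (wild type; 62 large, 37 small)
    embryo_width: float = 30.0         # um
    spindle_exponent: float = 0.75
    chromosome_exponent: float = 0.09
    final_separation: float = 6.2      # chromosome law plateau proxy at the 2-cell size
    time_constant: float = 29.0        # chromosome law tau (s)
    transition_size: float = 12.0      # um, elongation-rate breakpoint
    noise_sd: float = 0.2              # um, additive measurement noise
    cell_scatter: float = 0.04         # lognormal sd of per-cell quantities
    sampling_interval: float = 10.3    # s
    duration: float = 300.0            # s

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stage list must be non-empty")
        if any(s not in (2, 4, 8, 16, 32, 64) for s in self.stages):
            raise ValueError("stages must be a subset of {2,4,8,16,32,64}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (np.isfinite(self.spindle_exponent) and np.isfinite(self.chromosome_exponent)):
            raise ValueError("exponents must be finite")

    @property
    def embryo_volume(self) -> float:
        """Ellipsoid volume (length x width x width semi-axes)."""
        return (4.0 / 3.0) * math.pi * (self.embryo_length / 2) * (self.embryo_width / 2) ** 2


def _sigmoid(t, l1, l2, t0, tau):
    return l1 + l2 / (1.0 + np.exp(-(t - t0) / tau))


def _satexp(t, a, k):
    return a * (1.0 - np.exp(-t / k))


def gen_trajectory(
    sigmoid_params: tuple[float, float, float, float],
    exp_params: tuple[float, float],
    noise_sd: float = 0.2,
    sampling_interval: float = 10.3,
    duration: float = 300.0,
    seed: int = 0,
    cell_id: str = "synth",
    stage: Optional[int] = None,
    lineage: str = "",
) -> Trajectory:
    """Sample noisy sigmoid pole and exponential chromosome dynamics.

    ``sigmoid_params`` = (L1, L2, t0, tau); ``exp_params`` = (a, k). Time
    zero is anaphase onset; the chromosome trace is zero-based there by
    construction of the saturating exponential.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = sampling_interval * np.arange(int(duration / sampling_interval) + 1, dtype=float)
    d_pp = _sigmoid(t, *sigmoid_params) + rng.normal(0.0, noise_sd, t.size)
    d_cc = _satexp(t, *exp_params) + rng.normal(0.0, noise_sd, t.size)
    return Trajectory(
        times=t,
        d_pp=np.clip(d_pp, 0.0, None),
        d_cc=np.clip(d_cc, 0.0, None),
        cell_id=cell_id,
        stage=stage,
        lineage=lineage,
    )


def gen_atlas(config: AtlasGenConfig) -> tuple[list[Trajectory], pd.DataFrame]:
    """Synthetic lineage atlas: per-cell trajectories plus metadata.

    Metadata columns: cell_id, stage, lineage, volume_um3 and the
    generating (ground-truth) per-cell parameters flpp_true, erpp_true,
    flcc_true, srcc_true.
    """
    rng = np.random.default_rng(config.seed)
    size_2cell = (config.embryo_volume / 2.0) ** (1.0 / 3.0)
    flcc_scale = config.final_separation / size_2cell ** config.chromosome_exponent
    flpp_scale = _REF_FLPP / _REF_SIZE ** config.spindle_exponent
    lineages = ("ABa", "ABp", "EMS", "P2", "MS", "E", "C", "P3")
    trajs: list[Trajectory] = []
    meta_rows = []
    for stage_n in config.stages:
        vol_stage = config.embryo_volume / stage_n
        for i in range(config.cells_per_stage):
            vol = vol_stage * rng.lognormal(0.0, config.cell_scatter)
            size = vol ** (1.0 / 3.0)
            flpp = flpp_scale * size ** config.spindle_exponent * rng.lognormal(0.0, config.cell_scatter)
            # elongation rate: flat plateau above the transition size,
            # declining linearly toward zero size below it
            rate_factor = 1.0 if size >= config.transition_size else size / config.transition_size
            erpp = _REF_ERPP * rate_factor * rng.lognormal(0.0, config.cell_scatter)
            l1 = 0.5 * flpp
            l2 = flpp - l1
            tau = l2 * 60.0 / (4.0 * erpp)
            t0 = 30.0
            flcc = flcc_scale * size ** config.chromosome_exponent * rng.lognormal(0.0, config.cell_scatter)
            k = config.time_constant * rng.lognormal(0.0, config.cell_scatter)
            cell_id = f"s{stage_n}_c{i:03d}"
            lineage = lineages[i % len(lineages)]
            trajs.append(
                gen_trajectory(
                    (l1, l2, t0, tau),
                    (flcc, k),
                    noise_sd=config.noise_sd,
                    sampling_interval=config.sampling_interval,
                    duration=config.duration,
                    seed=int(rng.integers(2**31)),
                    cell_id=cell_id,
                    stage=stage_n,
                    lineage=lineage,
                )
            )
            meta_rows.append(
                {
                    "cell_id": cell_id,
                    "stage": stage_n,
                    "lineage": lineage,
                    "volume_um3": vol,
                    "flpp_true": flpp,
                    "erpp_true": erpp,
                    "flcc_true": flcc,
                    "srcc_true": flcc / k * 60.0,
                }
            )
    return trajs, pd.DataFrame(meta_rows)


def gen_kymograph(
    d_pp_series,
    d_cc_series,
    pixel_size: float = 0.1,
    frame_interval: float = 10.3,
    fov: float = 30.0,
    peak_width_px: float = 3.0,
    amplitude: float = 100.0,
    offset: float = 10.0,
    snr: Optional[float] = 10.0,
    seed: int = 0,
) -> tuple[Kymograph, Kymograph]:
    """Two-channel synthetic kymograph from a pole/chromosome track pair.

    Peaks are Gaussian in the fitted four-parameter shape, centred at
    +/- D/2 around the field-of-view centre. ``snr`` is the peak
    amplitude over the noise sd at the peak; noise variance scales with
    the local mean (Poisson-like). ``snr=None`` is noiseless.
    """
    d_pp = np.asarray(d_pp_series, dtype=float)
    d_cc = np.asarray(d_cc_series, dtype=float)
    if d_pp.shape != d_cc.shape:
        raise ValueError("pole and chromosome series must have equal length")
    n_px = int(round(fov / pixel_size))
    center = (n_px - 1) / 2.0
    margin_px = 4 * peak_width_px
    if np.any(d_pp / 2.0 / pixel_size + margin_px > center):
        raise ValueError("track leaves the field of view; enlarge fov")
    rng = np.random.default_rng(seed)
    x = np.arange(n_px, dtype=float)

    def build(separations):
        frames = np.empty((separations.shape[0], n_px))
        for f, sep in enumerate(separations):
            b1 = center - sep / 2.0 / pixel_size
            b2 = center + sep / 2.0 / pixel_size
            prof = offset + amplitude * (
                np.exp(-(((x - b1) / peak_width_px) ** 2))
                + np.exp(-(((x - b2) / peak_width_px) ** 2))
            )
            frames[f] = prof
        if snr is not None:
            sd = (amplitude / snr) * np.sqrt(np.clip(frames, 0.0, None) / amplitude)
            frames = frames + rng.normal(0.0, 1.0, frames.shape) * sd
        return np.clip(frames, 0.0, None)

    kymo_poles = Kymograph(build(d_pp), "poles", pixel_size, frame_interval)
    kymo_chrom = Kymograph(build(d_cc), "chromosomes", pixel_size, frame_interval)
    return kymo_poles, kymo_chrom


def gen_ablation(
    n_records: int = 20,
    v_pp_before: float = 0.04,
    v_cc: float = 0.12,
    pole_multiplier: float = 1.4,
    recovery_time: float = 15.0,
    chromosome_invariant: bool = True,
    noise_sd: float = 0.03,
    sampling_interval: float = 1.0,
    t_range: tuple[float, float] = (-12.0, 20.0),
    seed: int = 0,
    include_controls: bool = True,
) -> list[AblationRecord]:
    """Synthetic severing cohort with a pole-velocity jump at t = 0.

    Pole separation elongates at ``v_pp_before`` (um/s) before the cut and
    at ``pole_multiplier`` times that during the first ``recovery_time``
    seconds after it, then relaxes back. Chromosome separation proceeds at
    the constant rate ``v_cc``, unaffected by the cut when
    ``chromosome_invariant`` (the observed behaviour the cohort emulates);
    over the ~30 s record the saturating-exponential law is locally
    linear, so a constant rate is used. Controls share the pre-cut slopes
    with no jump.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(t_range[0], t_range[1] + 1e-9, sampling_interval)
    records = []
    n_controls = n_records // 4 if include_controls else 0
    for rec in range(n_records + n_controls):
        is_control = rec >= n_records
        v0 = v_pp_before * rng.lognormal(0.0, 0.05)
        mult = 1.0 if is_control else pole_multiplier
        d_pp = np.empty_like(t)
        d0 = 8.0
        for j, tj in enumerate(t):
            if tj <= 0:
                d_pp[j] = d0 + v0 * tj
            elif tj <= recovery_time:
                d_pp[j] = d0 + mult * v0 * tj
            else:
                d_pp[j] = d0 + mult * v0 * recovery_time + v0 * (tj - recovery_time)
        vc = v_cc * rng.lognormal(0.0, 0.05)
        cc_mult = 1.0 if (chromosome_invariant or is_control) else pole_multiplier
        d_cc = 2.0 + vc * np.where(t <= 0, t, cc_mult * t)
        d_pp = d_pp + rng.normal(0.0, noise_sd, t.size)
        d_cc = np.clip(d_cc + rng.normal(0.0, noise_sd, t.size), 0.0, None)
        d_pc = np.clip((d_pp - d_cc) / 2.0, 0.0, None)
        records.append(
            AblationRecord(
                times=t.copy(),
                d_pp=d_pp,
                d_pc=d_pc,
                d_cc=d_cc,
                condition="control" if is_control else "ablated",
                record_id=f"{'ctrl' if is_control else 'abl'}_{rec:02d}",
            )
        )
    return records


def gen_mt_set(
    counts: dict[str, int],
    geometry: Optional[SpindleGeometry] = None,
    pole_radius: float = 0.5,
    seed: int = 0,
) -> tuple[list[MTTrace], SpindleGeometry]:
    """Microtubule traces with exact per-class ground-truth counts.

    Default geometry resembles a 32-cell-stage anaphase spindle: poles
    4 um from the midplane, chromosome plates at +/-1.5 um along the axis.
    """
    if geometry is None:
        geometry = SpindleGeometry(
            centriole1=np.array([0.0, 0.0, 4.0]),
            centriole2=np.array([0.0, 0.0, -4.0]),
            plate1_centroid=np.array([0.0, 0.0, 1.5]),
            plate2_centroid=np.array([0.0, 0.0, -1.5]),
            axis=np.array([0.0, 0.0, 1.0]),
        )
    rng = np.random.default_rng(seed)
    axis = geometry.axis
    plate_half = abs((geometry.plate1_centroid - geometry.plate2_centroid) @ axis) / 2.0
    mid = 0.5 * (geometry.plate1_centroid + geometry.plate2_centroid)
    # local frame perpendicular to the axis
    perp = np.eye(3)[np.argmin(np.abs(axis))]
    u = np.cross(axis, perp)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)

    def radial(r_max):
        r = r_max * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        return r * (math.cos(phi) * u + math.sin(phi) * w)

    def polyline(p_start, p_end):
        n_pts = int(rng.integers(2, 6))
        frac = np.linspace(0.0, 1.0, n_pts)[:, None]
        return MTTrace(points=p_start + frac * (p_end - p_start))

    traces: list[MTTrace] = []
    for cls, n in counts.items():
        for _ in range(n):
            if cls == "interpolar":
                centriole = geometry.centriole1 if rng.uniform() < 0.5 else geometry.centriole2
                start = centriole + 0.6 * pole_radius * _unit(rng)
                end = mid + rng.uniform(-0.9, 0.9) * plate_half * axis + radial(1.5)
                traces.append(polyline(start, end))
            elif cls == "mid_spindle":
                z1 = rng.uniform(-0.8, 0.8) * plate_half
                z2 = rng.uniform(-0.8, 0.8) * plate_half
                start = mid + z1 * axis + radial(1.5)
                end = mid + z2 * axis + radial(1.5)
                traces.append(polyline(start, end))
            elif cls == "other":
                # astral stubs outside the inter-plate slab, clear of the poles
                side = 1.0 if rng.uniform() < 0.5 else -1.0
                z1 = side * (plate_half + rng.uniform(0.3, 0.8))
                z2 = side * (plate_half + rng.uniform(0.3, 0.8))
                start = mid + z1 * axis + radial(1.5) + 1.2 * pole_radius * u
                end = mid + z2 * axis + radial(1.5) + 1.2 * pole_radius * u
                for pt in (start, end):
                    for c in (geometry.centriole1, geometry.centriole2):
                        if np.linalg.norm(pt - c) <= pole_radius:
                            raise RuntimeError("generated 'other' end landed pole-proximal")
                traces.append(polyline(start, end))
            else:
                raise ValueError(f"unknown class {cls!r}")
    return traces, geometry


def _unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
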