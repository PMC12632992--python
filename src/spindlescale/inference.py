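"""Stage-wise inference of the microtubule catastrophe rate.

For each developmental stage the catastrophe rate lambda is the sole free
parameter: the squared error between the simulated and target pole-to-pole
trajectory,

    E(lambda) = sum_i (L_i^target - L_i^sim(lambda))^2,

is minimised over lambda in [0.001, 10] with differential evolution
(rand/1/bin, 50 candidates per generation). Simulations inside the search
loop run at reduced resolution (coarser cortical mesh); the reported error
is re-evaluated at full resolution for the returned optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .errors import InferenceError, SpindleError
from .model import simulate_spindle
from .params import (
    DEFAULT_DRAGS,
    DEFAULT_LAW,
    DEFAULT_MOTORS,
    ChromosomeLaw,
    DragParams,
    MotorParams,
    MTParams,
    StageConfig,
)
from .trajectory import Trajectory

__all__ = ["DEConfig", "InferenceResult", "trajectory_error", "fit_catastrophe_rate", "fit_all_stages"]

_LAMBDA_BOUNDS = (0.001, 10.0)
_PENALTY = 1e12  # finite sentinel for candidates whose simulation fails


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings; the seed is mandatory."""

    seed: int
    population_size: int = 50
    max_generations: int = 25
    bounds: tuple[float, float] = _LAMBDA_BOUNDS
    tol: float = 1e-3  # stop when the population's lambda spread falls below this

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (_LAMBDA_BOUNDS[0] <= lo < hi <= _LAMBDA_BOUNDS[1]):
            raise ValueError(f"bounds must lie within {_LAMBDA_BOUNDS}")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")


@dataclass(frozen=True)
class InferenceResult:
    lambda_hat: float
    error: float       # E(lambda_hat), um^2, at full resolution
    generations: int
    seed: int

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be >= 0")


def trajectory_error(
    lam: float,
    target: Trajectory,
    stage: StageConfig,
    motors: MotorParams = DEFAULT_MOTORS,
    drags: DragParams = DEFAULT_DRAGS,
    law: ChromosomeLaw = DEFAULT_LAW,
    dt: float = 0.01,
    n_patches: int = 2000,
) -> float:
    """E(lambda): squared D_P-P mismatch summed over the target's time points.

    The simulation runs to the last target time and is linearly
    interpolated onto the target grid.
    """
    if len(target) == 0:
        raise ValueError("target trajectory is empty")
    lo, hi = _LAMBDA_BOUNDS
    if not (lo <= lam <= hi):
        raise ValueError(f"lambda {lam} outside the search bounds {_LAMBDA_BOUNDS}")
    t_max = float(target.times[-1])
    sim = simulate_spindle(
        stage,
        mt=MTParams(catastrophe_rate=lam),
        motors=motors,
        drags=drags,
        law=law,
        t_end=t_max,
        dt=dt,
        n_patches=n_patches,
    )
    if sim.times[-1] < t_max - 1e-6:
        raise InferenceError(
            f"target times extend to {t_max} s but simulation sampled only to {sim.times[-1]} s"
        )
    l_sim = np.interp(target.times, sim.times, sim.d_pp)
    return float(np.sum((target.d_pp - l_sim) ** 2))


def fit_catastrophe_rate(
    target: Trajectory,
    stage: StageConfig,
    de: DEConfig,
    motors: MotorParams = DEFAULT_MOTORS,
    drags: DragParams = DEFAULT_DRAGS,
    law: ChromosomeLaw = DEFAULT_LAW,
    search_n_patches: int = 512,
    search_dt: float = 0.01,
    refine_n_patches: int = 2000,
) -> InferenceResult:
    """Bound-respecting DE minimiser of E(lambda); deterministic given the seed.

    Candidates whose simulation fails (stability or pole escape at extreme
    lambda) receive a large finite penalty so the search simply avoids
    them. The returned error is recomputed at full mesh resolution.
    """

    def objective(x: np.ndarray) -> float:
        try:
            return trajectory_error(
                float(x[0]), target, stage, motors, drags, law,
                dt=search_dt, n_patches=search_n_patches,
            )
        except SpindleError:
            return _PENALTY

    generations = 0

    def converged(intermediate_result) -> None:
        nonlocal generations
        generations = int(intermediate_result.nit)
        pop = np.asarray(intermediate_result.population)
        if np.ptp(pop[:, 0]) < de.tol:
            raise StopIteration

    result = differential_evolution(
        objective,
        bounds=[de.bounds],
        strategy="rand1bin",
        mutation=0.7,
        recombination=0.9,
        popsize=de.population_size,
        maxiter=de.max_generations,
        init="latinhypercube",
        tol=0.0,
        seed=de.seed,
        polish=False,
        callback=converged,
    )
    lam_hat = float(result.x[0])
    if not np.isfinite(result.fun) or result.fun >= _PENALTY:
        raise InferenceError("no candidate produced a finite trajectory error")
    error = trajectory_error(
        lam_hat, target, stage, motors, drags, law,
        dt=search_dt, n_patches=refine_n_patches,
    )
    return InferenceResult(
        lambda_hat=lam_hat,
        error=error,
        generations=max(generations, int(result.nit)),
        seed=de.seed,
    )


def _stage_seed(base_seed: int, stage: int) -> int:
    """Per-stage seed, order-independent and below 2**31."""
    return int(np.random.SeedSequence(entropy=base_seed, spawn_key=(stage,)).generate_state(1)[0] % (2**31))


def fit_all_stages(
    targets: Mapping[int, Trajectory],
    configs: Mapping[int, StageConfig],
    de: DEConfig,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit lambda per stage with all other parameters held fixed.

    Returns a table (stage, cell_radius, lambda_hat, error, generations,
    seed) in ascending stage order; failures propagate with the stage label.
    """
    rows = []
    for stage_n in sorted(targets):
        if stage_n not in configs:
            raise KeyError(f"no StageConfig for stage {stage_n}")
        cfg = configs[stage_n]
        stage_de = DEConfig(
            seed=_stage_seed(de.seed, stage_n),
            population_size=de.population_size,
            max_generations=de.max_generations,
            bounds=de.bounds,
            tol=de.tol,
        )
        try:
            res = fit_catastrophe_rate(targets[stage_n], cfg, stage_de, **fit_kwargs)
        except SpindleError as exc:
            raise InferenceError(f"stage {stage_n}: {exc}") from exc
        rows.append(
            {
                "stage": stage_n,
                "cell_radius": cfg.cell_radius,
                "lambda_hat": res.lambda_hat,
                "error": res.error,
                "generations": res.generations,
                "seed": res.seed,
            }
        )
    return pd.DataFrame(rows)
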