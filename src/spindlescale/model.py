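"""Stoichiometric model of anaphase spindle elongation in a spherical cell.

Two centrosomal asters nucleate microtubules isotropically; motors anchored
on the cell cortex bind at most one microtubule each (stoichiometric
binding) and pull on the aster they are bound to. The fraction of motors at
cortical position Y engaged with aster i is a coarse-grained field
P_i(Y, t) evolving as

    dP_i/dt = Omega_i(Y, t) * (1 - P_1 - P_2) - kappa * P_i,

where Omega_i is the rate at which microtubules from aster i impinge on Y
and kappa is the motor unbinding rate. The total pull on pole i is the
surface integral

    F_i = (M f0 / A) * Integral P_i(Y, t) xi_hat(x_i, Y) dA,

with M the motor count, f0 the per-motor force, A the cell area and xi_hat
the unit vector from the pole to the cortical point. Pole motion balances
this pull against cytoplasmic drag eta and a viscous coupling nu to the
chromosome plates along the spindle axis s_hat:

    eta dx_i/dt + nu ((dx_i/dt - dc_i/dt) . s_hat) s_hat = F_i.

Chromatid separation is imposed, Delta_c(t) = c_f (1 - exp(-t/tau)); the
plates ride the instantaneous pole midpoint, separated by Delta_c along
s_hat. Setting nu = 0 and freezing the chromosomes recovers the plain
aster-positioning model eta dx_i/dt = F_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SimulationError, StabilityError
from .mesh import SurfaceMesh, build_cell_mesh
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

__all__ = [
    "SpindleState",
    "MotorField",
    "impingement_rate",
    "evolve_motor_field",
    "cortical_force",
    "imposed_separation",
    "step_state",
    "simulate_spindle",
]

_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class SpindleState:
    """Positions of the two poles and two chromosome plates at time ``t``.

    ``s_hat`` is the spindle axis (x1 - x2) normalised; construction fails
    if the poles coincide.
    """

    t: float
    x1: np.ndarray
    x2: np.ndarray
    c1: np.ndarray
    c2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "c1", "c2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.linalg.norm(self.x1 - self.x2) == 0.0:
            raise SimulationError(f"poles coincide at t={self.t}: spindle axis undefined")

    @property
    def s_hat(self) -> np.ndarray:
        axis = self.x1 - self.x2
        return axis / np.linalg.norm(axis)

    @property
    def d_pp(self) -> float:
        return float(np.linalg.norm(self.x1 - self.x2))

    @property
    def d_cc(self) -> float:
        return float(np.linalg.norm(self.c1 - self.c2))


@dataclass(frozen=True)
class MotorField:
    """Per-patch probabilities that a cortical motor is bound to aster 1 / 2."""

    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self) -> None:
        p1 = np.asarray(self.p1, dtype=float)
        p2 = np.asarray(self.p2, dtype=float)
        if p1.shape != p2.shape:
            raise ValueError("p1 and p2 must be aligned to the same patches")
        if np.any(p1 < -_BOUND_TOL) or np.any(p2 < -_BOUND_TOL):
            raise ValueError("bound probabilities must be non-negative")
        if np.any(p1 + p2 > 1.0 + _BOUND_TOL):
            raise ValueError("stoichiometry violated: P1 + P2 > 1 at some patch")
        object.__setattr__(self, "p1", p1)
        object.__setattr__(self, "p2", p2)

    @classmethod
    def zeros(cls, n_patches: int) -> "MotorField":
        return cls(np.zeros(n_patches), np.zeros(n_patches))


def impingement_rate(d, mt: MTParams, motors: MotorParams):
    """Rate Omega (1/s) of microtubule impingement on a motor at distance ``d``.

    Omega = N_T lambda (r^2 / 4 d^2) exp(-lambda d / V_g): at steady state
    microtubules nucleate at n_dot = N_T lambda, a motor of capture
    cross-section pi r^2 subtends the fraction pi r^2 / (4 pi d^2) of the
    isotropic emission sphere, and a microtubule survives to length d with
    probability exp(-lambda d / V_g). This closed form is the single place
    to swap in an alternative impingement prefactor.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("impingement_rate requires d > 0 (pole on the cortex is out of domain)")
    lam = mt.catastrophe_rate
    out = (
        mt.n_per_aster
        * lam
        * (motors.size ** 2 / (4.0 * d ** 2))
        * np.exp(-lam * d / mt.growth_velocity)
    )
    return float(out) if out.ndim == 0 else out


def evolve_motor_field(
    field: MotorField,
    mesh: SurfaceMesh,
    state: SpindleState,
    mt: MTParams,
    motors: MotorParams,
    dt: float,
) -> MotorField:
    """One explicit first-order update of the bound-motor field.

    Raises :class:`StabilityError` if ``dt`` violates the explicit-update
    stability bound dt * (Omega_1 + Omega_2 + kappa) < 1 at any patch (the
    sum form is what guarantees P1 + P2 stays within [0, 1]).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    d1 = np.linalg.norm(mesh.patch_centers - state.x1, axis=1)
    d2 = np.linalg.norm(mesh.patch_centers - state.x2, axis=1)
    om1 = impingement_rate(d1, mt, motors)
    om2 = impingement_rate(d2, mt, motors)
    worst = float(np.max(om1 + om2)) + motors.unbinding_rate
    if dt * worst >= 1.0:
        raise StabilityError(
            f"dt={dt} violates the stability condition dt*(Omega+kappa) < 1 "
            f"(dt*worst={dt * worst:.3f}); reduce dt below {1.0 / worst:.4g} s"
        )
    free = 1.0 - field.p1 - field.p2
    p1 = field.p1 + dt * (om1 * free - motors.unbinding_rate * field.p1)
    p2 = field.p2 + dt * (om2 * free - motors.unbinding_rate * field.p2)
    return MotorField(p1, p2)


def cortical_force(
    field: MotorField,
    mesh: SurfaceMesh,
    pole_position: np.ndarray,
    which_aster: int,
    motors: MotorParams,
) -> np.ndarray:
    """Total pulling force (pN) on one pole from its bound cortical motors.

    F_i = (M f0 / A) sum_k P_i,k xi_hat(x_i, Y_k) dA_k with xi_hat the unit
    vector from the pole to the patch center.
    """
    pole = np.asarray(pole_position, dtype=float)
    if np.linalg.norm(pole) >= mesh.radius:
        raise SimulationError("pole lies on or outside the cell surface")
    if which_aster not in (1, 2):
        raise ValueError("which_aster must be 1 or 2")
    p = field.p1 if which_aster == 1 else field.p2
    vec = mesh.patch_centers - pole
    dist = np.linalg.norm(vec, axis=1)
    m = motors.count(mesh.radius)
    weights = (m * motors.force / mesh.area) * p * mesh.patch_areas / dist
    return weights @ vec


def imposed_separation(t, law: ChromosomeLaw = DEFAULT_LAW):
    """Imposed chromatid separation Delta_c(t) = c_f (1 - exp(-t/tau)), t >= 0."""
    return law.separation(t)


def step_state(
    state: SpindleState,
    f1: np.ndarray,
    f2: np.ndarray,
    drags: DragParams = DEFAULT_DRAGS,
    law: ChromosomeLaw = DEFAULT_LAW,
    dt: float = 0.01,
) -> SpindleState:
    """Advance poles and chromosome plates by one explicit step.

    The force balance is solved by axis decomposition: along s_hat the pole
    velocity is (F_par + nu * c_dot_par) / (eta + nu); perpendicular to the
    axis it is F_perp / eta. The plates are re-placed on the new pole
    midpoint, separated by Delta_c(t + dt) along the new axis; their axial
    velocity enters through the analytic derivative of Delta_c.
    """
    s_hat = state.s_hat
    dc_rate = law.rate(state.t)
    eta, nu = drags.pole_drag, drags.coupling

    new_poles = []
    for pole, force, sign in ((state.x1, np.asarray(f1, float), +1.0),
                              (state.x2, np.asarray(f2, float), -1.0)):
        f_par = float(force @ s_hat)
        f_perp = force - f_par * s_hat
        c_dot_par = sign * dc_rate / 2.0
        v = ((f_par + nu * c_dot_par) / (eta + nu)) * s_hat + f_perp / eta
        new_poles.append(pole + dt * v)
    x1, x2 = new_poles

    t_new = state.t + dt
    axis = x1 - x2
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        raise SimulationError(f"poles coincide at t={t_new}")
    s_new = axis / norm
    mid = 0.5 * (x1 + x2)
    half_sep = 0.5 * law.separation(t_new)
    return SpindleState(t=t_new, x1=x1, x2=x2,
                        c1=mid + half_sep * s_new, c2=mid - half_sep * s_new)


def _reference_run(stage, mt, motors, drags, law, t_end, dt, sample_every, mesh):
    """Step-by-step simulation through the public per-operation API.

    Slow; serves as the reference the fused kernel is checked against.
    """
    half = 0.5 * stage.initial_d_pp
    state = SpindleState(
        t=0.0,
        x1=np.array([0.0, 0.0, half]),
        x2=np.array([0.0, 0.0, -half]),
        c1=np.zeros(3),
        c2=np.zeros(3),
    )
    field = MotorField.zeros(mesh.n_patches)
    n_steps = int(round(t_end / dt))
    times, d_pp, d_cc, d_pc = [], [], [], []
    next_sample = 0.0
    for i in range(n_steps + 1):
        if state.t >= next_sample - 1e-9:
            times.append(state.t)
            d_pp.append(state.d_pp)
            d_cc.append(law.separation(state.t))
            d_pc.append(float(np.linalg.norm(state.x1 - state.c1)))
            next_sample += sample_every
        if i == n_steps:
            break
        field = evolve_motor_field(field, mesh, state, mt, motors, dt)
        f1 = cortical_force(field, mesh, state.x1, 1, motors)
        f2 = cortical_force(field, mesh, state.x2, 2, motors)
        state = step_state(state, f1, f2, drags, law, dt)
        for pole in (state.x1, state.x2):
            if np.linalg.norm(pole) >= mesh.radius:
                raise SimulationError(
                    f"pole escaped the cell at t={state.t:.2f} s (parameter pathology)"
                )
    return np.array(times), np.array(d_pp), np.array(d_cc), np.array(d_pc)


def simulate_spindle(
    stage: StageConfig,
    mt: MTParams | None = None,
    motors: MotorParams = DEFAULT_MOTORS,
    drags: DragParams = DEFAULT_DRAGS,
    law: ChromosomeLaw = DEFAULT_LAW,
    t_end: float = 300.0,
    dt: float = 0.01,
    sample_every: float = 10.3,
    n_patches: int = 2000,
    engine: str = "auto",
) -> Trajectory:
    """Simulate spindle elongation for one developmental stage.

    Poles start at the cell centre +/- initial_d_pp/2 along a fixed axis
    with the chromosome plates coincident at the centre and the motor field
    at zero. Samples D_P-P, D_C-C and D_P-C every ``sample_every`` seconds
    (default: the 10.3 s acquisition interval).

    ``engine`` selects the fused compiled kernel ("fast"), the
    per-operation reference loop ("reference"), or the kernel with a
    NumPy fallback ("auto").
    """
    if mt is None:
        if stage.catastrophe_rate is None:
            raise ValueError("stage.catastrophe_rate is unset and no MTParams given")
        mt = MTParams(catastrophe_rate=stage.catastrophe_rate)
    mesh = build_cell_mesh(stage.cell_radius, n_patches)
    if engine == "reference":
        times, d_pp, d_cc, d_pc = _reference_run(
            stage, mt, motors, drags, law, t_end, dt, sample_every, mesh
        )
    elif engine in ("auto", "fast"):
        from ._kernel import run_simulation

        times, d_pp, d_cc, d_pc = run_simulation(
            mesh, stage, mt, motors, drags, law, t_end, dt, sample_every
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return Trajectory(
        times=times,
        d_pp=d_pp,
        d_cc=d_cc,
        d_pc=d_pc,
        cell_id=f"sim_stage{stage.stage}",
        stage=stage.stage,
        lineage="sim",
    )
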