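"""Fused simulation kernel.

Implements exactly the per-step math of the public operations in
``model`` (field update, force quadrature, axis-decomposed pole step) as
one compiled loop. Equivalence with the per-operation reference path is
asserted in the test suite. Falls back to the reference loop when numba
is unavailable.
"""

from __future__ import annotations

import numpy as np

from .errors import SimulationError, StabilityError

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def _run(pts, radius, d0, lam, n_t, v_g, r_mot, kappa, f_w, eta, nu, c_f, tau_c,
         t_end, dt, sample_every):
    """Returns (times, d_pp, d_cc, d_pc, n_samples, status, aux).

    status 0 ok; 1 stability violated (aux = dt*(Omega1+Omega2+kappa));
    2 pole escaped (aux = time); 3 poles coincide (aux = time).
    f_w is the per-patch force weight M*f0*dA/A.
    """
    n = pts.shape[0]
    x1 = np.array([0.0, 0.0, d0 / 2.0])
    x2 = np.array([0.0, 0.0, -d0 / 2.0])
    p1 = np.zeros(n)
    p2 = np.zeros(n)
    n_steps = int(round(t_end / dt))
    n_samp = int(np.floor(t_end / sample_every + 1e-9)) + 1
    times = np.empty(n_samp)
    d_pp = np.empty(n_samp)
    d_cc = np.empty(n_samp)
    d_pc = np.empty(n_samp)
    i_samp = 0
    next_sample = 0.0
    t = 0.0
    status = 0
    aux = 0.0
    for i in range(n_steps + 1):
        sx = x1[0] - x2[0]
        sy = x1[1] - x2[1]
        sz = x1[2] - x2[2]
        dpp = np.sqrt(sx * sx + sy * sy + sz * sz)
        if dpp <= 0.0:
            status = 3
            aux = t
            break
        shx = sx / dpp
        shy = sy / dpp
        shz = sz / dpp
        dc = c_f * (1.0 - np.exp(-t / tau_c))
        dc_rate = c_f / tau_c * np.exp(-t / tau_c)
        if i_samp < n_samp and t >= next_sample - 1e-9:
            times[i_samp] = t
            d_pp[i_samp] = dpp
            d_cc[i_samp] = dc
            d_pc[i_samp] = np.abs(dpp - dc) / 2.0
            i_samp += 1
            next_sample += sample_every
        if i == n_steps:
            break
        f1x = 0.0; f1y = 0.0; f1z = 0.0
        f2x = 0.0; f2y = 0.0; f2z = 0.0
        worst = 0.0
        for k in range(n):
            vx = pts[k, 0] - x1[0]
            vy = pts[k, 1] - x1[1]
            vz = pts[k, 2] - x1[2]
            d1 = np.sqrt(vx * vx + vy * vy + vz * vz)
            wx = pts[k, 0] - x2[0]
            wy = pts[k, 1] - x2[1]
            wz = pts[k, 2] - x2[2]
            d2 = np.sqrt(wx * wx + wy * wy + wz * wz)
            om1 = n_t * lam * (r_mot * r_mot / (4.0 * d1 * d1)) * np.exp(-lam * d1 / v_g)
            om2 = n_t * lam * (r_mot * r_mot / (4.0 * d2 * d2)) * np.exp(-lam * d2 / v_g)
            if om1 + om2 > worst:
                worst = om1 + om2
            free = 1.0 - p1[k] - p2[k]
            p1n = p1[k] + dt * (om1 * free - kappa * p1[k])
            p2n = p2[k] + dt * (om2 * free - kappa * p2[k])
            p1[k] = p1n
            p2[k] = p2n
            f1x += p1n * vx / d1
            f1y += p1n * vy / d1
            f1z += p1n * vz / d1
            f2x += p2n * wx / d2
            f2y += p2n * wy / d2
            f2z += p2n * wz / d2
        if dt * (worst + kappa) >= 1.0:
            status = 1
            aux = dt * (worst + kappa)
            break
        f1x *= f_w; f1y *= f_w; f1z *= f_w
        f2x *= f_w; f2y *= f_w; f2z *= f_w
        # pole 1: along-axis solve with chromosome coupling, free perpendicular
        fp = f1x * shx + f1y * shy + f1z * shz
        vp = (fp + nu * (dc_rate / 2.0)) / (eta + nu)
        x1[0] += dt * (vp * shx + (f1x - fp * shx) / eta)
        x1[1] += dt * (vp * shy + (f1y - fp * shy) / eta)
        x1[2] += dt * (vp * shz + (f1z - fp * shz) / eta)
        fp = f2x * shx + f2y * shy + f2z * shz
        vp = (fp + nu * (-dc_rate / 2.0)) / (eta + nu)
        x2[0] += dt * (vp * shx + (f2x - fp * shx) / eta)
        x2[1] += dt * (vp * shy + (f2y - fp * shy) / eta)
        x2[2] += dt * (vp * shz + (f2z - fp * shz) / eta)
        if (x1[0] ** 2 + x1[1] ** 2 + x1[2] ** 2 >= radius * radius
                or x2[0] ** 2 + x2[1] ** 2 + x2[2] ** 2 >= radius * radius):
            status = 2
            aux = t + dt
            break
        t += dt
    return times, d_pp, d_cc, d_pc, i_samp, status, aux


def run_simulation(mesh, stage, mt, motors, drags, law, t_end, dt, sample_every):
    """Run the fused kernel; raise the same exceptions as the reference path."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    uniform = np.allclose(mesh.patch_areas, mesh.patch_areas[0], rtol=1e-12)
    if not _HAVE_NUMBA or not uniform:  # kernel assumes equal-area patches
        from .model import _reference_run

        return _reference_run(stage, mt, motors, drags, law, t_end, dt, sample_every, mesh)
    m = motors.count(mesh.radius)
    f_w = m * motors.force * float(mesh.patch_areas[0]) / mesh.area
    out = _run(
        np.ascontiguousarray(mesh.patch_centers),
        mesh.radius,
        stage.initial_d_pp,
        mt.catastrophe_rate,
        mt.n_per_aster,
        mt.growth_velocity,
        motors.size,
        motors.unbinding_rate,
        f_w,
        drags.pole_drag,
        drags.coupling,
        law.final_separation,
        law.time_constant,
        float(t_end),
        float(dt),
        float(sample_every),
    )
    times, d_pp, d_cc, d_pc, n_samp, status, aux = out
    if status == 1:
        raise StabilityError(
            f"dt={dt} violates the stability condition dt*(Omega+kappa) < 1 "
            f"(dt*worst={aux:.3f}); reduce dt"
        )
    if status == 2:
        raise SimulationError(f"pole escaped the cell at t={aux:.2f} s (parameter pathology)")
    if status == 3:
        raise SimulationError(f"poles coincide at t={aux:.2f} s: spindle axis undefined")
    return times[:n_samp], d_pp[:n_samp], d_cc[:n_samp], d_pc[:n_samp]
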