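"""Unit and property tests of the stoichiometric spindle model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spindlescale as ss
from spindlescale.errors import SimulationError, StabilityError
from spindlescale.mesh import build_cell_mesh
from spindlescale.model import (
    MotorField,
    SpindleState,
    _reference_run,
    cortical_force,
    evolve_motor_field,
    impingement_rate,
    imposed_separation,
    simulate_spindle,
    step_state,
)
from spindlescale.params import (
    DEFAULT_DRAGS,
    DEFAULT_LAW,
    DEFAULT_MOTORS,
    STAGE_TABLE,
    ChromosomeLaw,
    DragParams,
    MTParams,
    MotorParams,
    StageConfig,
)

MT_2CELL = MTParams(catastrophe_rate=0.038)


class TestImpingementRate:
    def test_closed_form_value(self):
        # N_T=5000, lambda=0.038, V_g=1, r=1.5 at d=10:
        # 5000*0.038 * (2.25/400) * exp(-0.38) = 0.730877...
        om = impingement_rate(10.0, MT_2CELL, DEFAULT_MOTORS)
        assert om == pytest.approx(0.730877, abs=1e-5)

    def test_decays_to_zero_monotonically(self):
        d = np.linspace(1.0, 200.0, 500)
        om = impingement_rate(d, MT_2CELL, DEFAULT_MOTORS)
        assert np.all(np.diff(om) < 0)
        assert om[-1] < 1e-4

    def test_higher_catastrophe_rate_reduces_rate_at_long_range(self):
        # at d*lambda/V_g >> 1 the survival factor dominates the prefactor
        d = 100.0
        lo = impingement_rate(d, MTParams(catastrophe_rate=0.1), DEFAULT_MOTORS)
        hi = impingement_rate(d, MTParams(catastrophe_rate=0.2), DEFAULT_MOTORS)
        assert hi < lo

    def test_pole_on_cortex_rejected(self):
        with pytest.raises(ValueError):
            impingement_rate(0.0, MT_2CELL, DEFAULT_MOTORS)

    @given(
        d1=st.floats(1.0, 50.0),
        factor=st.floats(1.01, 5.0),
        lam=st.floats(0.01, 2.0),
    )
    def test_strictly_decreasing_in_distance(self, d1, factor, lam):
        mt = MTParams(catastrophe_rate=lam)
        assert impingement_rate(d1 * factor, mt, DEFAULT_MOTORS) < impingement_rate(
            d1, mt, DEFAULT_MOTORS
        )


def _state_on_axis(d_pp, t=0.0, sep=0.0):
    half = d_pp / 2
    mid = np.zeros(3)
    return SpindleState(
        t=t,
        x1=np.array([0, 0, half]),
        x2=np.array([0, 0, -half]),
        c1=mid + np.array([0, 0, sep / 2]),
        c2=mid - np.array([0, 0, sep / 2]),
    )


class TestMotorField:
    def test_pure_unbinding_decay(self):
        """With zero impingement the field decays as exp(-kappa t)."""
        mesh = build_cell_mesh(1000.0, 256)  # huge cell: Omega ~ 0
        state = _state_on_axis(1.0)
        mt = MTParams(n_per_aster=1e-9, catastrophe_rate=1.0)
        field = MotorField(np.full(256, 0.5), np.zeros(256))
        dt, n_steps = 0.1, 100
        for _ in range(n_steps):
            field = evolve_motor_field(field, mesh, state, mt, DEFAULT_MOTORS, dt)
        kappa = DEFAULT_MOTORS.unbinding_rate
        expected = 0.5 * (1 - dt * kappa) ** n_steps  # explicit-update decay
        assert np.allclose(field.p1, expected, rtol=1e-9)
        assert np.allclose(expected, 0.5 * np.exp(-kappa * dt * n_steps), rtol=3e-3)

    def test_single_aster_steady_state(self):
        """Fixed point P* = Omega / (Omega + kappa) ~ 0.936 for Omega=0.731."""
        mesh = build_cell_mesh(11.5, 256)
        # pole placed 10 um from every patch is impossible on a sphere, so
        # check the fixed point patch-wise after long evolution
        state = SpindleState(
            t=0.0, x1=np.array([0, 0, 1.5]), x2=np.array([0, 0, -1.5]),
            c1=np.zeros(3), c2=np.zeros(3),
        )
        mt = MT_2CELL
        field = MotorField.zeros(256)
        for _ in range(4000):
            field = evolve_motor_field(field, mesh, state, mt, DEFAULT_MOTORS, 0.05)
        d1 = np.linalg.norm(mesh.patch_centers - state.x1, axis=1)
        d2 = np.linalg.norm(mesh.patch_centers - state.x2, axis=1)
        om1 = impingement_rate(d1, mt, DEFAULT_MOTORS)
        om2 = impingement_rate(d2, mt, DEFAULT_MOTORS)
        kappa = DEFAULT_MOTORS.unbinding_rate
        expected_p1 = om1 / (om1 + om2 + kappa)
        assert np.allclose(field.p1, expected_p1, atol=1e-6)

    def test_symmetric_two_aster_fixed_point_value(self):
        # scalar check of the symmetric fixed point P1 = P2 = Om/(2 Om + kappa)
        om, kappa = 0.731, 0.05
        p = om / (om + om + kappa)
        # one explicit step from the fixed point must not move
        p_next = p + 0.01 * (om * (1 - 2 * p) - kappa * p)
        assert p_next == pytest.approx(p, abs=1e-12)
        assert om / (om + kappa) == pytest.approx(0.93598, abs=1e-4)

    def test_stability_guard_names_dt(self):
        mesh = build_cell_mesh(5.0, 256)
        state = _state_on_axis(9.0)  # poles 0.5 um from the cortex
        field = MotorField.zeros(256)
        with pytest.raises(StabilityError, match="dt=1.0"):
            evolve_motor_field(field, mesh, state, MTParams(catastrophe_rate=1.0),
                               DEFAULT_MOTORS, 1.0)

    def test_bounds_preserved_throughout_simulation(self):
        """0 <= P1, P2 and P1+P2 <= 1 at every patch of every step."""
        mesh = build_cell_mesh(14.0, 256)
        state = _state_on_axis(9.0)
        mt = MTParams(catastrophe_rate=0.164)
        field = MotorField.zeros(256)
        for _ in range(500):
            field = evolve_motor_field(field, mesh, state, mt, DEFAULT_MOTORS, 0.05)
            total = field.p1 + field.p2
            assert np.all(field.p1 >= 0) and np.all(field.p2 >= 0)
            assert np.all(total <= 1.0 + 1e-12)


class TestCorticalForce:
    def test_uniform_field_centered_pole_is_force_free(self):
        mesh = build_cell_mesh(10.0, 2000)
        field = MotorField(np.full(mesh.n_patches, 0.4), np.zeros(mesh.n_patches))
        f = cortical_force(field, mesh, np.zeros(3), 1, DEFAULT_MOTORS)
        m = DEFAULT_MOTORS.count(10.0)
        assert np.linalg.norm(f) < 1e-6 * m * DEFAULT_MOTORS.force

    def test_single_patch_force_exact(self):
        mesh = build_cell_mesh(10.0, 256)
        p1 = np.zeros(mesh.n_patches)
        p1[17] = 1.0
        field = MotorField(p1, np.zeros_like(p1))
        pole = np.array([1.0, -2.0, 0.5])
        f = cortical_force(field, mesh, pole, 1, DEFAULT_MOTORS)
        m = DEFAULT_MOTORS.count(10.0)
        xi = mesh.patch_centers[17] - pole
        xi /= np.linalg.norm(xi)
        expected = (m * DEFAULT_MOTORS.force / mesh.area) * mesh.patch_areas[17] * xi
        assert np.allclose(f, expected, rtol=1e-12)

    def test_uniform_field_displaced_pole_is_centred(self):
        """Uniformly engaged cortex restores a displaced pole toward the
        centre: unit-vector pulls weighted by area favour the far
        hemisphere, which has the larger area beyond the pole's equatorial
        plane (checked against a Monte-Carlo surface integral)."""
        mesh = build_cell_mesh(10.0, 4000)
        field = MotorField(np.full(mesh.n_patches, 0.4), np.zeros(mesh.n_patches))
        f = cortical_force(field, mesh, np.array([0.0, 0.0, 5.0]), 1, DEFAULT_MOTORS)
        assert f[2] < 0
        # brute-force oracle: mean unit-vector z over the sphere is -0.334
        m = DEFAULT_MOTORS.count(10.0)
        mean_unit_z = f[2] / (m * DEFAULT_MOTORS.force * 0.4)
        assert mean_unit_z == pytest.approx(-0.334, abs=2e-3)
        assert abs(f[0]) < 1e-3 * abs(f[2]) and abs(f[1]) < 1e-3 * abs(f[2])

    def test_pole_outside_sphere_rejected(self):
        mesh = build_cell_mesh(10.0, 256)
        field = MotorField.zeros(mesh.n_patches)
        with pytest.raises(SimulationError):
            cortical_force(field, mesh, np.array([0.0, 0.0, 10.5]), 1, DEFAULT_MOTORS)


class TestImposedSeparation:
    def test_zero_at_onset_and_plateau(self):
        assert imposed_separation(0.0) == 0.0
        assert imposed_separation(1e6) == pytest.approx(6.2, abs=1e-9)

    def test_one_time_constant(self):
        assert imposed_separation(29.0) == pytest.approx(6.2 * (1 - np.exp(-1)), abs=1e-9)
        assert imposed_separation(29.0) == pytest.approx(3.92, abs=0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            imposed_separation(-1.0)

    def test_monotone_and_bounded(self):
        t = np.linspace(0, 600, 400)
        sep = imposed_separation(t)
        assert np.all(np.diff(sep) >= 0)
        assert np.all(sep <= 6.2)


class TestStepState:
    def test_nu_zero_reduces_to_force_over_drag(self):
        """With nu=0 a single step is exactly dx = F/eta dt."""
        state = _state_on_axis(10.0)
        drags = DragParams(pole_drag=450.0, coupling=0.0)
        law = ChromosomeLaw(final_separation=1e-12, time_constant=1.0)  # frozen chromosomes
        f1 = np.array([0.0, 0.0, 45.0])
        dt = 0.2
        new = step_state(state, f1, np.zeros(3), drags, law, dt)
        assert np.allclose((new.x1 - state.x1) / dt, [0, 0, 0.1], atol=1e-15)
        assert np.allclose(new.x2, state.x2, atol=1e-15)

    def test_chromosome_drag_pulls_poles(self):
        # F=0, c_dot_par = 0.1 um/s, eta=450, nu=50 -> pole velocity 0.01 um/s
        law = ChromosomeLaw(final_separation=0.2 * 29.0, time_constant=29.0)  # rate(0) = 0.2
        assert law.rate(0.0) == pytest.approx(0.2)
        state = _state_on_axis(10.0)
        drags = DragParams(pole_drag=450.0, coupling=50.0)
        dt = 0.1
        new = step_state(state, np.zeros(3), np.zeros(3), drags, law, dt)
        v1 = (new.x1 - state.x1) / dt
        assert v1[2] == pytest.approx(50 * 0.1 / 500, rel=1e-12)
        v2 = (new.x2 - state.x2) / dt
        assert v2[2] == pytest.approx(-50 * 0.1 / 500, rel=1e-12)

    def test_perpendicular_force_independent_of_nu(self):
        state = _state_on_axis(10.0)
        f_perp = np.array([9.0, 0.0, 0.0])
        law = ChromosomeLaw(final_separation=1e-12, time_constant=1.0)
        for nu in (0.0, 50.0, 500.0):
            new = step_state(state, f_perp, np.zeros(3), DragParams(450.0, nu), law, 0.1)
            v = (new.x1 - state.x1) / 0.1
            assert v[0] == pytest.approx(9.0 / 450.0, rel=1e-12)

    def test_coincident_poles_rejected(self):
        with pytest.raises(SimulationError):
            SpindleState(t=0.0, x1=np.ones(3), x2=np.ones(3), c1=np.zeros(3), c2=np.zeros(3))


class TestSimulateSpindle:
    def test_two_cell_starts_at_initial_separation(self):
        traj = simulate_spindle(STAGE_TABLE[2], n_patches=256, t_end=20.6)
        assert traj.d_pp[0] == pytest.approx(13.0, abs=1e-12)
        assert traj.d_cc[0] == 0.0

    def test_chromosome_trace_is_imposed_law(self, stage8_trajectory):
        expected = DEFAULT_LAW.separation(stage8_trajectory.times)
        assert np.allclose(stage8_trajectory.d_cc, expected, atol=1e-9)

    def test_kernel_matches_reference_path(self):
        stage = STAGE_TABLE[64]
        kw = dict(n_patches=256, t_end=30.0, dt=0.02)
        ref = simulate_spindle(stage, engine="reference", **kw)
        fast = simulate_spindle(stage, engine="fast", **kw)
        assert np.allclose(ref.d_pp, fast.d_pp, rtol=1e-12, atol=1e-12)
        assert np.allclose(ref.d_pc, fast.d_pc, rtol=1e-12, atol=1e-12)

    def test_time_step_convergence(self):
        """Halving dt changes final D_P-P by far less than 0.5%."""
        stage = STAGE_TABLE[8]
        a = simulate_spindle(stage, n_patches=512, dt=0.02)
        b = simulate_spindle(stage, n_patches=512, dt=0.01)
        assert abs(a.d_pp[-1] - b.d_pp[-1]) < 0.005 * b.d_pp[-1]

    def test_mesh_convergence(self):
        """Doubling the mesh changes final D_P-P by < 1% (8-cell config)."""
        stage = STAGE_TABLE[8]
        a = simulate_spindle(stage, n_patches=512, dt=0.01)
        b = simulate_spindle(stage, n_patches=1024, dt=0.01)
        assert abs(a.d_pp[-1] - b.d_pp[-1]) < 0.01 * b.d_pp[-1]

    def test_catastrophe_rate_effect_is_monotone_at_fixed_geometry(self):
        """At fixed cell radius the equilibrium length is monotone in lambda.

        Because nucleation is tied to the catastrophe rate (n_dot =
        N_T * lambda), raising lambda strengthens and localises cortical
        engagement near each pole, so the final length *increases* with
        lambda at fixed R (verified against the quasi-static force-balance
        oracle); the across-stage shrinkage comes from the cell radius
        falling jointly with lambda rising.
        """
        finals = []
        for lam in (0.04, 0.08, 0.164, 0.33):
            traj = simulate_spindle(
                STAGE_TABLE[8], mt=MTParams(catastrophe_rate=lam), n_patches=256, dt=0.005
            )
            finals.append(traj.d_pp[-1])
        assert np.all(np.diff(finals) > 0)
        # quasi-static equilibria at the grid ends (independent oracle)
        assert finals[0] == pytest.approx(10.25, abs=0.1)
        assert finals[-1] == pytest.approx(19.03, abs=0.1)

    def test_mirror_symmetry_of_pole_pair(self):
        """Symmetric initial conditions keep the pole pair centred."""
        stage = STAGE_TABLE[8]
        mesh = build_cell_mesh(stage.cell_radius, 256)
        mt = MTParams(catastrophe_rate=stage.catastrophe_rate)
        half = stage.initial_d_pp / 2
        state = SpindleState(
            t=0.0, x1=np.array([0, 0, half]), x2=np.array([0, 0, -half]),
            c1=np.zeros(3), c2=np.zeros(3),
        )
        field = MotorField.zeros(256)
        for _ in range(500):  # 25 s of dynamics
            field = evolve_motor_field(field, mesh, state, mt, DEFAULT_MOTORS, 0.05)
            f1 = cortical_force(field, mesh, state.x1, 1, DEFAULT_MOTORS)
            f2 = cortical_force(field, mesh, state.x2, 2, DEFAULT_MOTORS)
            state = step_state(state, f1, f2, DEFAULT_DRAGS, DEFAULT_LAW, 0.05)
            assert np.linalg.norm(state.x1 + state.x2) < 1e-6 * stage.cell_radius

    def test_unset_catastrophe_rate_rejected(self):
        stage = StageConfig(8, 14.0, 9.0, None)
        with pytest.raises(ValueError, match="catastrophe_rate"):
            simulate_spindle(stage, n_patches=256, t_end=10)
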