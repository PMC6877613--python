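import numpy as np
import pytest

from chemoflow.chemo_pathway import PathwayParams
from chemoflow.rod_dynamics import (
    SimState,
    Simulation,
    SimulationConfig,
    area_fraction,
    default_rotational_diffusion,
    find_contacts,
    run_simulation,
    steric_forces,
)
from chemoflow.synthetic_data import GradientSpec


def quiet_pathway():
    return PathwayParams(lambda0=1e-9)


def make_state(pos, theta, v=20.0, box=64.0):
    n = len(theta)
    return SimState(pos=np.asarray(pos, dtype=float),
                    unwrapped_x=np.asarray(pos, dtype=float)[:, 0].copy(),
                    theta=np.asarray(theta, dtype=float),
                    v_i=np.full(n, v), Theta=np.ones(n, dtype=np.int8),
                    t_state=np.zeros(n), m=np.full(n, 4.0))


def brute_force_segment_distance(c1, u1, c2, u2, half, n_samples=4001):
    """Oracle: dense point sampling on both segments."""
    s = np.linspace(-half, half, n_samples)
    p1 = c1[None] + s[:, None] * u1[None]
    p2 = c2[None] + s[:, None] * u2[None]
    d = np.linalg.norm(p1[:, None] - p2[None], axis=2)
    return d.min()


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(L=0.5, e=1.0, n_rods=1)
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.05, v0_mean=20.0, n_rods=1)
        with pytest.raises(ValueError):
            SimulationConfig(n_rods=5, phi=0.1)
        with pytest.raises(ValueError):
            SimulationConfig(phi=0.7)

    def test_friction_relations(self):
        cfg = SimulationConfig(n_rods=1)
        fr = cfg.friction()
        assert fr.gamma_par == pytest.approx(
            2 * np.pi * cfg.eta * cfg.L / np.log(cfg.L / cfg.e))
        assert fr.gamma_perp == pytest.approx(2 * fr.gamma_par)
        assert fr.gamma_rot == pytest.approx(fr.gamma_par * cfg.L**2 / 6)

    def test_dipole_length(self):
        assert SimulationConfig(n_rods=1, L=2.0).L_dip == pytest.approx(6.0)
        assert SimulationConfig(n_rods=1, L=4.0).L_dip == pytest.approx(7.0)

    def test_rotational_diffusion_defaults(self):
        assert SimulationConfig(n_rods=1, L=2.0).D_r == pytest.approx(0.057)
        assert SimulationConfig(n_rods=1, L=4.0).D_r == pytest.approx(
            0.01425, rel=1e-6)
        assert default_rotational_diffusion(4.0) < \
            default_rotational_diffusion(2.0)


class TestAreaFraction:
    def test_zero_rods(self):
        cfg = SimulationConfig(box_side=256.0, n_rods=0,
                               pathway=quiet_pathway())
        st = make_state(np.zeros((0, 2)), np.zeros(0))
        assert area_fraction(st, cfg) == 0.0

    def test_single_rod_worked_value(self):
        cfg = SimulationConfig(box_side=256.0, n_rods=1, L=2.0, e=1.0)
        st = make_state([[1.0, 1.0]], [0.0])
        assert area_fraction(st, cfg) == pytest.approx(
            (1 + np.pi / 4) / 65536, rel=1e-12)
        assert area_fraction(st, cfg) == pytest.approx(2.725e-5, rel=1e-3)

    def test_linear_in_n(self):
        cfg = SimulationConfig(box_side=128.0, n_rods=10)
        st1 = make_state(np.random.rand(10, 2) * 100, np.zeros(10))
        st2 = make_state(np.random.rand(20, 2) * 100, np.zeros(20))
        assert area_fraction(st2, cfg) == pytest.approx(
            2 * area_fraction(st1, cfg))


class TestContacts:
    def setup_method(self):
        self.cfg = SimulationConfig(box_side=64.0, n_rods=2, L=2.0, e=1.0,
                                    hydrodynamics_on=False)

    def test_distant_rods_no_contact(self):
        st = make_state([[10.0, 10.0], [20.0, 10.0]], [0.0, 0.0])
        assert find_contacts(st, self.cfg) == []

    def test_parallel_rods_perpendicular_offset(self):
        # side-by-side rods, centre separation 0.8 across their axes
        st = make_state([[10.0, 10.0], [10.0, 10.8]], [0.0, 0.0])
        contacts = find_contacts(st, self.cfg)
        assert len(contacts) == 1
        assert contacts[0].delta == pytest.approx(0.2, rel=1e-9)
        # oracle: dense sampling of both segments
        d = brute_force_segment_distance(
            np.array([10.0, 10.0]), np.array([1.0, 0.0]),
            np.array([10.0, 10.8]), np.array([1.0, 0.0]), 0.5)
        assert contacts[0].delta == pytest.approx(1.0 - d, abs=1e-6)

    def test_oblique_configuration_against_oracle(self, rng):
        cfg = self.cfg
        for _ in range(25):
            c1 = np.array([20.0, 20.0])
            c2 = c1 + rng.uniform(-2, 2, 2)
            th = rng.uniform(-np.pi, np.pi, 2)
            st = make_state([c1, c2], th)
            contacts = find_contacts(st, cfg)
            d = brute_force_segment_distance(
                c1, np.array([np.cos(th[0]), np.sin(th[0])]),
                c2, np.array([np.cos(th[1]), np.sin(th[1])]), 0.5)
            if d < 1.0 - 1e-4:
                assert len(contacts) == 1
                assert contacts[0].delta == pytest.approx(1.0 - d, abs=1e-4)
            elif d > 1.0 + 1e-4:
                assert contacts == []

    def test_contact_through_periodic_boundary(self):
        st = make_state([[0.2, 10.0], [63.9, 10.0]], [0.0, 0.0])
        assert len(find_contacts(st, self.cfg)) == 1

    def test_contact_geometry_invariants(self):
        st = make_state([[10.0, 10.0], [10.5, 10.6]], [0.3, -0.8])
        for c in find_contacts(st, self.cfg):
            assert c.delta >= 0
            assert np.linalg.norm(c.u_ij) == pytest.approx(1.0)
            assert np.linalg.norm(c.v_ij) == pytest.approx(1.0)
            assert np.dot(c.u_ij, c.v_ij) == pytest.approx(0.0, abs=1e-12)


class TestStericForces:
    def setup_method(self):
        self.cfg = SimulationConfig(box_side=64.0, n_rods=2, L=2.0, e=1.0,
                                    K_el=200.0, hydrodynamics_on=False)

    def test_no_overlap_no_force(self):
        st = make_state([[10.0, 10.0], [30.0, 30.0]], [0.0, 1.0])
        f, tq = steric_forces([], st, self.cfg)
        assert np.allclose(f, 0) and np.allclose(tq, 0)

    def test_elastic_magnitude_worked_value(self):
        # delta = 0.1 -> |F_el| = 200 * 0.1^1.5 = 6.325 pN
        st = make_state([[10.0, 10.0], [10.0, 10.9]], [0.0, 0.0])
        st.vel[:] = 0.0
        st.vel_free[:] = 0.0
        contacts = find_contacts(st, self.cfg)
        f, tq = steric_forces(contacts, st, self.cfg)
        assert np.linalg.norm(f[0]) == pytest.approx(200 * 0.1**1.5,
                                                     rel=1e-9)
        assert np.linalg.norm(f[0]) == pytest.approx(6.325, abs=1e-3)

    def test_newtons_third_law(self, rng):
        cfg = self.cfg
        for _ in range(10):
            c2 = np.array([10.0, 10.0]) + rng.uniform(-1.5, 1.5, 2)
            st = make_state([[10.0, 10.0], c2],
                            rng.uniform(-np.pi, np.pi, 2))
            st.vel = rng.normal(size=(2, 2)) * 10
            st.vel_free = st.vel.copy()
            contacts = find_contacts(st, cfg)
            f, tq = steric_forces(contacts, st, cfg)
            assert np.allclose(f[0] + f[1], 0, atol=1e-12)

    def test_friction_opposes_tangential_sliding(self):
        st = make_state([[10.0, 10.0], [10.0, 10.8]], [0.0, 0.0])
        st.vel[0] = [5.0, 0.0]
        st.vel[1] = [-5.0, 0.0]
        st.vel_free = st.vel.copy()
        contacts = find_contacts(st, self.cfg)
        f, _ = steric_forces(contacts, st, self.cfg)
        assert f[0, 0] < 0  # decelerates rod 0 along +x
        assert f[1, 0] > 0


class TestStep:
    def test_ballistic_motion_exact(self):
        cfg = SimulationConfig(box_side=64.0, n_rods=1, D_r=1e-30, D_T=0.0,
                               t_total=4.0, v0_std=1e-12, dt=0.01,
                               hydrodynamics_on=False, steric_on=False,
                               pathway=quiet_pathway(), seed=2)
        traj = run_simulation(cfg)
        th = traj.theta[0, 0]
        v = traj.v_i[0]
        expected = traj.unwrapped_x[0, 0] + v * np.cos(th) * traj.times
        assert np.allclose(traj.unwrapped_x[:, 0], expected, rtol=1e-12)

    def test_rotational_diffusion_variance(self):
        cfg = SimulationConfig(box_side=64.0, n_rods=1200, D_r=0.2,
                               t_total=4.0, dt=0.01, hydrodynamics_on=False,
                               steric_on=False, pathway=quiet_pathway(),
                               seed=3)
        traj = run_simulation(cfg)
        dth = np.diff(traj.theta, axis=0)
        dth = np.mod(dth + np.pi, 2 * np.pi) - np.pi
        var = np.cumsum(dth, axis=0)[-1].var()
        assert var == pytest.approx(2 * 0.2 * 4.0, rel=0.08)

    def test_two_rod_flow_displacement_matches_kernel(self):
        """Oracle: direct dipole-flow evaluation at rod B's two points."""
        from chemoflow.hydrodynamics import ForceDipole, dipole_flow
        cfg = SimulationConfig(box_side=256.0, n_rods=2, D_r=1e-30, D_T=0.0,
                               dt=0.001, t_total=0.1, v0_std=1e-12,
                               hydrodynamics_on=True, flow_method="pairwise",
                               steric_on=False, pathway=quiet_pathway(),
                               seed=0)
        sim = Simulation(cfg)
        st = make_state([[100.0, 100.0], [120.0, 110.0]], [0.0, np.pi / 2],
                        box=256.0)
        st.v_i[:] = 20.0
        sim._last_activity = np.zeros(2)
        x_b0 = st.pos[1].copy()
        n_b = np.array([np.cos(st.theta[1]), np.sin(st.theta[1])])
        fr = cfg.friction()
        medium = cfg.medium()
        dip_a = ForceDipole(
            F_vector=fr.gamma_par * 20.0 * np.array([1.0, 0.0]),
            application_point=st.pos[0].copy(), L_dip=cfg.L_dip,
            n=np.array([1.0, 0.0]))
        w1 = dipole_flow(dip_a, x_b0, medium)
        w2 = dipole_flow(dip_a, x_b0 - cfg.L_dip * n_b, medium)
        expected = st.pos[1] + (20.0 * n_b + 0.5 * (w1 + w2)) * cfg.dt
        sim.step(st)
        assert np.allclose(st.pos[1], expected, atol=1e-9)

    def test_momentum_conservation_steric_only(self, rng):
        cfg = SimulationConfig(box_side=32.0, n_rods=40, D_r=1e-30, D_T=0.0,
                               dt=0.002, t_total=0.1, hydrodynamics_on=False,
                               pathway=quiet_pathway(), seed=5)
        sim = Simulation(cfg)
        st = sim.initial_state()
        sim._last_activity = np.zeros(st.n)
        # contact forces alone must cancel pairwise each step
        from chemoflow._rod_kernels import (find_contacts_kernel,
                                            steric_forces_kernel)
        for _ in range(20):
            sim.step(st)
            ux, uy = np.cos(st.theta), np.sin(st.theta)
            cnt = find_contacts_kernel(st.pos, ux, uy, cfg.box_side,
                                       (cfg.L - cfg.e) / 2, cfg.e)
            f, _ = steric_forces_kernel(*cnt, st.vel_free, ux, uy,
                                        cfg.K_el, cfg.K_fr)
            assert np.abs(f.sum(axis=0)).max() <= 1e-10 * max(
                np.abs(f).max(), 1e-30)


class TestRunSimulation:
    def test_bit_reproducible(self):
        cfg = SimulationConfig(box_side=48.0, phi=0.05, t_total=1.0, dt=0.005,
                               K_el=50.0, seed=11, flow_method="pairwise",
                               gradient=GradientSpec())
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.methylation, b.methylation)

    def test_run_durations_exponential(self):
        cfg = SimulationConfig(box_side=64.0, n_rods=250, t_total=30.0,
                               dt=0.01, save_interval=0.01,
                               hydrodynamics_on=False, steric_on=False,
                               seed=7)
        traj = run_simulation(cfg)
        m = traj.motor_state
        durations = []
        for i in range(m.shape[1]):
            runs = m[:, i]
            edges = np.flatnonzero(np.diff(runs.astype(int)))
            if len(edges) < 2:
                continue
            starts = edges[runs[edges] == 0]  # tumble -> run transitions
            ends = edges[runs[edges] == 1]    # run -> tumble transitions
            for s in starts:
                later = ends[ends > s]
                if len(later):
                    durations.append((later[0] - s) * 0.01)
        durations = np.array(durations)
        assert len(durations) > 3_000
        assert durations.mean() == pytest.approx(1.0, rel=0.10)
        # exponential shape: std ~ mean
        assert durations.std() == pytest.approx(durations.mean(), rel=0.15)

    def test_dilute_gradient_drift_positive(self):
        cfg = SimulationConfig(box_side=96.0, n_rods=200, t_total=30.0,
                               dt=0.01, hydrodynamics_on=False,
                               steric_on=False, gradient=GradientSpec(),
                               seed=13)
        traj = run_simulation(cfg)
        drift = (traj.unwrapped_x[-1] - traj.unwrapped_x[40]).mean() \
            / (traj.times[-1] - traj.times[40])
        assert drift > 0.5  # um/s, clearly positive

    def test_save_layout_and_hdf5_roundtrip(self, tmp_path):
        cfg = SimulationConfig(box_side=48.0, phi=0.03, t_total=1.0, dt=0.005,
                               K_el=50.0, seed=1, gradient=GradientSpec())
        traj = run_simulation(cfg)
        T, n = traj.theta.shape
        assert traj.positions.shape == (T, n, 2)
        assert np.all(np.diff(traj.times) > 0)
        assert np.all((traj.positions >= 0) & (traj.positions < 48.0))
        path = tmp_path / "traj.h5"
        traj.save_hdf5(path)
        back = traj.load_hdf5(path)
        assert np.allclose(back.unwrapped_x, traj.unwrapped_x)
        assert back.config.seed == cfg.seed
        assert back.config.gradient.c_right == 200.0
        df = traj.summary_frame()
        assert len(df) == T
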