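"""Agent-based 2D simulator of self-propelled chemotactic rods.

Rods are 2D spherocylinders in a periodic box, self-propelled along their
axis, interacting through Hertzian repulsion + tangential contact friction
and (optionally) through the quasi-2D screened hydrodynamic flow of their
pusher force dipoles.  Orientation dynamics combine rotational Brownian
motion, random tumble torques gated by the internal chemotaxis pathway, and
reorientation by the local flow gradient sampled at the two dipole points.
The equations of motion are integrated with an explicit Euler scheme; a
step whose largest displacement exceeds half a rod width is rejected and
re-run at half the time step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from . import chemo_pathway as cp
from ._rod_kernels import (
    find_contacts_kernel,
    pairwise_flows_kernel,
    steric_forces_kernel,
)
from .hydrodynamics import HeleShawMedium, KernelTable, SpectralFlowSolver
from .synthetic_data import GradientSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "FrictionSet",
    "RodState",
    "ContactInfo",
    "Trajectories",
    "find_contacts",
    "steric_forces",
    "step",
    "run_simulation",
    "area_fraction",
]


def default_rotational_diffusion(L: float, e: float = 1.0) -> float:
    """Slender-body scaling D_r ~ ln(L/e)/L^3, pinned to 0.057 at L = 2."""
    return 0.057 * (2.0 / L) ** 3 * np.log(L / e) / np.log(2.0)


@dataclass(frozen=True)
class FrictionSet:
    """Rod friction coefficients (pN s/um and pN s um)."""

    gamma_par: float
    gamma_perp: float
    gamma_rot: float

    @classmethod
    def from_geometry(cls, L: float, e: float, eta: float) -> "FrictionSet":
        gpar = 2.0 * np.pi * eta * L / np.log(L / e)
        return cls(gamma_par=gpar, gamma_perp=2.0 * gpar,
                   gamma_rot=gpar * L**2 / 6.0)


@dataclass(frozen=True)
class SimulationConfig:
    """All physical and numerical parameters of one run.

    ``n_rods`` and ``phi`` are alternative ways to set the density; give
    exactly one.  ``D_r=None`` selects the slender-body default for the
    chosen rod length.
    """

    box_side: float = 256.0        # um
    h: float = 30.0                # channel height (um)
    L: float = 2.0                 # rod length (um)
    e: float = 1.0                 # rod width (um)
    L_flag: float = 10.0           # flagellar bundle length (um)
    eta: float = 1e-3              # Pa s
    K_el: float = 200.0            # pN um^-3/2
    K_fr: float = 0.01             # pN s/um
    v0_mean: float = 20.0          # um/s
    v0_std: float = 5.0            # um/s
    D_r: Optional[float] = None    # rad^2/s; None -> slender-body default
    D_T: float = 5.3               # tumble angular diffusion (rad^2/s)
    tau_t: float = 0.12            # tumble duration (s)
    dt: float = 0.01               # s
    t_total: float = 60.0          # s
    n_rods: Optional[int] = None
    phi: Optional[float] = None    # target area fraction
    hydrodynamics_on: bool = True
    steric_on: bool = True
    flow_method: str = "auto"      # "pairwise" | "spectral" | "auto"
    gradient: Optional[GradientSpec] = None
    pathway: cp.PathwayParams = field(default_factory=cp.PathwayParams)
    save_interval: float = 0.1     # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L <= self.e:
            raise ValueError("require rod length L > width e")
        for name in ("box_side", "h", "e", "eta", "K_el", "K_fr",
                     "v0_mean", "tau_t", "dt", "t_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt * self.v0_mean >= self.e / 2:
            raise ValueError("dt v0_mean must stay below e/2")
        if (self.n_rods is None) == (self.phi is None):
            raise ValueError("give exactly one of n_rods or phi")
        if self.phi is not None and not (0.0 <= self.phi <= 0.6):
            raise ValueError("phi must lie in [0, 0.6]")
        if self.D_r is None:
            object.__setattr__(
                self, "D_r", default_rotational_diffusion(self.L, self.e))
        if self.flow_method not in ("auto", "pairwise", "spectral"):
            raise ValueError("unknown flow method")

    # -- derived quantities ------------------------------------------------
    @property
    def rod_area(self) -> float:
        """Area of one 2D spherocylinder."""
        return (self.L - self.e) * self.e + np.pi * (self.e / 2) ** 2

    def resolved_n_rods(self) -> int:
        if self.n_rods is not None:
            return self.n_rods
        return int(round(self.phi * self.box_side**2 / self.rod_area))

    @property
    def L_dip(self) -> float:
        return self.L / 2.0 + self.L_flag / 2.0

    def friction(self) -> FrictionSet:
        return FrictionSet.from_geometry(self.L, self.e, self.eta)

    def medium(self) -> HeleShawMedium:
        cutoff = 6.0 / np.sqrt(12.0 / self.h**2)
        cutoff = min(cutoff, 0.49 * self.box_side)
        return HeleShawMedium(h=self.h, eta=self.eta,
                              r_clamp=self.e / 2.0, r_cutoff=cutoff)


@dataclass
class RodState:
    """Single-rod view, mostly for interactive poking; the simulator keeps
    the population in struct-of-arrays form (:class:`SimState`)."""

    position: np.ndarray
    unwrapped_x: float
    theta: float
    v_i: float
    Theta: int
    pathway: cp.PathwayState
    time_in_state: float = 0.0


@dataclass
class ContactInfo:
    """One rod-rod contact."""

    pair: tuple
    delta: float
    u_ij: np.ndarray    # contact normal, pointing from j to i
    v_ij: np.ndarray    # tangent (normal rotated +90 deg)
    contact_point: np.ndarray
    lever_i: float
    lever_j: float


class SimState:
    """Mutable population state (struct of arrays)."""

    def __init__(self, pos, unwrapped_x, theta, v_i, Theta, t_state, m,
                 vel=None):
        self.pos = pos
        self.unwrapped_x = unwrapped_x
        self.theta = theta
        self.v_i = v_i
        self.Theta = Theta
        self.t_state = t_state
        self.m = m
        self.vel = np.zeros_like(pos) if vel is None else vel
        # previous-step propulsion + advection velocity, the friction input;
        # excluding the contact-force response keeps the explicit contact
        # friction free of its runaway self-feedback (see module notes)
        self.vel_free = self.vel.copy()

    @property
    def n(self) -> int:
        return len(self.theta)


@dataclass
class Trajectories:
    """Uniformly sampled time series of a whole run."""

    times: np.ndarray          # (T,)
    positions: np.ndarray      # (T, n, 2) wrapped
    unwrapped_x: np.ndarray    # (T, n)
    theta: np.ndarray          # (T, n)
    motor_state: np.ndarray    # (T, n) 1 = run, 0 = tumble
    v_i: np.ndarray            # (n,) quenched intrinsic speeds
    velocity: np.ndarray       # (T, n, 2) full instantaneous velocities
    methylation: np.ndarray    # (T, n)
    activity: np.ndarray       # (T, n)
    config: SimulationConfig

    def __post_init__(self) -> None:
        T, n = self.theta.shape
        assert self.positions.shape == (T, n, 2)
        assert len(self.times) == T

    def save_hdf5(self, path) -> None:
        from .io import trajectories_to_hdf5
        trajectories_to_hdf5(self, path)

    @classmethod
    def load_hdf5(cls, path) -> "Trajectories":
        from .io import trajectories_from_hdf5
        return trajectories_from_hdf5(path)

    def summary_frame(self):
        """Per-time summary (mean speed, drift proxy, area fraction)."""
        import pandas as pd
        speed = np.linalg.norm(self.velocity, axis=2).mean(axis=1)
        return pd.DataFrame({
            "time": self.times,
            "mean_speed": speed,
            "mean_unwrapped_x": self.unwrapped_x.mean(axis=1),
            "area_fraction": np.full(len(self.times), area_fraction_config(
                self.theta.shape[1], self.config)),
        })


def area_fraction_config(n_rods: int, config: SimulationConfig) -> float:
    return n_rods * config.rod_area / config.box_side**2


def area_fraction(states: SimState, config: SimulationConfig) -> float:
    """Phi = n [ (L-e) e + pi (e/2)^2 ] / box^2."""
    return area_fraction_config(states.n, config)


# ---------------------------------------------------------------------------
# contacts and forces (public wrappers around the numba kernels)
# ---------------------------------------------------------------------------

def _axes(theta):
    return np.cos(theta), np.sin(theta)


def find_contacts(states: SimState, config: SimulationConfig) -> List[ContactInfo]:
    """Contacts between spherocylinders (minimal image convention)."""
    ux, uy = _axes(states.theta)
    seg_half = (config.L - config.e) / 2.0
    count, i_idx, j_idx, delta, unx, uny, li, lj = find_contacts_kernel(
        states.pos, ux, uy, config.box_side, seg_half, config.e)
    out = []
    for k in range(count):
        i = int(i_idx[k])
        normal = np.array([unx[k], uny[k]])
        ci = states.pos[i] + li[k] * np.array([ux[i], uy[i]])
        # contact point: midway between surface points along the normal
        cpoint = ci - normal * (config.e - delta[k]) / 2.0
        out.append(ContactInfo(
            pair=(i, int(j_idx[k])), delta=float(delta[k]),
            u_ij=normal, v_ij=np.array([-uny[k], unx[k]]),
            contact_point=cpoint % config.box_side,
            lever_i=float(li[k]), lever_j=float(lj[k])))
    return out


def steric_forces(contacts: List[ContactInfo], states: SimState,
                  config: SimulationConfig):
    """Per-rod contact force (pN) and torque (pN um) from a contact list."""
    count = len(contacts)
    i_idx = np.array([c.pair[0] for c in contacts], dtype=np.int64)
    j_idx = np.array([c.pair[1] for c in contacts], dtype=np.int64)
    delta = np.array([c.delta for c in contacts])
    unx = np.array([c.u_ij[0] for c in contacts])
    uny = np.array([c.u_ij[1] for c in contacts])
    li = np.array([c.lever_i for c in contacts])
    lj = np.array([c.lever_j for c in contacts])
    ux, uy = _axes(states.theta)
    return steric_forces_kernel(count, i_idx, j_idx, delta, unx, uny, li, lj,
                                states.vel, ux, uy, config.K_el, config.K_fr)


# ---------------------------------------------------------------------------
# the integrator
# ---------------------------------------------------------------------------

class Simulation:
    """Owns the per-run caches (kernel table / spectral solver / rng)."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.friction = config.friction()
        self.medium = config.medium()
        self._table = None
        self._solver = None
        n = config.resolved_n_rods()
        if config.hydrodynamics_on:
            method = config.flow_method
            if method == "auto":
                method = "spectral" if n > 256 else "pairwise"
            self.flow_method = method
            if method == "pairwise":
                self._table = KernelTable(self.medium)
            else:
                self._solver = SpectralFlowSolver(config.box_side, self.medium)
        else:
            self.flow_method = "off"
        self._rejected_steps = 0

    # -- initial condition -------------------------------------------------
    def initial_state(self) -> SimState:
        cfg = self.config
        n = cfg.resolved_n_rods()
        phi = n * cfg.rod_area / cfg.box_side**2
        if cfg.steric_on and phi > 0.45:
            raise ValueError("random sequential insertion works for phi <~ 0.3")
        rng = self.rng
        pos = np.empty((n, 2))
        theta = np.empty(n)
        seg_half = (cfg.L - cfg.e) / 2.0
        placed = 0
        attempts = 0
        max_attempts = 2000 * max(n, 1)
        while placed < n:
            if attempts > max_attempts:
                raise RuntimeError("insertion failed; density too high")
            attempts += 1
            p = rng.random(2) * cfg.box_side
            th = rng.random() * 2.0 * np.pi - np.pi
            if cfg.steric_on and placed > 0:
                trial_pos = np.concatenate([pos[:placed], p[None]], axis=0)
                trial_theta = np.concatenate([theta[:placed], [th]])
                ux, uy = _axes(trial_theta)
                count, *_ = find_contacts_kernel(
                    trial_pos, ux, uy, cfg.box_side, seg_half, cfg.e)
                if count > 0:
                    continue
            pos[placed] = p
            theta[placed] = th
            placed += 1
        v_i = rng.normal(cfg.v0_mean, cfg.v0_std, size=n)
        while np.any(v_i <= 0):
            bad = v_i <= 0
            v_i[bad] = rng.normal(cfg.v0_mean, cfg.v0_std, size=bad.sum())
        # pathway pre-adapted to the local concentration
        c = self.concentration(pos[:, 0])
        m = np.asarray(cp.adapted_methylation(c, cfg.pathway), dtype=float)
        # motor states drawn from steady-state run/tumble occupancy
        p_t = cfg.pathway.lambda0 * cfg.tau_t / (1 + cfg.pathway.lambda0 * cfg.tau_t)
        Theta = (rng.random(n) >= p_t).astype(np.int8)
        t_state = np.where(
            Theta == 1,
            rng.exponential(1.0 / cfg.pathway.lambda0, size=n),
            rng.random(n) * cfg.tau_t)
        state = SimState(pos=pos, unwrapped_x=pos[:, 0].copy(), theta=theta,
                         v_i=v_i, Theta=Theta, t_state=t_state, m=m)
        state.vel = (state.Theta * state.v_i)[:, None] * np.stack(
            _axes(state.theta), axis=1)
        return state

    def concentration(self, unwrapped_x: np.ndarray) -> np.ndarray:
        cfg = self.config
        if cfg.gradient is None:
            return np.full_like(np.asarray(unwrapped_x, dtype=float),
                                cfg.pathway.c_adapt)
        g = cfg.gradient
        slope = (g.c_right - g.c_left) / g.channel_length
        c_mid = 0.5 * (g.c_left + g.c_right)
        c = c_mid + slope * (np.asarray(unwrapped_x, dtype=float)
                             - cfg.box_side / 2.0)
        return np.clip(c, min(g.c_left, g.c_right), max(g.c_left, g.c_right))

    # -- dynamics ----------------------------------------------------------
    def _flows(self, state: SimState):
        cfg = self.config
        ux, uy = _axes(state.theta)
        fmag = self.friction.gamma_par * state.v_i * state.Theta
        if self.flow_method == "pairwise":
            t = self._table
            return pairwise_flows_kernel(
                state.pos, ux, uy, fmag, cfg.L_dip, cfg.box_side,
                t.r[0], t.dr, t.A, t.B, self.medium.r_clamp,
                self.medium.r_cutoff)
        n = state.n
        axes = np.stack([ux, uy], axis=1)
        fpoints = np.empty((2 * n, 2))
        forces = np.empty((2 * n, 2))
        fpoints[0::2] = state.pos
        fpoints[1::2] = state.pos - cfg.L_dip * axes
        forces[0::2] = fmag[:, None] * axes
        forces[1::2] = -fmag[:, None] * axes
        epoints = np.empty((2 * n, 2))
        epoints[0::2] = state.pos
        epoints[1::2] = state.pos - cfg.L_dip * axes
        u = self._solver.flows(fpoints, forces, epoints, subtract_self=True)
        return np.ascontiguousarray(u[0::2]), np.ascontiguousarray(u[1::2])

    def _attempt_step(self, state: SimState, dt: float):
        """One Euler sub-step; returns (dr, dtheta, velocity) or None if the
        displacement bound is violated."""
        cfg = self.config
        n = state.n
        ux, uy = _axes(state.theta)
        axes = np.stack([ux, uy], axis=1)

        if cfg.steric_on and n > 1:
            seg_half = (cfg.L - cfg.e) / 2.0
            cnt = find_contacts_kernel(state.pos, ux, uy, cfg.box_side,
                                       seg_half, cfg.e)
            force, torque = steric_forces_kernel(
                *cnt, state.vel_free, ux, uy, cfg.K_el, cfg.K_fr)
        else:
            force = np.zeros((n, 2))
            torque = np.zeros(n)

        if cfg.hydrodynamics_on and n > 1:
            w_c, w_r = self._flows(state)
        else:
            w_c = np.zeros((n, 2))
            w_r = np.zeros((n, 2))

        fr = self.friction
        f_par = force[:, 0] * ux + force[:, 1] * uy
        vel_force = (f_par / fr.gamma_par)[:, None] * axes \
            + (force - f_par[:, None] * axes) / fr.gamma_perp
        vel_free = (state.Theta * state.v_i)[:, None] * axes \
            + 0.5 * (w_c + w_r)
        velocity = vel_free + vel_force
        dr = velocity * dt

        dw = w_c - w_r
        omega = (ux * dw[:, 1] - uy * dw[:, 0]) / cfg.L_dip \
            + torque / fr.gamma_rot
        if np.max(np.abs(dr)) > cfg.e / 2.0 or np.max(np.abs(omega)) * dt > 0.5:
            return None

        xi_r = self.rng.standard_normal(n)
        xi_t = self.rng.standard_normal(n)
        dtheta = omega * dt \
            + np.sqrt(2.0 * cfg.D_r * dt) * xi_r \
            + np.sqrt(2.0 * cfg.D_T * dt) * xi_t * (1 - state.Theta)
        return dr, dtheta, velocity, vel_free

    def _advance(self, state: SimState, dt: float, depth: int = 0) -> None:
        """Advance by dt, recursively halving on displacement violations."""
        res = self._attempt_step(state, dt)
        if res is None:
            if depth >= 8:
                logger.warning("displacement bound still violated at dt/256; "
                               "clamping")
                res = self._attempt_step_clamped(state, dt)
            else:
                if depth == 0:
                    self._rejected_steps += 1
                    if self._rejected_steps in (1, 100, 10000):
                        logger.warning(
                            "step rejected (displacement > e/2); halving dt "
                            "(%d rejections so far)", self._rejected_steps)
                self._advance(state, dt / 2.0, depth + 1)
                self._advance(state, dt / 2.0, depth + 1)
                return
        dr, dtheta, velocity, vel_free = res
        self._apply(state, dr, dtheta, velocity, vel_free, dt)

    def _attempt_step_clamped(self, state: SimState, dt: float):
        """Last-resort fallback: propulsion-only displacements, clamped."""
        cfg = self.config
        n = state.n
        ux, uy = _axes(state.theta)
        axes = np.stack([ux, uy], axis=1)
        velocity = (state.Theta * state.v_i)[:, None] * axes
        dr = np.clip(velocity * dt, -cfg.e / 2.0, cfg.e / 2.0)
        xi_r = self.rng.standard_normal(n)
        xi_t = self.rng.standard_normal(n)
        dtheta = np.sqrt(2.0 * cfg.D_r * dt) * xi_r \
            + np.sqrt(2.0 * cfg.D_T * dt) * xi_t * (1 - state.Theta)
        return dr, dtheta, velocity, velocity

    def _apply(self, state: SimState, dr, dtheta, velocity, vel_free,
               dt) -> None:
        cfg = self.config
        state.unwrapped_x += dr[:, 0]
        state.pos += dr
        state.pos %= cfg.box_side
        state.theta = np.mod(state.theta + dtheta + np.pi, 2 * np.pi) - np.pi
        state.vel = velocity
        state.vel_free = vel_free

        # pathway + motor switching at the local ligand concentration
        c = self.concentration(state.unwrapped_x)
        pstate = cp.PathwayState(m=state.m, a=None, lam=None)
        pstate = cp.update_state(pstate, c, dt, cfg.pathway)
        state.m = pstate.m
        self._last_activity = pstate.a
        lam = np.minimum(pstate.lam, 0.5 / dt)

        running = state.Theta == 1
        start_tumble = running & (self.rng.random(state.n) < lam * dt)
        state.t_state += dt
        end_tumble = (~running) & (state.t_state >= cfg.tau_t)
        state.Theta = np.where(start_tumble, 0, state.Theta).astype(np.int8)
        state.Theta = np.where(end_tumble, 1, state.Theta).astype(np.int8)
        state.t_state = np.where(start_tumble | end_tumble, 0.0, state.t_state)

    def step(self, state: SimState) -> SimState:
        self._advance(state, self.config.dt)
        return state

    # -- driver ------------------------------------------------------------
    def run(self) -> Trajectories:
        cfg = self.config
        state = self.initial_state()
        self._last_activity = cp.receptor_activity(
            state.m, self.concentration(state.unwrapped_x), cfg.pathway)
        n_steps = int(round(cfg.t_total / cfg.dt))
        save_every = max(1, int(round(cfg.save_interval / cfg.dt)))
        n_save = n_steps // save_every + 1
        n = state.n
        times = np.empty(n_save)
        positions = np.empty((n_save, n, 2), dtype=np.float32)
        unwrapped = np.empty((n_save, n), dtype=np.float64)
        theta = np.empty((n_save, n), dtype=np.float64)
        motor = np.empty((n_save, n), dtype=np.int8)
        velocity = np.empty((n_save, n, 2), dtype=np.float64)
        methyl = np.empty((n_save, n), dtype=np.float32)
        activ = np.empty((n_save, n), dtype=np.float32)

        k = 0
        for istep in range(n_steps + 1):
            if istep % save_every == 0 and k < n_save:
                if not np.all(np.isfinite(state.pos)):
                    raise RuntimeError(
                        f"non-finite state at t = {istep * cfg.dt:.3f} s")
                times[k] = istep * cfg.dt
                positions[k] = state.pos
                unwrapped[k] = state.unwrapped_x
                theta[k] = state.theta
                motor[k] = state.Theta
                velocity[k] = state.vel
                methyl[k] = state.m
                activ[k] = self._last_activity
                k += 1
            if istep < n_steps:
                self.step(state)
        return Trajectories(
            times=times[:k], positions=positions[:k], unwrapped_x=unwrapped[:k],
            theta=theta[:k], motor_state=motor[:k], v_i=state.v_i,
            velocity=velocity[:k], methylation=methyl[:k], activity=activ[:k],
            config=cfg)


def step(states: SimState, config: SimulationConfig,
         rng: np.random.Generator) -> SimState:
    """Single Euler step (functional wrapper used by the unit tests)."""
    sim = Simulation(config)
    sim.rng = rng
    sim._last_activity = np.zeros(states.n)
    return sim.step(states)


def run_simulation(config: SimulationConfig) -> Trajectories:
    """Run a full simulation; bit-reproducible for a fixed seed."""
    return Simulation(config).run()
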