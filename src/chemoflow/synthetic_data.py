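"""Generators for every input the analysis layer assumes.

Swimmer trajectory ensembles (Schulz speeds, run-and-tumble directions,
non-motile Brownian fraction), microscopy-like rendered image stacks,
reference velocity fields for the spectral analysis, and quasi-static 1-D
attractant gradient profiles.  All generators are bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.linalg import solve_banded

from .flow_analysis import VelocityField
from .fourier_motility import ImageStack

__all__ = [
    "SwimmerEnsembleSpec",
    "RenderSpec",
    "GradientSpec",
    "ParticleTracks",
    "generate_swimmers",
    "render_stack",
    "vortex_field",
    "gradient_profile",
    "peclet",
    "schulz_speeds",
]


@dataclass(frozen=True)
class SwimmerEnsembleSpec:
    """Population of ideal swimmers mirroring the DDM model assumptions."""

    n: int = 1000
    dimension: int = 3
    v0_mean: float = 20.0          # um/s
    Z: float = 2.0                 # Schulz parameter; sigma_v = v0/sqrt(Z+1)
    alpha: float = 1.0             # motile fraction
    D: float = 0.4                 # diffusivity of non-motile particles (um^2/s)
    tumble_rate: float = 0.0       # 1/s (instantaneous tumbles)
    D_r: float = 0.0               # rotational diffusion (rad^2/s)
    duration: float = 10.0         # s
    dt: float = 0.01               # s
    box: float = 716.8             # um (512 px at 1.4 um/px)
    tumble_kick_std: float = 1.13  # rad, 2D tumble kick
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("need at least one particle")
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")


@dataclass(frozen=True)
class RenderSpec:
    """How to turn particle tracks into a grayscale movie."""

    px_size: float = 1.4           # um
    frame_size: int = 512          # px (square frames)
    frame_rate: float = 100.0      # 1/s
    psf_sigma: float = 1.5         # px
    amplitude: float = 100.0       # integrated counts per particle
    noise_sigma: float = 0.0       # additive Gaussian noise (counts)
    poisson_noise: bool = False
    background: float = 10.0       # counts

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.frame_size < 64:
            raise ValueError("frame size must be >= 64 px")


@dataclass(frozen=True)
class GradientSpec:
    """Quasi-static 1-D attractant gradient between two reservoirs."""

    c_left: float = 0.0            # uM
    c_right: float = 200.0         # uM
    channel_length: float = 2000.0  # um
    D_ligand: float = 500.0        # um^2/s
    dx: float = 10.0               # grid spacing (um)
    v_f: float = 10.0              # advective speed scale for Pe (um/s)

    def __post_init__(self) -> None:
        if self.c_left < 0 or self.c_right < 0:
            raise ValueError("concentrations must be >= 0")
        if self.D_ligand <= 0:
            raise ValueError("D_ligand must be positive")


@dataclass
class ParticleTracks:
    """Trajectories of an ideal ensemble (attribute-compatible subset of
    the simulator's ``Trajectories``)."""

    times: np.ndarray              # (T,)
    positions: np.ndarray          # (T, n, dim), um, wrapped into the box
    speeds: np.ndarray             # (n,) quenched speed of each particle
    motile: np.ndarray             # (n,) bool
    theta: Optional[np.ndarray] = None  # (T, n) in-plane angle (2D only)
    box: float = 716.8


def schulz_speeds(n: int, v0_mean: float, Z: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Schulz(Z) speed sample == Gamma(shape Z+1, mean v0_mean)."""
    return rng.gamma(shape=Z + 1.0, scale=v0_mean / (Z + 1.0), size=n)


def _unit_vectors(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_swimmers(spec: SwimmerEnsembleSpec) -> ParticleTracks:
    """Ideal run-and-tumble/Brownian ensemble.

    Motile particles move at a quenched Schulz-distributed speed; their
    direction performs rotational diffusion and is redrawn (3D: uniform;
    2D: Gaussian kick) at Poisson tumble events.  Non-motile particles are
    Brownian with diffusivity D.
    """
    rng = np.random.default_rng(spec.seed)
    n, dim = spec.n, spec.dimension
    n_steps = int(round(spec.duration / spec.dt))
    motile = rng.random(n) < spec.alpha
    speeds = np.where(motile, schulz_speeds(n, spec.v0_mean, spec.Z, rng), 0.0)
    pos = rng.random((n, dim)) * spec.box
    dirs = _unit_vectors(n, dim, rng)
    theta = np.arctan2(dirs[:, 1], dirs[:, 0]) if dim == 2 else None

    times = np.arange(n_steps + 1) * spec.dt
    out = np.empty((n_steps + 1, n, dim))
    out[0] = pos
    thetas = np.empty((n_steps + 1, n)) if dim == 2 else None
    if thetas is not None:
        thetas[0] = theta
    sqdt_D = np.sqrt(2.0 * spec.D * spec.dt)
    for t in range(1, n_steps + 1):
        # non-motile: Brownian
        if np.any(~motile):
            pos[~motile] += sqdt_D * rng.standard_normal(((~motile).sum(), dim))
        # motile: ballistic + rotational diffusion + tumbles
        if np.any(motile):
            idx = np.flatnonzero(motile)
            pos[idx] += speeds[idx, None] * dirs[idx] * spec.dt
            if spec.D_r > 0:
                if dim == 2:
                    theta[idx] += np.sqrt(2 * spec.D_r * spec.dt) \
                        * rng.standard_normal(len(idx))
                    dirs[idx, 0] = np.cos(theta[idx])
                    dirs[idx, 1] = np.sin(theta[idx])
                else:
                    kick = rng.standard_normal((len(idx), 3)) \
                        * np.sqrt(2 * spec.D_r * spec.dt)
                    d = dirs[idx]
                    kick -= np.sum(kick * d, axis=1, keepdims=True) * d
                    d = d + kick
                    dirs[idx] = d / np.linalg.norm(d, axis=1, keepdims=True)
            if spec.tumble_rate > 0:
                tumble = rng.random(len(idx)) < spec.tumble_rate * spec.dt
                tidx = idx[tumble]
                if len(tidx):
                    if dim == 3:
                        dirs[tidx] = _unit_vectors(len(tidx), 3, rng)
                    else:
                        theta[tidx] += spec.tumble_kick_std \
                            * rng.standard_normal(len(tidx))
                        dirs[tidx, 0] = np.cos(theta[tidx])
                        dirs[tidx, 1] = np.sin(theta[tidx])
        pos %= spec.box
        out[t] = pos
        if thetas is not None:
            thetas[t] = theta
    return ParticleTracks(times=times, positions=out, speeds=speeds,
                          motile=motile, theta=thetas, box=spec.box)


@njit(cache=True)
def _stamp_frames(frames, xs, ys, amplitude, sigma, radius):
    """Add a normalized Gaussian spot per particle per frame (in place)."""
    T, H, W = frames.shape
    n = xs.shape[1]
    for t in range(T):
        for p in range(n):
            x = xs[t, p]
            y = ys[t, p]
            i0 = int(np.floor(x))
            j0 = int(np.floor(y))
            total = 0.0
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    dx = i0 + di - x
                    dy = j0 + dj - y
                    total += np.exp(-(dx * dx + dy * dy) / (2 * sigma * sigma))
            if total <= 0.0:
                continue
            norm = amplitude / total
            for di in range(-radius, radius + 1):
                ii = (i0 + di) % H
                for dj in range(-radius, radius + 1):
                    jj = (j0 + dj) % W
                    dx = i0 + di - x
                    dy = j0 + dj - y
                    frames[t, ii, jj] += norm * np.exp(
                        -(dx * dx + dy * dy) / (2 * sigma * sigma))


def render_stack(tracks: ParticleTracks, spec: RenderSpec,
                 rod_aspect: float = 1.0, seed: int = 0) -> ImageStack:
    """Render particle tracks as a noisy grayscale movie.

    Each particle deposits exactly ``spec.amplitude`` counts as a Gaussian
    spot (periodic wrap; truncation radius 6 sigma keeps the pre-noise
    intensity budget conserved to better than 1e-6).  3D tracks are
    projected on (x, y) with z-independent amplitude (thin-slab imaging).
    With ``rod_aspect > 1`` and in-plane angles available, spots are
    anisotropic Gaussians elongated along the particle axis.
    """
    rng = np.random.default_rng(seed)
    T = tracks.positions.shape[0]
    H = W = spec.frame_size
    xs = (tracks.positions[:, :, 1] / spec.px_size) % W  # columns <- y
    ys = (tracks.positions[:, :, 0] / spec.px_size) % H  # rows   <- x
    frames = np.zeros((T, H, W))
    radius = int(np.ceil(6.0 * spec.psf_sigma * max(rod_aspect, 1.0)))
    if rod_aspect == 1.0 or tracks.theta is None:
        _stamp_frames(frames, ys, xs, spec.amplitude, spec.psf_sigma, radius)
    else:
        _stamp_anisotropic(frames, ys, xs, tracks.theta, spec.amplitude,
                           spec.psf_sigma, rod_aspect, radius)
    frames += spec.background
    if spec.poisson_noise:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    if spec.noise_sigma > 0:
        frames += spec.noise_sigma * rng.standard_normal(frames.shape)
    return ImageStack(frames=frames.astype(np.float32),
                      px_size=spec.px_size, frame_rate=spec.frame_rate)


def _stamp_anisotropic(frames, ys, xs, thetas, amplitude, sigma, aspect,
                       radius):
    T, H, W = frames.shape
    offs = np.arange(-radius, radius + 1)
    di, dj = np.meshgrid(offs, offs, indexing="ij")
    for t in range(T):
        ct = np.cos(thetas[t])
        st = np.sin(thetas[t])
        for p in range(ys.shape[1]):
            x, y = ys[t, p], xs[t, p]
            i0, j0 = int(np.floor(x)), int(np.floor(y))
            dx = i0 + di - x
            dy = j0 + dj - y
            # rotate into the rod frame (long axis first)
            a_ = dx * ct[p] + dy * st[p]
            b_ = -dx * st[p] + dy * ct[p]
            patch = np.exp(-(a_**2 / (aspect**2) + b_**2) / (2 * sigma**2))
            patch *= amplitude / patch.sum()
            ii = (i0 + offs) % H
            jj = (j0 + offs) % W
            frames[t][np.ix_(ii, jj)] += patch


def vortex_field(ell: float, amplitude: float, side: float,
                 spacing: float = 1.0, n_frames: int = 1) -> VelocityField:
    """Periodic vortex lattice with spectral eddy size exactly ``ell``.

    Built from the stream function ``psi = (cos(kx) + cos(ky)) A/k`` with
    ``k = pi/ell`` (a Taylor-Green array rotated by 45 degrees), so the
    kinetic energy sits on the wave vectors (+-k, 0), (0, +-k): the
    annularly averaged spectrum peaks at q = pi/ell, i.e. the pi/q eddy
    size convention returns ``ell`` exactly.
    """
    n = int(round(side / spacing))
    if abs(n * spacing - side) > 1e-9:
        raise ValueError("side must be a multiple of the grid spacing")
    if abs((side / (2 * ell)) - round(side / (2 * ell))) > 1e-9:
        raise ValueError("grid side must be a multiple of 2*ell")
    k = np.pi / ell
    x = np.arange(n) * spacing
    X, Y = np.meshgrid(x, x, indexing="ij")
    u = np.empty((n_frames, n, n, 2))
    u[..., 0] = -amplitude * np.sin(k * Y)
    u[..., 1] = amplitude * np.sin(k * X)
    times = np.arange(n_frames, dtype=float)
    return VelocityField(u=u, spacing=spacing, times=times)


def gradient_profile(spec: GradientSpec, t: float,
                     c_init: Optional[np.ndarray] = None):
    """Concentration profile c(x, t) of the 1-D reservoir-fed gradient.

    Crank-Nicolson integration of the diffusion equation with Dirichlet
    boundaries (c_left, c_right); the initial condition defaults to a
    uniform profile at ``c_left``.  Returns (x, c).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    nx = int(round(spec.channel_length / spec.dx)) + 1
    x = np.linspace(0.0, spec.channel_length, nx)
    c = np.full(nx, spec.c_left) if c_init is None else c_init.astype(float).copy()
    c[0] = spec.c_left
    c[-1] = spec.c_right
    if t == 0:
        return x, c
    # time step: a fraction of the slowest relaxation time, but never
    # coarser than ~200 steps over the requested horizon
    tau1 = spec.channel_length**2 / (np.pi**2 * spec.D_ligand)
    dt = min(tau1 / 200.0, t / 20.0)
    n_steps = max(1, int(np.ceil(t / dt)))
    dt = t / n_steps
    r = spec.D_ligand * dt / (2.0 * spec.dx**2)

    # banded matrices for interior nodes
    n_int = nx - 2
    ab = np.zeros((3, n_int))
    ab[0, 1:] = -r
    ab[1, :] = 1 + 2 * r
    ab[2, :-1] = -r
    for _ in range(n_steps):
        rhs = c[1:-1] + r * (c[2:] - 2 * c[1:-1] + c[:-2])
        rhs[0] += r * spec.c_left
        rhs[-1] += r * spec.c_right
        c[1:-1] = solve_banded((1, 1), ab, rhs)
        c[0] = spec.c_left
        c[-1] = spec.c_right
    return x, c


def peclet(spec: GradientSpec, h: float) -> float:
    """Pe = h v_f / D comparing eddy stirring to ligand diffusion."""
    if h <= 0:
        raise ValueError("h must be positive")
    return h * spec.v_f / spec.D_ligand
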