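"""Quasi-2D Hele-Shaw Green's function and pusher force-dipole flows.

A point force in a thin fluid slab of height ``h`` (depth-averaged Stokes
flow with wall friction) generates an in-plane velocity field screened on
the length ``1/sqrt(kappa)`` with ``kappa = 12/h^2``::

    U(r) = G(r) . F,
    G(r) = [c1(z) I + c2(z) rr/|r|^2] / (pi eta h kappa |r|^2),  z = sqrt(kappa)|r|
    c1(z) = z^2 [K0(z) + K2(z)] / 2 - 1
    c2(z) = 2 - z^2 K2(z)

with ``K_n`` modified Bessel functions of the second kind.  A swimmer is a
dipole of two opposite point forces (pusher symmetry) separated by
``L_dip`` along its axis, both evaluated explicitly (the far-field dipole
expansion is not used).

Units: um, s, pN, with eta in Pa*s = pN*s/um^2.

Two evaluation paths are provided:

* an exact pairwise kernel (:func:`hele_shaw_kernel`, :func:`dipole_flow`)
  plus a tabulated radial interpolation used by the numba force loops;
* a periodic spectral solver (:class:`SpectralFlowSolver`) that solves the
  same screened-Stokes equation with FFTs on a grid, used for large
  ensembles where the O(N^2) sum is too slow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import kn

logger = logging.getLogger(__name__)

__all__ = [
    "HeleShawMedium",
    "ForceDipole",
    "bessel_factors",
    "hele_shaw_kernel",
    "dipole_flow",
    "KernelTable",
    "SpectralFlowSolver",
]


@dataclass(frozen=True)
class HeleShawMedium:
    """Fluid slab parameters; ``kappa`` is derived, never set independently."""

    h: float                       # channel height (um)
    eta: float = 1e-3              # dynamic viscosity (Pa s)
    r_clamp: float = 0.5           # minimum evaluation distance (um)
    r_cutoff: float | None = None  # interaction cutoff (um); None -> 6/sqrt(kappa)

    def __post_init__(self) -> None:
        if self.h <= 0 or self.eta <= 0:
            raise ValueError("h and eta must be positive")
        if self.r_cutoff is None:
            object.__setattr__(self, "r_cutoff", 6.0 / np.sqrt(self.kappa))
        if not self.r_clamp < self.r_cutoff:
            raise ValueError("require r_clamp < r_cutoff")

    @property
    def kappa(self) -> float:
        """Screening parameter 12/h^2 (1/um^2), exact by construction."""
        return 12.0 / self.h**2


@dataclass(frozen=True)
class ForceDipole:
    """Pusher force dipole: +F applied at the rod centre, -F a distance
    ``L_dip`` behind it along the orientation ``n``."""

    F_vector: np.ndarray           # point force (pN, 2D) = gamma_par * v * n
    application_point: np.ndarray  # rod centre (um)
    L_dip: float                   # dipole length L/2 + L_flag/2 (um)
    n: np.ndarray                  # unit orientation

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float)
        if abs(np.hypot(n[0], n[1]) - 1.0) > 1e-8:
            raise ValueError("orientation must be a unit vector")


def bessel_factors(z):
    """The scalar factors c1, c2 of the screened point-force kernel."""
    z = np.asarray(z, dtype=float)
    k0 = kn(0, z)
    k2 = kn(2, z)
    c1 = z**2 * (k0 + k2) / 2.0 - 1.0
    c2 = 2.0 - z**2 * k2
    return c1, c2


def hele_shaw_kernel(r, medium: HeleShawMedium) -> np.ndarray:
    """Mobility tensor G(r) (um s^-1 pN^-1) of a point force in the slab.

    Separations shorter than ``medium.r_clamp`` are clamped to the value on
    the clamp circle (the kernel diverges logarithmically at the origin);
    an exactly zero separation is additionally reported, as self
    interactions must be excluded upstream.
    """
    r = np.asarray(r, dtype=float)
    dist = float(np.hypot(r[0], r[1]))
    if dist == 0.0:
        logger.warning("hele_shaw_kernel evaluated at |r| = 0; clamped "
                       "(self-interaction should be excluded upstream)")
        r = np.array([medium.r_clamp, 0.0])
        dist = medium.r_clamp
    elif dist < medium.r_clamp:
        r = r * (medium.r_clamp / dist)
        dist = medium.r_clamp
    kappa = medium.kappa
    z = np.sqrt(kappa) * dist
    c1, c2 = bessel_factors(z)
    rhat = r / dist
    pref = 1.0 / (np.pi * medium.eta * medium.h * kappa * dist**2)
    return pref * (c1 * np.eye(2) + c2 * np.outer(rhat, rhat))


def dipole_flow(source: ForceDipole, eval_point, medium: HeleShawMedium) -> np.ndarray:
    """Fluid velocity (um/s) at ``eval_point`` from one force dipole.

    w(r) = U(+F, r) + U(-F, r + L_dip n), each term through the exact
    kernel.  Beyond ``medium.r_cutoff`` of both force points the flow is
    treated as zero.
    """
    eval_point = np.asarray(eval_point, dtype=float)
    x0 = np.asarray(source.application_point, dtype=float)
    n = np.asarray(source.n, dtype=float)
    F = np.asarray(source.F_vector, dtype=float)
    w = np.zeros(2)
    for sign, origin in ((1.0, x0), (-1.0, x0 - source.L_dip * n)):
        d = eval_point - origin
        if np.hypot(d[0], d[1]) <= medium.r_cutoff:
            w += sign * hele_shaw_kernel(d, medium) @ F
    return w


class KernelTable:
    """Radial tabulation of the kernel factors for the numba pair loops.

    Stores A(r) = c1/(pi eta h kappa r^2) and B(r) = c2/(pi eta h kappa r^2)
    on a uniform radial grid from ``r_clamp`` to ``r_cutoff`` (spacing
    0.02/sqrt(kappa)); lookups are linearly interpolated, and the exact
    Bessel evaluation is retained as the oracle in the tests.
    """

    def __init__(self, medium: HeleShawMedium):
        self.medium = medium
        sk = np.sqrt(medium.kappa)
        dr = 0.02 / sk
        n = int(np.ceil((medium.r_cutoff - medium.r_clamp) / dr)) + 2
        self.r = medium.r_clamp + dr * np.arange(n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # K2 overflow at tiny z is benign
            c1, c2 = bessel_factors(sk * self.r)
        pref = 1.0 / (np.pi * medium.eta * medium.h * medium.kappa * self.r**2)
        self.A = c1 * pref
        self.B = c2 * pref
        self.dr = dr

    def evaluate(self, dist):
        """Interpolated (A, B) at distance(s); clamped below r_clamp."""
        d = np.clip(np.asarray(dist, dtype=float),
                    self.medium.r_clamp, self.r[-1])
        idx = np.clip(((d - self.r[0]) / self.dr).astype(int), 0, len(self.r) - 2)
        w = (d - self.r[idx]) / self.dr
        return (self.A[idx] * (1 - w) + self.A[idx + 1] * w,
                self.B[idx] * (1 - w) + self.B[idx + 1] * w)


class SpectralFlowSolver:
    """Periodic FFT solution of the screened Stokes (Brinkman) equation.

    In Fourier space the incompressible solution of
    ``grad P - eta (lap U - kappa U) = F delta2(r) / h`` is
    ``U(q) = (I - qq/q^2) F / (eta h (q^2 + kappa))``.  Point forces are
    spread to the grid with cloud-in-cell weights; flows are read back by
    bilinear interpolation.  The grid response to a single force (the
    discrete Green's function, including the spreading) is precomputed so
    that each rod's spurious self-generated flow can be subtracted.
    """

    def __init__(self, box_side: float, medium: HeleShawMedium,
                 n_grid: int | None = None):
        if n_grid is None:
            n_grid = int(np.clip(2 * (round(box_side) // 2), 64, 512))
        self.box = float(box_side)
        self.n = int(n_grid)
        self.dx = self.box / self.n
        self.medium = medium
        q1 = 2.0 * np.pi * np.fft.fftfreq(self.n, d=self.dx)
        q1r = 2.0 * np.pi * np.fft.rfftfreq(self.n, d=self.dx)
        qx, qy = np.meshgrid(q1, q1r, indexing="ij")
        q2 = qx**2 + qy**2
        # the factor 2 matches the normalization of the printed real-space
        # kernel (twice the bare Brinkman Green's function); both evaluation
        # paths must agree, and the pairwise kernel is the contract
        denom = medium.eta * medium.h * (q2 + medium.kappa) / 2.0
        q2safe = np.where(q2 == 0.0, 1.0, q2)
        # tensor (I - qq/q^2) / denom; the q=0 (net force) mode is dropped
        self.Txx = np.where(q2 == 0, 0.0, (1.0 - qx * qx / q2safe) / denom)
        self.Tyy = np.where(q2 == 0, 0.0, (1.0 - qy * qy / q2safe) / denom)
        self.Txy = np.where(q2 == 0, 0.0, (-qx * qy / q2safe) / denom)
        self._self_response = self._measure_self_response()

    # -- grid plumbing -----------------------------------------------------
    def _spread(self, points: np.ndarray, forces: np.ndarray) -> np.ndarray:
        """Cloud-in-cell spreading of forces to a (2, n, n) density grid."""
        g = np.zeros((2, self.n, self.n))
        x = (points[:, 0] / self.dx) % self.n
        y = (points[:, 1] / self.dx) % self.n
        i0 = np.floor(x).astype(int)
        j0 = np.floor(y).astype(int)
        fx = x - i0
        fy = y - j0
        i1 = (i0 + 1) % self.n
        j1 = (j0 + 1) % self.n
        for c in range(2):
            f = forces[:, c] / self.dx**2
            np.add.at(g[c], (i0, j0), f * (1 - fx) * (1 - fy))
            np.add.at(g[c], (i1, j0), f * fx * (1 - fy))
            np.add.at(g[c], (i0, j1), f * (1 - fx) * fy)
            np.add.at(g[c], (i1, j1), f * fx * fy)
        return g

    def _weights(self, points: np.ndarray):
        x = (points[:, 0] / self.dx) % self.n
        y = (points[:, 1] / self.dx) % self.n
        i0 = np.floor(x).astype(int)
        j0 = np.floor(y).astype(int)
        fx = x - i0
        fy = y - j0
        i1 = (i0 + 1) % self.n
        j1 = (j0 + 1) % self.n
        return ((i0, j0, 1.0 - fx - fy + fx * fy),
                (i1, j0, fx * (1.0 - fy)),
                (i0, j1, (1.0 - fx) * fy),
                (i1, j1, fx * fy))

    def _interp_stack(self, fields: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of a (..., n, n) field stack; returns
        (n_points, ...)."""
        w4 = self._weights(points)
        lead = fields.shape[:-2]
        out = np.zeros((len(points),) + lead)
        flat = fields.reshape((-1, self.n, self.n))
        acc = np.zeros((len(points), flat.shape[0]))
        for i, j, w in w4:
            acc += flat[:, i, j].T * w[:, None]
        return acc.reshape((len(points),) + lead)

    def _interp(self, fields: np.ndarray, points: np.ndarray) -> np.ndarray:
        return self._interp_stack(fields, points)

    def solve_grid(self, points: np.ndarray, forces: np.ndarray) -> np.ndarray:
        """Velocity field (2, n, n) generated by the given point forces."""
        g = self._spread(points, forces)
        gx = np.fft.rfft2(g[0])
        gy = np.fft.rfft2(g[1])
        ux = np.fft.irfft2(self.Txx * gx + self.Txy * gy, s=(self.n, self.n))
        uy = np.fft.irfft2(self.Txy * gx + self.Tyy * gy, s=(self.n, self.n))
        return np.stack([ux, uy])

    def _measure_self_response(self) -> np.ndarray:
        """Grid Green's function (2, 2, n, n): response fields to a unit
        force placed exactly on the node (n//2, n//2), shifted to origin."""
        c = self.n // 2
        pt = np.array([[c * self.dx, c * self.dx]])
        resp = np.empty((2, 2, self.n, self.n))
        for axis in range(2):
            f = np.zeros((1, 2))
            f[0, axis] = 1.0
            field = self.solve_grid(pt, f)
            resp[axis] = np.roll(field, (-c, -c), axis=(1, 2))
        return resp

    def grid_kernel(self, displacement) -> np.ndarray:
        """Effective discrete G(dr) tensor, for tests and self-subtraction."""
        d = np.atleast_2d(np.asarray(displacement, dtype=float))
        # self_response is (axis j, component i, n, n) -> (npts, j, i)
        out = self._interp_stack(self._self_response, d)
        out = np.swapaxes(out, 1, 2)
        return out if out.shape[0] > 1 else out[0]

    # -- public entry ------------------------------------------------------
    def flows(self, force_points: np.ndarray, forces: np.ndarray,
              eval_points: np.ndarray, subtract_self: bool = False) -> np.ndarray:
        """Flow velocities at ``eval_points`` from all point forces.

        With ``subtract_self=True`` the layout is assumed to be two force
        points and two evaluation points per rod (rows 2i, 2i+1 belong to
        rod i) and each rod's own contribution is removed using the
        discrete grid kernel, mirroring the excluded self-interaction of
        the pairwise sum.
        """
        field = self.solve_grid(force_points, forces)
        u = self._interp_stack(field, eval_points)
        if subtract_self:
            # Remove each rod's own contribution EXACTLY as the grid pipeline
            # added it: its forces were spread with CIC weights and the flow
            # read back with CIC weights, so the self term is the double sum
            # over the 4x4 involved node pairs of the node-to-node Green's
            # function (self_response holds exactly that field).
            n_eval = len(eval_points)
            eval_groups = np.arange(n_eval) // 2
            we4 = self._weights(eval_points)
            resp = self._self_response
            for k in range(2):  # the rod's two force points
                fp = force_points[2 * eval_groups + k]
                fv = forces[2 * eval_groups + k]
                wf4 = self._weights(fp)
                for fi, fj, wf in wf4:
                    for ei, ej, we in we4:
                        di = (ei - fi) % self.n
                        dj = (ej - fj) % self.n
                        G = resp[:, :, di, dj]      # (j_force, i_comp, n)
                        w = wf * we
                        u[:, 0] -= w * (G[0, 0] * fv[:, 0] + G[1, 0] * fv[:, 1])
                        u[:, 1] -= w * (G[0, 1] * fv[:, 0] + G[1, 1] * fv[:, 1])
        return u
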